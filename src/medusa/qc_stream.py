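"""Streaming read processing: quality filter -> host filter -> dual-database counting.

One pass over each FASTQ file produces a count vector per reference
database (genes and genomes) plus a statistics log, without writing any
intermediate read files. The design mirrors a Unix pipe: each stage is a
generator consuming the previous one, so peak memory is the reference
index plus a constant per read.

Alignment is abstracted behind the :class:`Aligner` contract (read ->
scored hits). Two implementations ship:

* :class:`KmerSeedAligner` — an exact-k-mer-seed, mismatch-counting
  aligner for synthetic references; deterministic, no external binary.
* SAM adaptation — :func:`read_sam_alignments` turns the SAM output of
  any external aligner into the :class:`AlignmentRecord` stream consumed
  by :func:`count_alignments`.
"""

from __future__ import annotations

import bz2
import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import ReferenceCatalogue, Thresholds


class MalformedFastqError(ValueError):
    pass


class PhredOffsetError(ValueError):
    pass


class FastqRead(NamedTuple):
    id: str
    seq: str
    qual: str


def open_text(source) -> io.TextIOBase:
    """Open a path as text, decoding gz/bz2 transparently by suffix."""
    if hasattr(source, "read"):
        first = source.read(0)
        if isinstance(first, bytes):
            return io.TextIOWrapper(source)
        return source
    p = str(source)
    if p.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(p, "rb"))
    if p.endswith(".bz2"):
        return io.TextIOWrapper(bz2.open(p, "rb"))
    return open(p, "r")


def read_fastq(source) -> Iterator[FastqRead]:
    """Stream FASTQ records; malformed input raises an error naming the record index."""
    handle = open_text(source)
    it = FastqGeneralIterator(handle)
    i = 0
    while True:
        try:
            title, seq, qual = next(it)
        except StopIteration:
            break
        except ValueError as exc:
            raise MalformedFastqError(f"malformed FASTQ record at index {i}: {exc}") from exc
        yield FastqRead(title.split()[0], seq.upper(), qual)
        i += 1


def _pass_table(min_quality: int, phred_offset: int) -> bytes:
    """Translation table: quality byte -> 1 if Phred >= min_quality else 0."""
    return bytes(1 if b - phred_offset >= min_quality else 0 for b in range(256))


def quality_filter(
    reads: Iterable[FastqRead],
    min_quality: int = 20,
    min_fraction: float = 0.8,
    phred_offset: int = 33,
):
    """Keep a read iff >= min_fraction of its bases have quality >= min_quality.

    Returns ``(generator, stats)``; ``stats`` is a dict updated in place
    (``n_input``, ``n_pass``) as the generator is consumed, preserving
    the streaming contract. Quality bytes below the declared Phred
    offset raise :class:`PhredOffsetError` naming the offset.
    """
    stats = {"n_input": 0, "n_pass": 0}
    tbl = _pass_table(min_quality, phred_offset)

    def gen():
        for read in reads:
            stats["n_input"] += 1
            q = read.qual.encode("ascii")
            if q and min(q) < phred_offset:
                raise PhredOffsetError(
                    f"quality byte below declared Phred offset {phred_offset} "
                    f"in read {read.id!r}"
                )
            n = len(q)
            if n and q.translate(tbl).count(1) / n >= min_fraction:
                stats["n_pass"] += 1
                yield read

    return gen(), stats


# ---------------------------------------------------------------------------
# Aligner contract


class Hit(NamedTuple):
    reference_id: str
    score: int


class Aligner:
    """Contract: map a read sequence to a list of scored reference hits."""

    def map_read(self, seq: str) -> list[Hit]:  # pragma: no cover - interface
        raise NotImplementedError


class KmerSeedAligner(Aligner):
    """Exact-k-mer-seeded, substitution-tolerant test aligner.

    Seeds at a few evenly spaced read positions are looked up in a full
    k-mer index of the references; each candidate placement is verified
    by counting matching bases over the read's span. A hit is called
    when matches / read length >= ``min_identity``. Score = number of
    matching bases. Handles substitution errors, not indels.
    """

    def __init__(
        self,
        references: Mapping[str, str],
        k: int = 21,
        n_seeds: int = 3,
        min_identity: float = 0.9,
    ):
        self.k = k
        self.n_seeds = n_seeds
        self.min_identity = min_identity
        self._ids = list(references)
        self._seqs = [references[i] for i in self._ids]
        index: dict[str, list[tuple[int, int]]] = {}
        for ri, seq in enumerate(self._seqs):
            for p in range(0, len(seq) - k + 1):
                index.setdefault(seq[p : p + k], []).append((ri, p))
        self._index = index

    def _seed_positions(self, read_len: int) -> list[int]:
        span = read_len - self.k
        if span < 0:
            return []
        if self.n_seeds == 1 or span == 0:
            return [0]
        step = max(1, span // (self.n_seeds - 1))
        pos = list(range(0, span + 1, step))[: self.n_seeds]
        if pos[-1] != span:
            pos.append(span)
        return pos

    def map_read(self, seq: str) -> list[Hit]:
        L = len(seq)
        candidates: set[tuple[int, int]] = set()
        for p in self._seed_positions(L):
            for ri, rpos in self._index.get(seq[p : p + self.k], ()):
                start = rpos - p
                if 0 <= start and start + L <= len(self._seqs[ri]):
                    candidates.add((ri, start))
        if not candidates:
            return []
        need = int(np.ceil(self.min_identity * L))
        hits: dict[str, int] = {}
        for ri, start in candidates:
            window = self._seqs[ri][start : start + L]
            if window == seq:
                m = L
            else:
                m = sum(a == b for a, b in zip(seq, window))
            if m >= need:
                rid = self._ids[ri]
                if m > hits.get(rid, -1):
                    hits[rid] = m
        return [Hit(r, s) for r, s in hits.items()]


def host_filter(reads: Iterable[FastqRead], host_aligner: Aligner):
    """Drop reads that hit the host reference; count them.

    Returns ``(generator, stats)`` with ``stats["n_host"]`` filled as the
    stream is consumed.
    """
    stats = {"n_host": 0}

    def gen():
        for read in reads:
            if host_aligner.map_read(read.seq):
                stats["n_host"] += 1
            else:
                yield read

    return gen(), stats


# ---------------------------------------------------------------------------
# Alignment-record counting (SAM adapter path)


@dataclass
class AlignmentRecord:
    """One alignment of a read (reference None == unmapped)."""

    read_id: str
    reference_id: str | None
    score: int = 0
    is_best: bool = False


def read_sam_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Adapt a SAM file into an AlignmentRecord stream (grouped as in file).

    Score priority: AS tag, then MAPQ, else 0. Flag 4 (unmapped) yields a
    record with ``reference_id=None`` so unmapped reads stay accounted.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                yield AlignmentRecord(aln.query_name, None, 0)
                continue
            if aln.has_tag("AS"):
                score = int(aln.get_tag("AS"))
            else:
                score = int(aln.mapping_quality)
            yield AlignmentRecord(aln.query_name, aln.reference_name, score)


def count_alignments(
    records: Iterable[AlignmentRecord],
    policy: str = "best-unique",
    seed: int = 0,
    reference_ids: list[str] | None = None,
) -> pd.Series:
    """Count one unit per aligned read onto a reference, under a multimapping policy.

    Records must be grouped by read (all hits of one read adjacent);
    regrouping raises. Policies:

    * ``best-unique`` — the best-scoring hit gets 1; score ties broken by
      a seeded uniform choice (integer counts).
    * ``all-best-fractional`` — every best-scoring hit gets 1/n_best
      (float counts).
    """
    if policy not in ("best-unique", "all-best-fractional"):
        raise ValueError(f"unknown multimapping policy: {policy!r}")
    rng = np.random.default_rng(seed)
    counts: dict[str, float] = {}
    seen: set[str] = set()
    current: str | None = None
    group: list[AlignmentRecord] = []

    def flush():
        hits = [r for r in group if r.reference_id is not None]
        if not hits:
            return
        best = max(r.score for r in hits)
        best_hits = [r for r in hits if r.score == best]
        for r in best_hits:
            r.is_best = True
        if policy == "best-unique":
            chosen = best_hits[0] if len(best_hits) == 1 else best_hits[rng.integers(len(best_hits))]
            counts[chosen.reference_id] = counts.get(chosen.reference_id, 0) + 1
        else:
            w = 1.0 / len(best_hits)
            for r in best_hits:
                counts[r.reference_id] = counts.get(r.reference_id, 0) + w

    for rec in records:
        if rec.read_id != current:
            if current is not None:
                flush()
                seen.add(current)
            if rec.read_id in seen:
                raise ValueError(
                    f"alignment stream not grouped by read: {rec.read_id!r} reappeared"
                )
            current = rec.read_id
            group = []
        group.append(rec)
    if current is not None:
        flush()

    ids = reference_ids if reference_ids is not None else sorted(counts)
    out = pd.Series([counts.get(i, 0) for i in ids], index=ids)
    if policy == "best-unique":
        out = out.astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# One-pass run processing


@dataclass
class RunStats:
    """Per-run accounting; conservation n_input = fail_qc + host + unaligned + aligned
    holds for each database by construction."""

    run_id: str
    n_input: int = 0
    n_fail_qc: int = 0
    n_host: int = 0
    n_aligned_genes: int = 0
    n_aligned_genomes: int = 0

    @property
    def n_pass_qc(self) -> int:
        return self.n_input - self.n_fail_qc

    @property
    def n_clean(self) -> int:
        """Reads surviving QC and host filtering."""
        return self.n_pass_qc - self.n_host

    def fraction(self, name: str) -> float:
        if self.n_input == 0:
            return 0.0
        num = {
            "pass_qc": self.n_pass_qc,
            "host": self.n_host,
            "aligned_genes": self.n_aligned_genes,
            "aligned_genomes": self.n_aligned_genomes,
        }[name]
        denom = self.n_input if name == "pass_qc" else max(self.n_pass_qc, 1)
        return num / denom

    def to_lines(self) -> list[str]:
        d = {
            "run_id": self.run_id,
            "n_input": self.n_input,
            "n_fail_qc": self.n_fail_qc,
            "n_pass_qc": self.n_pass_qc,
            "n_host": self.n_host,
            "n_aligned_genes": self.n_aligned_genes,
            "n_aligned_genomes": self.n_aligned_genomes,
            "n_unaligned_genes": self.n_clean - self.n_aligned_genes,
            "n_unaligned_genomes": self.n_clean - self.n_aligned_genomes,
        }
        return [f"{k}={v}" for k, v in d.items()]


def _run_id_from_path(path: str | Path) -> str:
    name = Path(path).name
    for suf in (".gz", ".bz2"):
        if name.endswith(suf):
            name = name[: -len(suf)]
    for suf in (".fastq", ".fq"):
        if name.endswith(suf):
            name = name[: -len(suf)]
    return name


def _best_unique(hits: list[Hit], rng: np.random.Generator) -> str | None:
    if not hits:
        return None
    best = max(h.score for h in hits)
    tied = [h.reference_id for h in hits if h.score == best]
    if len(tied) == 1:
        return tied[0]
    return tied[rng.integers(len(tied))]


def stream_align(
    fastq_paths: list[str | Path],
    gene_catalogue: Mapping[str, str] | ReferenceCatalogue,
    genome_catalogue: Mapping[str, str] | ReferenceCatalogue,
    thresholds: Thresholds,
    out_dir: str | Path,
    *,
    host_reference: Mapping[str, str] | None = None,
    aligner_factory=None,
    seed: int = 0,
    phred_offset: int = 33,
    claim: bool = False,
) -> list[RunStats]:
    """Process each FASTQ run through QC -> host filter -> dual-database counting.

    Writes, per run, ``<run>.genes.counts.tsv`` and
    ``<run>.genomes.counts.tsv`` (2-column TSV over the full catalogue in
    catalogue order) plus ``<run>.log`` with key=value statistics. No
    intermediate read files are written; partial outputs are removed on
    error. With ``claim=True``, concurrent invocations skip runs already
    claimed via an exclusive-create ``<run>.claim`` file.
    """
    if isinstance(gene_catalogue, ReferenceCatalogue):
        gene_catalogue = gene_catalogue.subset("gene") or gene_catalogue.sequences
    if isinstance(genome_catalogue, ReferenceCatalogue):
        genome_catalogue = genome_catalogue.subset("contig") or genome_catalogue.sequences
    if aligner_factory is None:
        aligner_factory = KmerSeedAligner
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gene_aligner = aligner_factory(gene_catalogue)
    genome_aligner = aligner_factory(genome_catalogue)
    host_aligner = aligner_factory(host_reference) if host_reference else None
    gene_ids = list(gene_catalogue)
    genome_ids = list(genome_catalogue)

    all_stats: list[RunStats] = []
    for run_idx, path in enumerate(fastq_paths):
        run_id = _run_id_from_path(path)
        if claim:
            claim_path = out_dir / f"{run_id}.claim"
            try:
                fd = os.open(claim_path, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
                os.close(fd)
            except FileExistsError:
                continue
        outputs = [
            out_dir / f"{run_id}.genes.counts.tsv",
            out_dir / f"{run_id}.genomes.counts.tsv",
            out_dir / f"{run_id}.log",
        ]
        try:
            stats = _process_run(
                path,
                run_id,
                gene_aligner,
                genome_aligner,
                host_aligner,
                gene_ids,
                genome_ids,
                thresholds,
                outputs,
                np.random.default_rng([seed, run_idx]),
                phred_offset,
            )
        except Exception as exc:
            for f in outputs:
                if f.exists():
                    f.unlink()
            raise RuntimeError(f"stream_align failed on {path}: {exc}") from exc
        all_stats.append(stats)
    return all_stats


def _process_run(
    path,
    run_id,
    gene_aligner,
    genome_aligner,
    host_aligner,
    gene_ids,
    genome_ids,
    thresholds: Thresholds,
    outputs,
    rng,
    phred_offset,
) -> RunStats:
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    genome_pos = {g: i for i, g in enumerate(genome_ids)}
    gene_counts = np.zeros(len(gene_ids), dtype=np.int64)
    genome_counts = np.zeros(len(genome_ids), dtype=np.int64)
    stats = RunStats(run_id)

    reads = read_fastq(path)
    passed, qstats = quality_filter(
        reads,
        thresholds.qc_min_quality,
        thresholds.qc_min_fraction,
        phred_offset,
    )
    if host_aligner is not None:
        clean, hstats = host_filter(passed, host_aligner)
    else:
        clean, hstats = passed, {"n_host": 0}

    for read in clean:
        ref = _best_unique(gene_aligner.map_read(read.seq), rng)
        if ref is not None:
            gene_counts[gene_pos[ref]] += 1
            stats.n_aligned_genes += 1
        ref = _best_unique(genome_aligner.map_read(read.seq), rng)
        if ref is not None:
            genome_counts[genome_pos[ref]] += 1
            stats.n_aligned_genomes += 1

    stats.n_input = qstats["n_input"]
    stats.n_fail_qc = qstats["n_input"] - qstats["n_pass"]
    stats.n_host = hstats["n_host"]

    for ids, counts, out in (
        (gene_ids, gene_counts, outputs[0]),
        (genome_ids, genome_counts, outputs[1]),
    ):
        with open(out, "w") as fh:
            fh.write("reference_id\tcount\n")
            for i, c in zip(ids, counts):
                fh.write(f"{i}\t{c}\n")
    with open(outputs[2], "w") as fh:
        fh.write("\n".join(stats.to_lines()) + "\n")
    return stats
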