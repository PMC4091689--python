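"""Core data containers shared by every pipeline stage.

The pipeline manipulates three central objects:

* :class:`CountTable` — an integer matrix of read counts with features
  (contigs, genes, taxa, KEGG orthologs) as rows and samples as columns,
  plus optional per-sample metadata (study, subject, visit).
* :class:`AbundanceTable` — a column-normalised relative-abundance matrix
  derived from a count table; each column sums to one (or is all-zero for
  an empty sample, which is flagged rather than silently kept).
* :class:`ReferenceCatalogue` — named nucleotide sequences together with
  the annotation maps used downstream (contig → genome/species lineage,
  gene → KEGG orthologs, gene → study membership).

Features that carry no annotation are pooled under the sentinel
:data:`UNANNOTATED` and, by default, excluded from relative-abundance
denominators of taxon-level tables (abundances are fractions of
*annotated* reads).

All identifiers are opaque strings; input order is preserved so that
outputs are stable and diffable. Counts are 64-bit integers everywhere
upstream of :class:`AbundanceTable` — no floating point sneaks into the
counting path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Sentinel lineage/group for features without an annotation.
UNANNOTATED = "unannotated"

#: Tolerance on column sums of a normalised abundance table.
ABUNDANCE_TOL = 1e-9


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cutoff used by the pipeline, in one place.

    Parameters
    ----------
    gene_presence_min_reads:
        Minimum aligned reads from one sample for a gene to be called
        present (default 2).
    species_presence_min_abund:
        Minimum relative abundance (strictly above) for a species to be
        called present in a subject (default 1e-4).
    rarefaction_depth:
        Number of aligned reads to subsample per sample before presence
        calling (default 11,000,000; scale down for small experiments).
    core_fraction:
        Fraction of subjects that must carry a feature for it to belong
        to the core (0.5 and 0.9 are the conventional choices).
    cluster_identity, cluster_coverage:
        Greedy gene clustering thresholds: nucleotide identity and
        coverage of the shorter sequence (defaults 0.95 / 0.90).
    genus_filter_min_mean:
        Minimum cross-sample mean abundance for a genus to enter
        enterotype analysis (default 1e-4, i.e. 0.01 %).
    qc_min_quality, qc_min_fraction:
        A read passes quality control iff at least ``qc_min_fraction``
        of its bases have Phred quality >= ``qc_min_quality``.
    """

    gene_presence_min_reads: int = 2
    species_presence_min_abund: float = 1e-4
    rarefaction_depth: int = 11_000_000
    core_fraction: float = 0.5
    cluster_identity: float = 0.95
    cluster_coverage: float = 0.90
    genus_filter_min_mean: float = 1e-4
    qc_min_quality: int = 20
    qc_min_fraction: float = 0.8

    def __post_init__(self) -> None:
        for name in ("gene_presence_min_reads", "rarefaction_depth", "qc_min_quality"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        for name in (
            "species_presence_min_abund",
            "core_fraction",
            "cluster_identity",
            "cluster_coverage",
            "genus_filter_min_mean",
            "qc_min_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")


def _check_axis(ids: pd.Index, axis: str) -> list[str]:
    out = []
    dup = ids[ids.duplicated()].unique()
    for d in dup:
        out.append(f"duplicate {axis} id: {d!r}")
    return out


@dataclass
class CountTable:
    """Integer read-count matrix, features x samples.

    ``data`` is a pandas DataFrame with feature ids as the index and
    sample ids as columns, integer dtype. ``meta`` (optional) is indexed
    by sample id with columns such as ``study``, ``subject``, ``visit``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None

    @classmethod
    def from_arrays(
        cls,
        feature_ids: Iterable[str],
        sample_ids: Iterable[str],
        counts: np.ndarray,
        meta: pd.DataFrame | None = None,
    ) -> "CountTable":
        df = pd.DataFrame(
            np.asarray(counts, dtype=np.int64),
            index=pd.Index(list(feature_ids), name="feature_id"),
            columns=list(sample_ids),
        )
        return cls(df, meta)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def column_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def validate(self) -> list[str]:
        """Report every invariant violation; an empty list means valid."""
        v: list[str] = []
        v += _check_axis(self.data.index, "feature")
        v += _check_axis(self.data.columns, "sample")
        if not pd.api.types.is_integer_dtype(self.data.dtypes.iloc[0] if len(self.data.columns) else np.dtype("int64")):
            v.append("counts are not integer typed")
        arr = self.data.to_numpy()
        if arr.size and pd.api.types.is_numeric_dtype(arr):
            neg = np.argwhere(arr < 0)
            for i, j in neg[:50]:
                v.append(
                    f"negative count at feature {self.data.index[i]!r}, "
                    f"sample {self.data.columns[j]!r}: {arr[i, j]}"
                )
        if self.meta is not None:
            missing = set(self.meta.index) - set(self.data.columns)
            for s in sorted(missing):
                v.append(f"meta refers to unknown sample id: {s!r}")
        return v

    # -- TSV round trip (gzip-transparent via pandas) ------------------
    def to_tsv(self, path: str | Path) -> None:
        self.data.rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, meta: pd.DataFrame | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df.astype(np.int64), meta)


def validate(table: CountTable) -> list[str]:
    """Functional alias for :meth:`CountTable.validate`."""
    return table.validate()


@dataclass
class AbundanceTable:
    """Column-normalised relative abundances on the same axes as a CountTable.

    ``denominator_policy`` records what the column total was when
    normalising (e.g. ``"annotated"`` when the unannotated pool was
    excluded). Samples whose column was all-zero are listed in
    ``zero_samples`` and left as zero columns.
    """

    data: pd.DataFrame
    denominator_policy: str = "annotated"
    zero_samples: tuple[str, ...] = ()
    meta: pd.DataFrame | None = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def validate(self) -> list[str]:
        v: list[str] = []
        v += _check_axis(self.data.index, "feature")
        v += _check_axis(self.data.columns, "sample")
        arr = self.data.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            v.append("abundances outside [0, 1]")
        sums = arr.sum(axis=0)
        for j, s in enumerate(sums):
            sid = self.data.columns[j]
            if sid in self.zero_samples:
                if s != 0:
                    v.append(f"sample {sid!r} flagged all-zero but sums to {s}")
            elif abs(s - 1.0) > ABUNDANCE_TOL:
                v.append(f"column {sid!r} sums to {s}, not 1")
        return v

    def to_tsv(self, path: str | Path) -> None:
        self.data.rename_axis("feature_id").to_csv(path, sep="\t")


@dataclass
class ReferenceCatalogue:
    """Named reference sequences plus their annotation maps.

    ``feature_to_group`` maps a sequence id to its group (contig to
    genome/species, gene to cluster). ``group_to_lineage`` maps a group
    to a ``(species, genus, phylum)`` tuple; unannotated groups carry the
    sentinel :data:`UNANNOTATED`. ``feature_kind`` optionally tags each
    id as ``"contig"``, ``"gene"`` or ``"host"`` so one catalogue object
    can hold both databases of a dual-database mapping run.
    """

    sequences: dict[str, str]
    feature_to_group: dict[str, str] = field(default_factory=dict)
    group_to_lineage: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    gene_to_ko: dict[str, frozenset[str]] = field(default_factory=dict)
    gene_to_study: dict[str, frozenset[str]] = field(default_factory=dict)
    feature_kind: dict[str, str] = field(default_factory=dict)

    def validate(self) -> list[str]:
        v: list[str] = []
        for fid in self.feature_to_group:
            if fid not in self.sequences:
                v.append(f"feature_to_group id not in sequences: {fid!r}")
        for g, lin in self.group_to_lineage.items():
            if not all(isinstance(x, str) and x for x in lin):
                v.append(f"group {g!r} has an empty lineage field")
        return v

    def subset(self, kind: str) -> dict[str, str]:
        """Sequences of one kind (``contig`` / ``gene`` / ``host``)."""
        return {
            i: s for i, s in self.sequences.items() if self.feature_kind.get(i) == kind
        }

    def feature_to_level(self, level: str) -> dict[str, str]:
        """Map each feature id to its taxon name at ``level``.

        ``level`` is ``species``, ``genus`` or ``phylum``. Features whose
        group has no lineage map to :data:`UNANNOTATED`.
        """
        pos = {"species": 0, "genus": 1, "phylum": 2}[level]
        out = {}
        for fid in self.sequences:
            grp = self.feature_to_group.get(fid)
            lin = self.group_to_lineage.get(grp) if grp is not None else None
            out[fid] = lin[pos] if lin is not None else UNANNOTATED
        return out

    # -- FASTA IO ------------------------------------------------------
    def write_fasta(self, path: str | Path, kind: str | None = None) -> None:
        seqs = self.sequences if kind is None else self.subset(kind)
        write_fasta(seqs, path)

    @classmethod
    def from_fasta(cls, path: str | Path, kind: str | None = None) -> "ReferenceCatalogue":
        seqs = read_fasta(path)
        kinds = {i: kind for i in seqs} if kind else {}
        return cls(sequences=seqs, feature_kind=kinds)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class SampleMap:
    """Links sequencing runs to samples, samples to subjects and visits.

    Every run maps to exactly one sample (a sample may span several
    runs); visits are 1-based, with visit 1 the sample kept when
    deduplicating repeat visits per subject.
    """

    run_to_sample: dict[str, str] = field(default_factory=dict)
    sample_to_subject: dict[str, str] = field(default_factory=dict)
    sample_to_visit: dict[str, int] = field(default_factory=dict)
    sample_to_study: dict[str, str] = field(default_factory=dict)

    def validate(self) -> list[str]:
        v = []
        for s, visit in self.sample_to_visit.items():
            if visit < 1:
                v.append(f"sample {s!r} has visit {visit} < 1")
        return v

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        samples = set(self.run_to_sample.values()) | set(self.sample_to_subject)
        for run, sample in self.run_to_sample.items():
            rows.append(
                (
                    run,
                    sample,
                    self.sample_to_subject.get(sample, sample),
                    self.sample_to_visit.get(sample, 1),
                    self.sample_to_study.get(sample, "NA"),
                )
            )
        for sample in sorted(samples - set(self.run_to_sample.values())):
            rows.append(
                (
                    "NA",
                    sample,
                    self.sample_to_subject.get(sample, sample),
                    self.sample_to_visit.get(sample, 1),
                    self.sample_to_study.get(sample, "NA"),
                )
            )
        pd.DataFrame(
            rows, columns=["run_id", "sample_id", "subject_id", "visit", "study"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        sm = cls()
        for _, row in df.iterrows():
            run = row.get("run_id")
            sample = str(row["sample_id"])
            if run is not None and not pd.isna(run) and run != "NA":
                if run in sm.run_to_sample and sm.run_to_sample[run] != sample:
                    raise ValueError(f"run {run!r} maps to two samples")
                sm.run_to_sample[str(run)] = sample
            if "subject_id" in df.columns and not pd.isna(row["subject_id"]):
                sm.sample_to_subject[sample] = str(row["subject_id"])
            if "visit" in df.columns and not pd.isna(row["visit"]):
                sm.sample_to_visit[sample] = int(row["visit"])
            if "study" in df.columns and not pd.isna(row["study"]):
                sm.sample_to_study[sample] = str(row["study"])
        return sm


def read_annotation_tsv(path: str | Path, value_cols: int = 1):
    """Read a 2+-column annotation TSV (id, value...).

    With ``value_cols == 1`` returns ``dict[id, str]``; with more,
    ``dict[id, tuple]``. Repeated ids accumulate into a frozenset of
    values (a gene may map to several KEGG orthologs or studies).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, object] = {}
    multi = False
    for row in df.itertuples(index=False):
        key = row[0]
        val = row[1] if value_cols == 1 else tuple(row[1 : 1 + value_cols])
        if key in out:
            prev = out[key]
            if not isinstance(prev, frozenset):
                prev = frozenset([prev])
            out[key] = prev | {val}
            multi = True
        else:
            out[key] = val
    if multi:  # promote all values to sets for a uniform type
        out = {
            k: (v if isinstance(v, frozenset) else frozenset([v])) for k, v in out.items()
        }
    return out


def ceil_fraction(fraction: float, n: int) -> int:
    """Smallest integer >= fraction * n, robust to float representation.

    Used for "present in at least X % of subjects": with 10 subjects and
    fraction 0.9 the threshold is 9, not 10 (0.9 * 10 stored as
    9.000000000000002 must not round up).
    """
    return int(math.ceil(fraction * n - 1e-9))
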