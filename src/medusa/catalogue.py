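"""Non-redundant gene-catalogue construction by greedy incremental clustering.

Sequences are sorted by decreasing length (ties by id) and each joins
the first existing cluster whose *representative* it matches at the
identity/coverage thresholds (95 % nucleotide identity and 90 %
coverage of the shorter sequence by default), else it founds a new
cluster. Per-study catalogues are built first and then merged into a
global catalogue with the same thresholds, keeping study provenance per
global cluster for downstream sharing (Venn) analysis.

The pairwise kernel is a glocal alignment: the shorter sequence is
aligned end-to-end against the best-matching stretch of the longer
(edlib, infix mode). Identity is matches over the aligned columns of
the shorter's span; coverage is the aligned length of the shorter over
its length. ``N`` bases never match, not even another ``N``.

To keep clustering of large inputs tractable, candidate clusters are
pre-filtered by shared k-mers (k = 8) with the representative; at 95 %
identity a shared 8-mer is guaranteed for any plausible gene length, so
the filter does not change results versus all-pairs comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib

_CIG_RE = re.compile(r"(\d+)([=XIDM])")
_VALID = re.compile(r"^[ACGTN]+$")


def _check_seq(seq: str, sid: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence: {sid!r}")
    s = seq.upper()
    if not _VALID.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"sequence {sid!r} contains invalid characters: {bad}")
    return s


def sequence_identity(a: str, b: str) -> tuple[float, float]:
    """Identity and coverage of the shorter sequence under glocal alignment.

    Returns ``(identity, coverage)`` where identity = matching columns /
    aligned columns of the shorter sequence's span and coverage =
    aligned length of the shorter / its length (1.0 under a full glocal
    alignment; gaps opened inside the span still count as aligned
    columns and depress identity).
    """
    a = _check_seq(a, "a")
    b = _check_seq(b, "b")
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    # N must never match: give each side a private placeholder letter.
    q = query.replace("N", "P")
    t = target.replace("N", "Q")
    res = edlib.align(q, t, mode="HW", task="path")
    cigar = res["cigar"]
    matches = cols = q_cols = 0
    for num, op in _CIG_RE.findall(cigar):
        num = int(num)
        cols += num
        if op == "=":
            matches += num
            q_cols += num
        elif op in ("X", "I"):
            q_cols += num
    identity = matches / cols if cols else 0.0
    coverage = q_cols / len(query)
    return identity, coverage


@dataclass
class GeneCluster:
    representative: str
    members: list[str] = field(default_factory=list)
    member_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    studies: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def greedy_cluster(
    sequences: Mapping[str, str],
    identity_t: float = 0.95,
    coverage_t: float = 0.90,
    k: int = 8,
    studies: Mapping[str, Iterable[str]] | None = None,
) -> list[GeneCluster]:
    """Length-sorted greedy clustering against cluster representatives.

    Each sequence (processed longest first, ties by id) joins the first
    existing cluster — in founding order — whose representative it
    matches at >= identity_t and >= coverage_t, else founds a new
    cluster. Deterministic; duplicate ids raise.
    """
    ids = list(sequences)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    seqs = {sid: _check_seq(sequences[sid], sid) for sid in ids}
    order = sorted(ids, key=lambda sid: (-len(seqs[sid]), sid))

    clusters: list[GeneCluster] = []
    kmer_index: dict[str, list[int]] = {}  # kmer -> cluster indices (founding order)

    for sid in order:
        seq = seqs[sid]
        cand: set[int] = set()
        for km in _kmers(seq, k):
            cand.update(kmer_index.get(km, ()))
        joined = False
        for ci in sorted(cand):
            rep = clusters[ci].representative
            ident, cov = sequence_identity(seq, seqs[rep])
            if ident >= identity_t and cov >= coverage_t:
                cl = clusters[ci]
                cl.members.append(sid)
                cl.member_stats[sid] = (ident, cov)
                if studies:
                    cl.studies.update(studies.get(sid, ()))
                joined = True
                break
        if not joined:
            ci = len(clusters)
            cl = GeneCluster(representative=sid, members=[sid], member_stats={sid: (1.0, 1.0)})
            if studies:
                cl.studies.update(studies.get(sid, ()))
            clusters.append(cl)
            for km in _kmers(seq, k):
                kmer_index.setdefault(km, []).append(ci)
    return clusters


def merge_catalogues(
    per_study: list[tuple[str, Mapping[str, str]]],
    identity_t: float = 0.95,
    coverage_t: float = 0.90,
) -> list[GeneCluster]:
    """Cluster the pooled per-study representatives into a global catalogue.

    Input is ``[(study_label, {gene_id: seq}), ...]`` — typically the
    representatives of each per-study catalogue. Ids are namespaced as
    ``study/gene_id`` so identical ids across studies stay distinct.
    Each global cluster's study set is the union of its members' labels,
    ready for :func:`medusa.corepan.venn_partition`.
    """
    pooled: dict[str, str] = {}
    study_of: dict[str, set[str]] = {}
    for label, seqs in per_study:
        for gid, seq in seqs.items():
            nid = f"{label}/{gid}"
            if nid in pooled:
                raise ValueError(f"duplicate gene id within study: {nid!r}")
            pooled[nid] = seq
            study_of[nid] = {label}
    return greedy_cluster(pooled, identity_t, coverage_t, studies=study_of)


def cluster_membership_rows(clusters: list[GeneCluster]) -> list[tuple]:
    """Flatten clusters to (cluster_rep, member, identity, coverage, studies) rows."""
    rows = []
    for cl in clusters:
        for m in cl.members:
            ident, cov = cl.member_stats[m]
            rows.append((cl.representative, m, ident, cov, ",".join(sorted(cl.studies))))
    return rows


def clusters_to_study_map(clusters: list[GeneCluster]) -> dict[str, frozenset]:
    """Cluster representative -> study-label set (input to venn_partition)."""
    return {cl.representative: frozenset(cl.studies) for cl in clusters}
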