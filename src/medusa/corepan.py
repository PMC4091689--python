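"""Presence calling and core/pan analysis for species and genes.

The core microbiome is defined on the individual: repeat visits are
removed first (one column per subject), a presence rule is applied
(>= 2 reads for genes on rarefied counts; relative abundance strictly
above 1e-4 for species), and a feature belongs to the core at fraction
f if it is present in at least ceil(f * n_subjects) subjects. Pan/core
accumulation curves average over seeded random subject orderings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AbundanceTable, CountTable, SampleMap, ceil_fraction


@dataclass
class PresenceMatrix:
    """Boolean features x subjects matrix plus the rule that produced it."""

    data: pd.DataFrame  # bool
    rule: str

    @property
    def n_subjects(self) -> int:
        return self.data.shape[1]


@dataclass
class PanCoreCurve:
    n_subjects: np.ndarray  # 1..N
    pan: np.ndarray  # mean pan size per n
    core: dict[float, np.ndarray]  # core_fraction -> mean core size per n
    n_orderings: int = 0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"n_subjects": self.n_subjects, "pan": self.pan})
        for f, c in self.core.items():
            df[f"core{int(round(f * 100))}"] = c
        return df


@dataclass
class VennPartition:
    """Disjoint regions keyed by study subset; union covers all clusters."""

    regions: dict[frozenset, set] = field(default_factory=dict)

    def sizes(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region_of(self, cluster_id: str) -> frozenset | None:
        for k, members in self.regions.items():
            if cluster_id in members:
                return k
        return None


def dedupe_subjects(
    table: CountTable, sample_map: SampleMap
) -> tuple[CountTable, list[str]]:
    """Keep one column per subject: the visit-1 sample, else the lowest visit (with a warning)."""
    by_subject: dict[str, list[tuple[int, str]]] = {}
    for s in table.sample_ids:
        subj = sample_map.sample_to_subject.get(s, s)
        visit = sample_map.sample_to_visit.get(s, 1)
        by_subject.setdefault(subj, []).append((visit, s))
    keep: list[str] = []
    dropped: list[str] = []
    for subj, visits in by_subject.items():
        visits.sort()
        if visits[0][0] != 1:
            warnings.warn(
                f"subject {subj!r} has no visit-1 sample; keeping visit {visits[0][0]}"
            )
        keep.append(visits[0][1])
        dropped.extend(s for _, s in visits[1:])
    keep = [s for s in table.sample_ids if s in set(keep)]  # preserve input order
    data = table.data[keep]
    meta = table.meta.loc[keep] if table.meta is not None else None
    return CountTable(data, meta), dropped


def call_presence_reads(table: CountTable, min_reads: int = 2) -> PresenceMatrix:
    """Present iff at least ``min_reads`` reads aligned in the sample.

    The table should be rarefied to a common depth first so presence is
    comparable across samples (not enforced).
    """
    return PresenceMatrix(table.data >= min_reads, rule=f"reads>={min_reads}")


def call_presence_abundance(
    abund: AbundanceTable, min_abund: float = 1e-4, strict: bool = True
) -> PresenceMatrix:
    """Present iff relative abundance is above ``min_abund`` (strictly, by default)."""
    if strict:
        return PresenceMatrix(abund.data > min_abund, rule=f"abund>{min_abund}")
    return PresenceMatrix(abund.data >= min_abund, rule=f"abund>={min_abund}")


def core_size(presence: PresenceMatrix, core_fraction: float) -> int:
    """Number of features present in >= ceil(core_fraction * n_subjects) subjects."""
    n = presence.n_subjects
    need = ceil_fraction(core_fraction, n)
    return int((presence.data.sum(axis=1) >= need).sum())


def pan_size(presence: PresenceMatrix) -> int:
    return int((presence.data.sum(axis=1) >= 1).sum())


def pan_core_curve(
    presence: PresenceMatrix,
    fractions: Sequence[float] = (0.5, 0.9),
    n_orderings: int = 100,
    seed: int = 0,
) -> PanCoreCurve:
    """Pan and core sizes as subjects accumulate, averaged over random orderings.

    For each ordering, after adding the first n subjects the pan is the
    number of features seen at least once and the core at fraction f the
    number present in >= ceil(f * n) of those n.
    """
    M = presence.data.to_numpy(dtype=np.int64)
    n_feat, N = M.shape
    rng = np.random.default_rng(seed)
    pan_acc = np.zeros(N)
    core_acc = {f: np.zeros(N) for f in fractions}
    needs = {f: np.array([ceil_fraction(f, n) for n in range(1, N + 1)]) for f in fractions}
    for _ in range(n_orderings):
        order = rng.permutation(N)
        cum = M[:, order].cumsum(axis=1)
        pan_acc += (cum > 0).sum(axis=0)
        for f in fractions:
            core_acc[f] += (cum >= needs[f][None, :]).sum(axis=0)
    return PanCoreCurve(
        n_subjects=np.arange(1, N + 1),
        pan=pan_acc / n_orderings,
        core={f: core_acc[f] / n_orderings for f in fractions},
        n_orderings=n_orderings,
        seed=seed,
    )


def core_sensitivity(
    abund: AbundanceTable,
    cutoffs: Iterable[float],
    core_fraction: float = 0.5,
    strict: bool = True,
) -> pd.DataFrame:
    """Core and pan sizes as a function of the abundance presence cutoff."""
    rows = []
    for c in cutoffs:
        pres = call_presence_abundance(abund, c, strict=strict)
        rows.append((c, core_size(pres, core_fraction), pan_size(pres)))
    return pd.DataFrame(rows, columns=["cutoff", "core_size", "pan_size"])


def venn_partition(cluster_to_studies: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition clusters by the exact set of studies they occur in."""
    regions: dict[frozenset, set] = {}
    for cid, studies in cluster_to_studies.items():
        key = frozenset(studies)
        if not key:
            raise ValueError(f"cluster {cid!r} has an empty study set")
        regions.setdefault(key, set()).add(cid)
    return VennPartition(regions)


def abundance_by_region(
    table: CountTable,
    venn: VennPartition,
    normalize_by_region_size: bool = False,
) -> pd.DataFrame:
    """Per-sample read fraction attributed to each sharing region.

    Rows are regions (keyed by '+'-joined sorted study labels), columns
    samples; each column sums to 1 unless the sample had no reads on any
    catalogued cluster (flagged by an all-zero column). In normalised
    mode each region's fraction is divided by the number of genes in the
    region before rescaling, giving a per-gene abundance share.
    """
    region_keys = sorted(venn.regions, key=lambda k: (len(k), tuple(sorted(k))))
    rows = []
    for key in region_keys:
        members = [m for m in venn.regions[key] if m in table.data.index]
        rows.append(table.data.loc[members].sum(axis=0))
    mat = pd.DataFrame(
        rows, index=["+".join(sorted(k)) for k in region_keys], columns=table.sample_ids
    ).astype(float)
    if normalize_by_region_size:
        sizes = np.array([len(venn.regions[k]) for k in region_keys], dtype=float)
        mat = mat.div(sizes, axis=0)
    totals = mat.sum(axis=0)
    safe = totals.replace(0, 1.0)
    return mat.div(safe, axis=1)


def gene_richness(rarefied: CountTable, min_reads: int = 2) -> pd.Series:
    """Number of features with >= min_reads reads, per sample (at fixed depth)."""
    return (rarefied.data >= min_reads).sum(axis=0)
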