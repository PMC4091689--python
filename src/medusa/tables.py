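"""Count-table algebra: combine runs, annotate to taxa/KOs, normalise, rarefy, test.

All counting operations are exact integer arithmetic; combine and
aggregate conserve total counts (including the pooled "unannotated"
features). Rarefaction is a single seeded multivariate-hypergeometric
draw — reads are subsampled without replacement so each rarefied column
sums exactly to the requested depth.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import UNANNOTATED, AbundanceTable, CountTable, SampleMap


def read_count_file(path: str | Path) -> pd.Series:
    """Read a 2-column (reference id, count) TSV into an integer Series."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    s = pd.Series(df.iloc[:, 1].to_numpy(np.int64), index=df.iloc[:, 0].astype(str))
    return s


def _run_id(path: str | Path) -> str:
    return Path(path).name.split(".")[0]


def combine_counts(
    run_counts: Mapping[str, pd.Series] | Iterable[str | Path],
    sample_map: SampleMap,
) -> CountTable:
    """Merge per-run count vectors into one table with a column per sample.

    ``run_counts`` is either a mapping run_id -> count Series, or an
    iterable of 2-column count-file paths whose run id is the filename
    up to the first dot. Runs mapping to the same sample are summed
    element-wise; the feature axis is the union over runs (absent
    features count 0). Unmapped run ids raise, listing them.
    """
    if not isinstance(run_counts, Mapping):
        run_counts = {_run_id(p): read_count_file(p) for p in run_counts}
    unmapped = [r for r in run_counts if r not in sample_map.run_to_sample]
    if unmapped:
        raise KeyError(f"run ids missing from sample map: {sorted(unmapped)}")

    feature_order: list[str] = []
    seen: set[str] = set()
    sample_order: list[str] = []
    per_sample: dict[str, pd.Series] = {}
    for run, counts in run_counts.items():
        for f in counts.index:
            if f not in seen:
                seen.add(f)
                feature_order.append(f)
        sample = sample_map.run_to_sample[run]
        if sample in per_sample:
            per_sample[sample] = per_sample[sample].add(counts, fill_value=0)
        else:
            per_sample[sample] = counts.astype(np.int64)
            sample_order.append(sample)

    data = pd.DataFrame(
        {s: per_sample[s].reindex(feature_order, fill_value=0).astype(np.int64) for s in sample_order},
        index=pd.Index(feature_order, name="feature_id"),
    )
    meta_rows = {}
    for s in sample_order:
        meta_rows[s] = {
            "study": sample_map.sample_to_study.get(s, "NA"),
            "subject": sample_map.sample_to_subject.get(s, s),
            "visit": sample_map.sample_to_visit.get(s, 1),
        }
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return CountTable(data, meta)


def aggregate_by_annotation(
    table: CountTable,
    feature_to_group: Mapping[str, str | frozenset | set],
    level: str = "group",
    multi_policy: str = "full",
) -> CountTable:
    """Sum feature counts into annotation groups; unmapped features pool as "unannotated".

    A feature mapping to several groups (e.g. a gene with several KEGG
    orthologs) contributes its full count to each group under
    ``multi_policy="full"`` (documented double counting; the unannotated
    pool and singly-mapped features still conserve totals) or count/n
    per group under ``"fractional"`` (rounded back to integers by
    truncation of the summed float — use full mode when exact
    conservation matters).
    """
    if multi_policy not in ("full", "fractional"):
        raise ValueError(f"unknown multi_policy: {multi_policy!r}")
    groups: dict[str, np.ndarray] = {}
    order: list[str] = []
    n_samples = len(table.sample_ids)
    arr = table.counts
    acc: dict[str, np.ndarray] = {}

    def add(group: str, row: np.ndarray):
        if group not in acc:
            acc[group] = row.astype(float).copy()
            order.append(group)
        else:
            acc[group] = acc[group] + row

    for i, fid in enumerate(table.feature_ids):
        g = feature_to_group.get(fid)
        if g is None:
            add(UNANNOTATED, arr[i])
        elif isinstance(g, (set, frozenset)):
            if not g:
                add(UNANNOTATED, arr[i])
            elif multi_policy == "full":
                for gg in sorted(g):
                    add(gg, arr[i])
            else:
                for gg in sorted(g):
                    add(gg, arr[i] / len(g))
        else:
            add(g, arr[i])

    # keep the unannotated pool last for readable output
    if UNANNOTATED in order:
        order.remove(UNANNOTATED)
        order.append(UNANNOTATED)
    data = pd.DataFrame(
        np.rint([acc[g] for g in order]).astype(np.int64) if order else np.zeros((0, n_samples), np.int64),
        index=pd.Index(order, name=level),
        columns=table.sample_ids,
    )
    return CountTable(data, table.meta)


def relative_abundance(
    table: CountTable, include_unannotated: bool = False
) -> AbundanceTable:
    """Column-normalise a count table to relative abundances.

    By default the "unannotated" pool is dropped from both the matrix
    and the denominator, so fractions are of *annotated* reads; pass
    ``include_unannotated=True`` to normalise over everything. All-zero
    columns stay zero and are flagged in ``zero_samples``.
    """
    data = table.data
    policy = "all"
    if not include_unannotated and UNANNOTATED in data.index:
        data = data.drop(index=UNANNOTATED)
        policy = "annotated"
    arr = data.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    zero = totals == 0
    safe = np.where(zero, 1.0, totals)
    frac = arr / safe
    out = pd.DataFrame(frac, index=data.index, columns=data.columns)
    return AbundanceTable(
        out,
        denominator_policy=policy,
        zero_samples=tuple(data.columns[zero]),
        meta=table.meta,
    )


def rarefy(
    table: CountTable, depth: int, seed: int = 0
) -> tuple[CountTable, list[str]]:
    """Subsample every column to exactly ``depth`` reads without replacement.

    Each kept column is one multivariate-hypergeometric draw (the reads
    of the sample are an urn with one colour per feature). Samples with
    fewer than ``depth`` total reads cannot be subsampled and are
    dropped; their ids are returned. A fixed seed gives an identical
    draw.
    """
    if depth < 0:
        raise ValueError(f"rarefaction depth must be >= 0, got {depth}")
    rng = np.random.default_rng(seed)
    kept_cols = []
    dropped: list[str] = []
    out = {}
    for s in table.sample_ids:
        col = table.data[s].to_numpy(np.int64)
        total = int(col.sum())
        if total < depth:
            dropped.append(s)
            continue
        if total == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth, method="marginals")
        kept_cols.append(s)
    data = pd.DataFrame(
        np.column_stack([out[s] for s in kept_cols]) if kept_cols else np.zeros((len(table.feature_ids), 0), np.int64),
        index=table.data.index,
        columns=kept_cols,
        dtype=np.int64,
    )
    meta = table.meta.loc[kept_cols] if table.meta is not None else None
    return CountTable(data, meta), dropped


def diff_abundance(
    abund: AbundanceTable | pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney rank-sum test per feature between two groups.

    Returns a DataFrame (statistic, p, q) indexed by feature;
    q-values are Benjamini-Hochberg adjusted. Features constant across
    both groups (including all-zero) get p = 1. Requires two groups with
    at least 2 samples each.
    """
    data = abund.data if isinstance(abund, AbundanceTable) else abund
    labels = pd.Series(group_labels)
    labels = labels.reindex(data.columns)
    if labels.isna().any():
        missing = list(data.columns[labels.isna()])
        raise KeyError(f"samples without a group label: {missing}")
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = data.loc[:, labels == levels[0]].to_numpy(float)
    b = data.loc[:, labels == levels[1]].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")

    allv = np.hstack([a, b])
    constant = allv.max(axis=1) == allv.min(axis=1)
    stat = np.full(len(data), np.nan)
    p = np.ones(len(data))
    if (~constant).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sps.mannwhitneyu(
                a[~constant], b[~constant], axis=1, alternative="two-sided"
            )
        stat[~constant] = res.statistic
        p[~constant] = np.nan_to_num(res.pvalue, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"statistic": stat, "p": p, "q": q}, index=data.index)
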