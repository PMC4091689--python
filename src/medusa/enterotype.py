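"""Enterotype analysis of genus-level profiles.

Protocol: filter low-abundance genera (mean abundance above 0.01 % by
default), compute the root Jensen-Shannon distance matrix between
samples, cluster with partitioning-around-medoids (PAM) for a range of
k, and pick the k with the strongest Calinski-Harabasz support; the
silhouette width and the per-cluster driver genus (the genus with the
largest mean-abundance excess inside the cluster) are reported as
diagnostics.

The root-JSD, d(a, b) = sqrt(0.5 KL(a||m) + 0.5 KL(b||m)) with
m = (a+b)/2 and natural logarithms, is a metric on compositions; zeros
are replaced by a small pseudocount and columns renormalised before the
KL terms are evaluated.

PAM here is the classic BUILD + SWAP local search on a distance matrix:
BUILD greedily seeds k medoids, SWAP repeatedly applies the best
medoid/non-medoid exchange until no exchange lowers the total
within-cluster distance-to-medoid cost. The seed only breaks exact
ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import jensenshannon

from .model import AbundanceTable


def filter_genera(abund: AbundanceTable, min_mean: float = 1e-4) -> AbundanceTable:
    """Keep genera with cross-sample mean abundance strictly above ``min_mean``; renormalise columns."""
    means = abund.data.mean(axis=1)
    keep = means > min_mean
    if not keep.any():
        raise ValueError(f"no genus has mean abundance above {min_mean}")
    data = abund.data.loc[keep]
    totals = data.sum(axis=0)
    zero = totals == 0
    data = data.div(totals.replace(0, 1.0), axis=1)
    return AbundanceTable(
        data,
        denominator_policy=f"{abund.denominator_policy}|genus-filtered>{min_mean}",
        zero_samples=tuple(data.columns[zero]),
        meta=abund.meta,
    )


def jsd_matrix(abund: AbundanceTable, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Symmetric root-Jensen-Shannon distance matrix between sample profiles."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    X = abund.data.to_numpy(float).copy()
    if pseudocount > 0:
        X[X == 0] = pseudocount
        X = X / X.sum(axis=0, keepdims=True)
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = jensenshannon(X[:, i], X[:, j])
    D = np.nan_to_num(D, nan=0.0)
    return pd.DataFrame(D, index=abund.sample_ids, columns=abund.sample_ids)


# ---------------------------------------------------------------------------
# PAM


@dataclass
class PAMResult:
    labels: np.ndarray  # 1..k per point, in distance-matrix order
    medoids: np.ndarray  # point indices, ascending
    cost: float


def _tie_pick(values: np.ndarray, best, rng: np.random.Generator, minimize: bool) -> int:
    tol = 1e-12 * max(1.0, abs(best))
    cand = np.flatnonzero(np.abs(values - best) <= tol)
    if len(cand) == 1:
        return int(cand[0])
    return int(rng.choice(cand))


def _build(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """BUILD: first medoid minimises the total distance; each subsequent
    medoid maximises the total decrease in nearest-medoid distance."""
    totals = D.sum(axis=1)
    medoids = [_tie_pick(totals, totals.min(), rng, True)]
    dmin = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dmin[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        j = _tie_pick(gains, gains.max(), rng, False)
        medoids.append(j)
        dmin = np.minimum(dmin, D[j])
    return np.array(sorted(medoids))


def _swap(D: np.ndarray, med: np.ndarray, rng: np.random.Generator, max_iter: int):
    """Best-improvement SWAP until no medoid/non-medoid exchange lowers cost."""
    n = D.shape[0]
    k = len(med)
    cost = D[med].min(axis=0).sum()
    for _ in range(max_iter):
        dm = D[med]  # k x n
        order = np.argsort(dm, axis=0)
        nearest = order[0]
        d1 = dm[nearest, np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        best_cost = cost
        best_swap = None
        for mi in range(k):
            base = np.where(nearest == mi, d2, d1)  # per-point cost with medoid mi removed
            cand_costs = np.minimum(base[None, :], D).sum(axis=1)
            cand_costs[med] = np.inf
            c = cand_costs.min()
            if c < best_cost - 1e-12:
                best_cost = c
                best_swap = (mi, _tie_pick(cand_costs, c, rng, True))
        if best_swap is None:
            break
        mi, h = best_swap
        med = med.copy()
        med[mi] = h
        med = np.sort(med)
        cost = best_cost
    return med, float(cost)


def pam(dist, k: int, seed: int = 0, max_iter: int = 200, n_restarts: int = 6) -> PAMResult:
    """k-medoids by BUILD + SWAP on a precomputed distance matrix.

    Each run terminates at a local optimum: no single medoid/non-medoid
    exchange lowers the total distance of points to their nearest
    medoid. Because best-improvement SWAP from the BUILD seeding can
    stall in a sub-optimal basin, ``n_restarts`` additional SWAP runs
    are started from seeded random medoid sets and the lowest-cost
    solution is kept. Deterministic for a given seed.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dist must be a square matrix")
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    rng = np.random.default_rng(seed)

    med, cost = _swap(D, _build(D, k, rng), rng, max_iter)
    for _ in range(n_restarts):
        init = np.sort(rng.choice(n, size=k, replace=False))
        m, c = _swap(D, init, rng, max_iter)
        if c < cost - 1e-12:
            med, cost = m, c
    labels = np.argmin(D[med], axis=0) + 1
    labels[med] = np.arange(1, k + 1)  # a medoid belongs to its own cluster
    return PAMResult(labels=labels, medoids=med, cost=float(cost))


# ---------------------------------------------------------------------------
# Cluster-quality indices on a distance matrix


def ch_index(dist, labels) -> float:
    """Calinski-Harabasz score computed directly from a distance matrix.

    Uses the pairwise dispersion identity (the same device as the
    PERMANOVA pseudo-F): for a set S, the sum of squared deviations from
    its centroid equals sum_{i<j in S} d_ij^2 / |S|, so

        W = sum_c sum_{i<j in c} d_ij^2 / n_c,   B = T - W,
        CH = (B / (k-1)) / (W / (n-k)),

    with T the total dispersion over all n points. No embedding or
    explicit centroid is needed, and unlike a medoid plug-in this keeps
    the classical variance decomposition exact for Euclidean-embeddable
    distances. With a single cluster (or k == n) the score is undefined
    and NaN is returned with a warning.
    """
    D = np.asarray(dist, float)
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= n:
        warnings.warn(f"CH index undefined for k={k}, n={n}")
        return float("nan")
    D2 = D**2
    iu = np.triu_indices(n, 1)
    T = D2[iu].sum() / n
    W = 0.0
    for c in uniq:
        idx = np.flatnonzero(labels == c)
        sub = D2[np.ix_(idx, idx)]
        W += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    B = max(T - W, 0.0)
    if W == 0:
        return float("inf") if B > 0 else float("nan")
    return (B / (k - 1)) / (W / (n - k))


def silhouette(dist, labels) -> tuple[pd.Series | None, float]:
    """Per-sample silhouette widths and their mean (precomputed distances).

    s(i) = (b - a) / max(a, b) with a the mean distance to the own
    cluster and b the smallest mean distance to another cluster;
    singleton clusters score 0. A single cluster is undefined:
    returns (None, NaN) with a warning.
    """
    from sklearn.metrics import silhouette_samples

    D = np.asarray(dist, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("silhouette undefined for a single cluster")
        return None, float("nan")
    widths = silhouette_samples(D, labels, metric="precomputed")
    idx = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(len(labels))
    return pd.Series(widths, index=idx, name="silhouette"), float(widths.mean())


# ---------------------------------------------------------------------------
# Full protocol


@dataclass
class EnterotypeResult:
    k: int
    labels: pd.Series  # sample id -> 1..k
    medoids: list[str]
    ch_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    driver_genera: dict[int, str] = field(default_factory=dict)
    degenerate: bool = False


def enterotype(
    abund: AbundanceTable,
    k_range=range(2, 11),
    pseudocount: float = 1e-6,
    min_mean: float = 1e-4,
    seed: int = 0,
) -> EnterotypeResult:
    """Filter genera -> root-JSD -> PAM over k_range -> pick k by CH.

    The driver genus of a cluster is the genus whose mean abundance
    inside the cluster most exceeds its mean outside. If every pairwise
    distance is (numerically) zero the cohort is degenerate: no cluster
    structure exists and the result is flagged.
    """
    filt = filter_genera(abund, min_mean)
    dist = jsd_matrix(filt, pseudocount)
    D = dist.to_numpy()
    if D.max() < 1e-12:
        labels = pd.Series(1, index=filt.sample_ids)
        return EnterotypeResult(
            k=1, labels=labels, medoids=[filt.sample_ids[0]],
            ch_by_k={}, silhouette_by_k={}, degenerate=True,
        )
    results: dict[int, PAMResult] = {}
    ch_by_k: dict[int, float] = {}
    sil_by_k: dict[int, float] = {}
    for k in k_range:
        res = pam(D, k, seed=seed)
        results[k] = res
        ch_by_k[k] = ch_index(D, res.labels)
        _, sil_by_k[k] = silhouette(D, res.labels)
    best_k = max(ch_by_k, key=lambda k: (np.nan_to_num(ch_by_k[k], nan=-np.inf), -k))
    best = results[best_k]
    labels = pd.Series(best.labels, index=filt.sample_ids, name="enterotype")

    drivers: dict[int, str] = {}
    for c in range(1, best_k + 1):
        inside = labels.index[labels == c]
        outside = labels.index[labels != c]
        diff = filt.data[inside].mean(axis=1)
        if len(outside):
            diff = diff - filt.data[outside].mean(axis=1)
        drivers[c] = str(diff.idxmax())
    return EnterotypeResult(
        k=best_k,
        labels=labels,
        medoids=[filt.sample_ids[i] for i in best.medoids],
        ch_by_k=ch_by_k,
        silhouette_by_k=sil_by_k,
        driver_genera=drivers,
    )


def clustering_agreement(labels_a, labels_b) -> float:
    """Best label-permutation agreement between two clusterings of the same samples.

    The contingency table is matched with the Hungarian algorithm and
    the maximal fraction of identically assigned samples returned.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings must cover the same samples")
    tab = pd.crosstab(a.to_numpy(), b.to_numpy()).to_numpy()
    rows, cols = linear_sum_assignment(-tab)
    return float(tab[rows, cols].sum()) / len(a)
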