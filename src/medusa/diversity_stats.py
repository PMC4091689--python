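"""Diversity indices and sample clustering.

Shannon diversity is computed with the natural logarithm:
H = -sum_i p_i ln p_i over features with p_i > 0, so 0 <= H <= ln(S).
Sample heatmap clustering uses complete linkage on 1 - Spearman
correlation between profiles restricted to the most abundant features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .model import AbundanceTable


def shannon(abund: AbundanceTable) -> pd.Series:
    """Per-sample Shannon index (natural log); all-zero samples get NaN."""
    arr = abund.data.to_numpy(float)
    out = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        p = arr[:, j]
        p = p[p > 0]
        out[j] = np.nan if p.size == 0 else float(sps.entropy(p))
    return pd.Series(out, index=abund.sample_ids, name="shannon")


def top_features(abund: AbundanceTable, n_top: int) -> list[str]:
    """The n features with highest mean relative abundance across samples."""
    means = abund.data.mean(axis=1)
    return list(means.sort_values(ascending=False, kind="stable").index[:n_top])


@dataclass
class SampleDendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def spearman_distance(abund: AbundanceTable, n_top_features: int | None = None) -> pd.DataFrame:
    """1 - Spearman correlation between sample profiles.

    Profiles are optionally restricted to the top features by mean
    abundance. A constant profile has undefined rank correlation; its
    distances are set to 1 with a warning.
    """
    data = abund.data
    if n_top_features is not None:
        data = data.loc[top_features(abund, n_top_features)]
    arr = data.to_numpy(float)
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(arr, axis=0).statistic
    rho = np.asarray(rho, float)
    if rho.ndim == 0:  # scipy collapses the 2-sample case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    if np.isnan(rho).any():
        warnings.warn("constant profile: Spearman undefined, distance set to 1")
    dist = 1.0 - np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    return pd.DataFrame(dist, index=data.columns, columns=data.columns)


def cluster_samples(
    abund: AbundanceTable, n_top_features: int | None = 30
) -> SampleDendrogram:
    """Complete-linkage hierarchical clustering on Spearman-correlation distance."""
    dist = spearman_distance(abund, n_top_features)
    Z = hierarchy.linkage(squareform(dist.to_numpy(), checks=False), method="complete")
    return SampleDendrogram(Z, list(dist.columns))
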