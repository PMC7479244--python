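"""Correlation-based hierarchical clustering of samples on methylation
percentages, after a per-group completeness filter.

On sperm methylomes this reproduces the qualitative finding that samples group
by individual (bull) rather than by diet: with inter-individual variability
exceeding the group effect, paired samples from the same bull at two ages are
mutual nearest neighbours while a 2-cluster cut is uninformative about diet.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform


def completeness_filter(
    pct: pd.DataFrame, groups: dict[str, str], min_per_group: int = 4
) -> pd.DataFrame:
    """Retain sites (rows) with non-missing values in at least ``min_per_group``
    samples of *every* listed group.

    ``pct`` is sites x samples (NaN = missing); ``groups`` maps sample id ->
    group label.  ``min_per_group = 0`` is the identity.
    """
    labels = set(groups.values())
    missing_cols = [s for s in pct.columns if s not in groups]
    if missing_cols:
        raise ValueError(f"samples without group label: {missing_cols}")
    keep = np.ones(len(pct), dtype=bool)
    for g in sorted(labels):
        cols = [s for s in pct.columns if groups[s] == g]
        if min_per_group > len(cols):
            raise ValueError(
                f"min_per_group={min_per_group} exceeds size of group {g} ({len(cols)})"
            )
        keep &= pct[cols].notna().sum(axis=1).to_numpy() >= min_per_group
    return pct.loc[keep]


def correlation_distance_matrix(
    pct: pd.DataFrame, method: str = "pearson", min_shared_sites: int = 100
) -> pd.DataFrame:
    """Sample-by-sample correlation distance ``d = 1 - r`` with pairwise-complete
    site sets per sample pair.  Raises if any pair shares fewer than
    ``min_shared_sites`` sites (and always if fewer than 2)."""
    if pct.shape[1] < 2:
        raise ValueError("need at least two samples")
    notna = pct.notna().to_numpy()
    shared = notna.T.astype(int) @ notna.astype(int)
    ids = list(pct.columns)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if shared[i, j] < max(min_shared_sites, 2):
                raise ValueError(
                    f"samples {ids[i]} and {ids[j]} share only {shared[i, j]} sites"
                )
    r = pct.corr(method=method, min_periods=2)
    d = 1.0 - r
    np.fill_diagonal(d.values, 0.0)
    return d


class Dendrogram:
    """Agglomerative clustering result over samples.

    Holds the scipy linkage matrix and the (lexicographically ordered) leaf
    labels; exports newick with branch lengths and flat cluster cuts.
    """

    def __init__(self, linkage: np.ndarray, labels: list[str], method: str):
        self.linkage = linkage
        self.labels = list(labels)
        self.method = method
        heights = linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise AssertionError("merge heights must be non-decreasing")

    def cut(self, n_clusters: int) -> pd.Series:
        assign = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.labels)
        return str(tree).strip()

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(sch.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        sch.dendrogram(self.linkage, labels=self.labels, ax=ax, leaf_rotation=90)
        ax.set_ylabel("correlation distance")
        return ax


def hierarchical_cluster(distances: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a sample distance matrix.

    Samples are reordered lexicographically by id before linkage so tie-breaking
    is deterministic; repeated runs on equal inputs give identical trees.
    """
    d = distances.to_numpy()
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    order = np.argsort(np.asarray(distances.columns, dtype=object), kind="mergesort")
    labels = [distances.columns[i] for i in order]
    d = d[np.ix_(order, order)]
    np.fill_diagonal(d, 0.0)
    Z = sch.linkage(squareform(d, checks=False), method=linkage)
    return Dendrogram(Z, labels, method=linkage)


def mutual_nearest_neighbors(distances: pd.DataFrame) -> list[tuple[str, str]]:
    """Pairs of samples that are each other's nearest neighbour."""
    d = distances.copy()
    np.fill_diagonal(d.values, np.inf)
    nn = d.idxmin(axis=1)
    pairs = []
    for s, t in nn.items():
        if nn[t] == s and s < t:
            pairs.append((s, t))
    return pairs


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two flat partitions (comb-based form)."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    n = len(a)
    ct = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(ct).sum()
    sum_a = comb2(ct.sum(axis=1)).sum()
    sum_b = comb2(ct.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 0.0
    return float((sum_ij - expected) / (max_index - expected))
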