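"""Hierarchical clustering of concatenated elution features.

Profile similarity is the squared Euclidean distance between feature
vectors.  Agglomerative clustering (Ward's criterion by default, which
minimizes the within-cluster sum of squared distances and therefore pairs
naturally with the metric) produces a merge tree that can be cut at any
number of clusters; cluster IDs at a cut are numbered 1..k by dendrogram
left-to-right position so that nearby IDs correspond to nearby leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform


@dataclass
class ClusteringResult:
    """Merge tree plus cached cluster assignments at requested cuts."""

    entry_ids: list[str]
    linkage_matrix: np.ndarray
    metric: str = "sqeuclidean"
    linkage_method: str = "ward"
    assignments: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def n_entries(self) -> int:
        return len(self.entry_ids)

    def labels(self, k: int) -> np.ndarray:
        """Cluster labels (1..k, dendrogram order) aligned with entry_ids."""
        assign = self.assignments.get(k)
        if assign is None:
            raise KeyError(f"cut k={k} not computed")
        return np.array([assign[e] for e in self.entry_ids])


def pairwise_distance(features: np.ndarray) -> np.ndarray:
    """Squared-Euclidean distance matrix: d(x, y) = sum_j (x_j - y_j)^2."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be 2-D (entries x features)")
    return squareform(pdist(features, metric="sqeuclidean"))


def build_dendrogram(
    features: np.ndarray,
    entry_ids: list[str] | None = None,
    linkage_method: str = "ward",
) -> ClusteringResult:
    """Agglomerative merge tree on squared-Euclidean profile distances.

    'ward' operates on the raw observations (its objective is the increase
    in within-cluster squared distance); 'average' and friends use the
    precomputed squared-Euclidean condensed distances.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 2:
        raise ValueError("need >= 2 entries to cluster")
    if entry_ids is None:
        entry_ids = [f"entry{i}" for i in range(n)]
    if len(entry_ids) != n:
        raise ValueError("entry_ids length must match features")
    if linkage_method == "ward":
        z = linkage(features, method="ward")
    else:
        z = linkage(pdist(features, metric="sqeuclidean"), method=linkage_method)
    return ClusteringResult(
        entry_ids=list(entry_ids),
        linkage_matrix=z,
        linkage_method=linkage_method,
    )


def cut_dendrogram(result: ClusteringResult, k: int) -> dict[str, int]:
    """Cut the merge tree into exactly k clusters.

    IDs are renumbered 1..k by the position of each cluster's first leaf
    in dendrogram left-to-right order, so IDs are stable across runs and
    adjacent IDs correspond to adjacent subtrees.  The assignment is
    cached on the result.
    """
    n = result.n_entries
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    if k in result.assignments:
        return result.assignments[k]
    raw = cut_tree(result.linkage_matrix, n_clusters=k).ravel()
    order = leaves_list(result.linkage_matrix)
    relabel: dict[int, int] = {}
    for leaf in order:
        lab = raw[leaf]
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    assign = {
        result.entry_ids[i]: relabel[raw[i]] for i in range(n)
    }
    result.assignments[k] = assign
    return assign


def cut_sweep(result: ClusteringResult, k_values: list[int]) -> dict[int, dict[str, int]]:
    """Assignments at every requested cut (e.g. 20..600 step 10)."""
    return {k: cut_dendrogram(result, k) for k in k_values if 1 <= k <= result.n_entries}


@dataclass
class ClusterDiagnostics:
    """Within-cluster distance diagnostics at one cut."""

    k: int
    cluster_sizes: dict[int, int]
    within_distances: dict[int, float]  # mean member-to-center distance per cluster
    quartiles: tuple[float, float, float]  # Q1, median, Q3 across clusters

    @property
    def mean_within(self) -> float:
        return float(np.mean(list(self.within_distances.values())))


def _within_distance(members: np.ndarray, exponent: int = 2) -> float:
    """Mean member-to-center distance; squared Euclidean by default."""
    center = members.mean(axis=0)
    d = np.sum((members - center) ** 2, axis=1)
    if exponent == 1:
        d = np.sqrt(d)
    return float(d.mean())


def within_cluster_distance_sweep(
    features: np.ndarray,
    result: ClusteringResult,
    k_values: list[int],
    exponent: int = 2,
) -> dict[int, ClusterDiagnostics]:
    """Per-cluster mean member-to-center distance at each cut.

    A singleton cluster has distance exactly 0.  The cross-cluster
    quartiles drive the resolution diagnostic: as k grows the third
    quartile approaches zero once most clusters are tight or singletons.
    """
    features = np.asarray(features, dtype=float)
    out: dict[int, ClusterDiagnostics] = {}
    for k in k_values:
        if not 1 <= k <= result.n_entries:
            continue
        assign = cut_dendrogram(result, k)
        labels = result.labels(k)
        sizes: dict[int, int] = {}
        within: dict[int, float] = {}
        for cid in range(1, k + 1):
            mask = labels == cid
            sizes[cid] = int(mask.sum())
            within[cid] = 0.0 if sizes[cid] <= 1 else _within_distance(features[mask], exponent)
        vals = np.array(list(within.values()))
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        out[k] = ClusterDiagnostics(
            k=k, cluster_sizes=sizes, within_distances=within, quartiles=(q1, q2, q3)
        )
    return out


def choose_cut(
    diagnostics: dict[int, ClusterDiagnostics],
    quantile_drop: float = 0.1,
) -> int:
    """Pick the smallest cut where the third quartile of within-cluster
    distances has collapsed to <= ``quantile_drop`` of its value at the
    smallest cut (or to 0).  Mirrors choosing the cluster number where the
    distance boxplot's upper quartile approaches zero.
    """
    if not diagnostics:
        raise ValueError("no diagnostics supplied")
    ks = sorted(diagnostics)
    q3_first = diagnostics[ks[0]].quartiles[2]
    threshold = quantile_drop * q3_first
    for k in ks:
        if diagnostics[k].quartiles[2] <= threshold:
            return k
    return ks[-1]
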