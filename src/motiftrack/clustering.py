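"""Behavioral motif discovery by Ward hierarchical clustering.

Clips are clustered on Euclidean distance between their weighted,
normalized feature rows with Ward's minimum-variance criterion, which
suits behavior because the taxonomy of actions is intrinsically
hierarchical and the merge tree can be re-cut without re-fitting. Flat
motif labels come from a dendrogram threshold cut (``thred``, in linkage
distance units of the table): clusters are the connected components left
after removing every merge above the threshold. The inspection reports —
per-cluster feature heatmap, per-feature mutual information with the
labels, inter-cluster similarity, and medoid representatives — are the
quantities a user consults to pick the threshold and name the motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from motiftrack.features import FeatureTable


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history (scipy linkage matrix convention).

    ``merges`` is the (N-1, 4) array of (cluster a, cluster b, linkage
    distance, merged size); with Ward on Euclidean distances the merge
    heights are non-decreasing.
    """

    merges: np.ndarray
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat per-row labels from a threshold cut; labels are contiguous
    1..C, numbered by first appearance in row (temporal) order."""

    labels: np.ndarray
    threshold: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def ward_linkage(table: FeatureTable) -> LinkageTree:
    """Ward minimum-variance linkage on Euclidean distances between rows."""
    X = np.asarray(table.values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite entries")
    Z = hierarchy.linkage(X, method="ward")
    return LinkageTree(merges=Z, n_leaves=X.shape[0])


def _relabel_by_first_appearance(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cut_tree(tree: LinkageTree, thred: float) -> ClusterAssignment:
    """Cut the dendrogram at a linkage-distance threshold.

    Rows joined only through merges above ``thred`` fall into different
    clusters; labels are renumbered by first appearance so reports are
    stable across runs.
    """
    if thred <= 0:
        raise ValueError("thred must be positive")
    raw = hierarchy.fcluster(tree.merges, t=thred, criterion="distance")
    return ClusterAssignment(
        labels=_relabel_by_first_appearance(raw), threshold=thred
    )


def suggest_threshold(tree: LinkageTree, n_clusters: int) -> float:
    """Threshold midway inside the merge-height gap giving ``n_clusters``.

    Mirrors the interactive workflow of eyeballing the dendrogram and
    re-cutting: the cut lands between the (N - C)-th and (N - C + 1)-th
    merge heights.
    """
    N = tree.n_leaves
    if not 1 <= n_clusters <= N:
        raise ValueError(f"n_clusters must be in 1..{N}")
    h = np.sort(tree.heights)
    if n_clusters == 1:
        return float(h[-1]) * 1.01 + 1e-9
    lo = h[N - n_clusters - 1] if N - n_clusters - 1 >= 0 else 0.0
    hi = h[N - n_clusters]
    return float(0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# Inspection reports
# ---------------------------------------------------------------------------

def feature_heatmap(table: FeatureTable, labels: np.ndarray) -> np.ndarray:
    """(clusters, features) matrix of per-cluster means of per-clip feature
    means, on the table's normalized scale."""
    means = table.per_clip_means()
    C = int(labels.max())
    return np.vstack([means[labels == c].mean(axis=0) for c in range(1, C + 1)])


def feature_mutual_information(
    table: FeatureTable,
    labels: np.ndarray,
    n_bins: int = 10,
) -> dict[str, float]:
    """Plug-in mutual information (bits) between each feature and the labels.

    Each feature's per-clip mean is discretized into ``n_bins`` quantile
    bins; MI is estimated from the empirical joint distribution of bin
    index and cluster label, log base 2. Larger MI marks a feature as a
    stronger discriminator of the clustering.
    """
    means = table.per_clip_means()
    out: dict[str, float] = {}
    for j, name in enumerate(table.feature_names):
        x = means[:, j]
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.digitize(x, np.unique(edges))
        out[name] = _plugin_mi(bins, labels)
    return out


def _plugin_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI of two discrete variables, in bits."""
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xv), len(yv)))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def cluster_similarity(table: FeatureTable, labels: np.ndarray) -> np.ndarray:
    """Symmetric (clusters, clusters) similarity in (0, 1].

    Similarity is exp(-d / m) of the Euclidean distance d between cluster
    centroids, scaled by the median inter-centroid distance m; the diagonal
    is exactly 1. Pairs with high similarity are hard to differentiate and
    are candidates for merging.
    """
    C = int(labels.max())
    centroids = np.vstack(
        [table.values[labels == c].mean(axis=0) for c in range(1, C + 1)]
    )
    if C == 1:
        return np.ones((1, 1))
    diff = centroids[:, None, :] - centroids[None, :, :]
    D = np.linalg.norm(diff, axis=2)
    off = D[~np.eye(C, dtype=bool)]
    m = np.median(off)
    if m <= 0:
        return np.ones((C, C))
    S = np.exp(-D / m)
    np.fill_diagonal(S, 1.0)
    return S


def representative_skeleton(
    table: FeatureTable, labels: np.ndarray
) -> dict[int, int]:
    """Medoid clip id per cluster: the member minimizing summed Euclidean
    feature distance to all members of its cluster (ties -> lowest clip id)."""
    out: dict[int, int] = {}
    for c in range(1, int(labels.max()) + 1):
        idx = np.flatnonzero(labels == c)
        X = table.values[idx]
        diff = X[:, None, :] - X[None, :, :]
        cost = np.linalg.norm(diff, axis=2).sum(axis=1)
        order = sorted(
            range(len(idx)),
            key=lambda i: (cost[i], table.clip_ids[idx[i]]),
        )
        out[c] = table.clip_ids[idx[order[0]]]
    return out


@dataclass(frozen=True)
class ClusterReport:
    """Bundle of the inspection computations for one threshold cut."""

    heatmap: np.ndarray
    mutual_information: dict[str, float]
    similarity: np.ndarray
    medoids: dict[int, int]
    timeline: np.ndarray          # labels in temporal (row) order


def cluster_report(
    table: FeatureTable, assignment: ClusterAssignment, n_bins: int = 10
) -> ClusterReport:
    labels = assignment.labels
    return ClusterReport(
        heatmap=feature_heatmap(table, labels),
        mutual_information=feature_mutual_information(table, labels, n_bins),
        similarity=cluster_similarity(table, labels),
        medoids=representative_skeleton(table, labels),
        timeline=labels[np.argsort(np.asarray(table.start_frames, dtype=float),
                                   kind="stable")],
    )
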