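"""Single-omic clustering of samples or features.

K-means is Lloyd's algorithm with k-means++ restarts; correlation distance is
handled by standardizing item vectors (zero mean, unit norm), under which
squared euclidean distance equals 2(1 - Pearson r), so both metrics share one
code path. Hierarchical clustering wraps scipy's agglomerative linkage.
Records carry a parent reference so zoomed re-clusterings keep their history.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.cluster import kmeans_plusplus

from .data_io import Axis, OmicMatrix, Partition

__all__ = [
    "ClusteringRecord",
    "kmeans_partition",
    "hierarchical_partition",
    "zoom_cluster",
    "reorder_by_partitions",
]

Distance = Literal["euclidean", "correlation"]


@dataclass
class ClusteringRecord:
    """One clustering solution: the partition, its objective, and provenance."""

    partition: Partition
    objective: float
    algorithm: str
    params: dict
    seed: int | None = None
    parent: Optional["ClusteringRecord"] = None
    leaf_order: list[str] | None = None
    objective_trace: list[float] = field(default_factory=list)

    def depth(self) -> int:
        d, rec = 0, self.parent
        seen = {id(self)}
        while rec is not None:
            if id(rec) in seen:
                raise ValueError("cyclic parent chain in clustering history")
            seen.add(id(rec))
            d += 1
            rec = rec.parent
        return d


def _item_matrix(m: OmicMatrix, axis: Axis) -> tuple[np.ndarray, list[str]]:
    """Items-as-rows view: samples are columns-as-rows, features are rows."""
    if axis == "samples":
        X, ids = m.values.T, m.sample_ids
    elif axis == "features":
        X, ids = m.values, m.feature_ids
    else:
        raise ValueError(f"axis must be 'samples' or 'features', got {axis!r}")
    if np.isnan(X).any():
        raise ValueError(
            "matrix has missing values on the clustered axis; "
            "filter or impute first (e.g. preprocess.filter_features / pca imputation)")
    return np.ascontiguousarray(X, dtype=float), list(ids)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm (correlation geometry)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Xc / norms


def _prepare(X: np.ndarray, distance: Distance) -> np.ndarray:
    if distance == "correlation":
        return _standardize_rows(X)
    if distance != "euclidean":
        raise ValueError(f"unknown distance {distance!r}")
    return X


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300, tol: float = 1e-9) -> tuple[np.ndarray, float, list[float]]:
    """One Lloyd run with k-means++ init; returns (labels, objective, trace).

    The objective is the within-cluster sum of squared euclidean distances.
    An emptied cluster is re-seeded from the point farthest from its centroid.
    """
    n = X.shape[0]
    centers, _ = kmeans_plusplus(X, n_clusters=k,
                                 random_state=int(rng.integers(2**31 - 1)))
    trace: list[float] = []
    labels = np.zeros(n, dtype=int)
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(n), labels].sum())
        # handle emptied clusters: seed from the globally farthest point
        for c in range(k):
            if not np.any(labels == c):
                far = int(d2[np.arange(n), labels].argmax())
                labels[far] = c
        obj = float(((X - centers[labels]) ** 2).sum())
        trace.append(obj)
        new_centers = np.stack([X[labels == c].mean(axis=0) for c in range(k)])
        if obj >= prev_obj - tol and np.allclose(new_centers, centers):
            break
        centers = new_centers
        prev_obj = obj
    # final assignment against final centers
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    obj = float(d2[np.arange(len(X)), labels].sum())
    trace.append(obj)
    return labels, obj, trace


def kmeans_partition(m: OmicMatrix, axis: Axis, k: int,
                     distance: Distance = "euclidean",
                     n_restarts: int = 10, seed: int = 0,
                     parent: ClusteringRecord | None = None) -> ClusteringRecord:
    """Best-of-restarts Lloyd k-means on samples or features."""
    X, ids = _item_matrix(m, axis)
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n} items")
    Xp = _prepare(X, distance)
    ss = np.random.SeedSequence(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        labels, obj, trace = _lloyd(Xp, k, rng)
        if best is None or obj < best[1]:
            best = (labels, obj, trace)
    assert best is not None
    labels, obj, trace = best
    part = Partition.from_labels(
        axis, ids, labels,
        provenance=f"kmeans(k={k}, distance={distance}, restarts={n_restarts}, seed={seed})")
    return ClusteringRecord(partition=part, objective=obj, algorithm="kmeans",
                            params={"k": k, "distance": distance, "n_restarts": n_restarts},
                            seed=seed, parent=parent, objective_trace=trace)


def hierarchical_partition(m: OmicMatrix, axis: Axis, k: int,
                           distance: Distance = "euclidean",
                           linkage: Literal["average", "complete", "ward"] = "average",
                           parent: ClusteringRecord | None = None) -> ClusteringRecord:
    """Agglomerative clustering cut to k clusters; leaf order is retained."""
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    X, ids = _item_matrix(m, axis)
    n = len(ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n} items")
    metric = "euclidean" if distance == "euclidean" else "correlation"
    D = pdist(X, metric=metric)
    D = np.clip(D, 0.0, None)  # correlation pdist can give tiny negatives
    Z = hierarchy.linkage(D, method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    leaf_idx = hierarchy.leaves_list(Z)
    # objective: sum over clusters of within-cluster pairwise distances
    from scipy.spatial.distance import squareform
    Dsq = squareform(D)
    obj = 0.0
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        obj += float(Dsq[np.ix_(idx, idx)].sum() / 2.0)
    part = Partition.from_labels(
        axis, ids, labels,
        provenance=f"hierarchical(k={k}, distance={distance}, linkage={linkage})")
    return ClusteringRecord(partition=part, objective=obj, algorithm="hierarchical",
                            params={"k": k, "distance": distance, "linkage": linkage},
                            parent=parent, leaf_order=[ids[i] for i in leaf_idx])


def zoom_cluster(m: OmicMatrix, rec: ClusteringRecord, cluster_id: int) -> OmicMatrix:
    """Submatrix restricted to one cluster of a clustering record."""
    part = rec.partition
    members = part.members(cluster_id)  # raises KeyError on unknown cluster
    order = m.sample_ids if part.axis == "samples" else m.feature_ids
    keep = [i for i in order if i in set(members)]
    if part.axis == "samples":
        return m.subset(samples=keep)
    return m.subset(features=keep)


def reorder_by_partitions(m: OmicMatrix,
                          sample_part: Partition | None = None,
                          feature_part: Partition | None = None,
                          ) -> tuple[OmicMatrix, dict[str, list[int]]]:
    """Group columns/rows by cluster index (stable within cluster).

    Returns the reordered matrix and cluster block boundaries per axis: the
    cumulative sizes of clusters 1..k-1, i.e. the indices where separator
    lines would be drawn.
    """
    def ordered(ids: Sequence[str], part: Partition) -> tuple[list[str], list[int]]:
        labels = part.labels_for(ids)
        order = [i for c in range(1, part.k + 1) for i, lab in zip(ids, labels) if lab == c]
        sizes = [int((labels == c).sum()) for c in range(1, part.k + 1)]
        return order, list(np.cumsum(sizes)[:-1])

    boundaries: dict[str, list[int]] = {"samples": [], "features": []}
    samples, features = None, None
    if sample_part is not None:
        if sample_part.axis != "samples":
            raise ValueError("sample_part must have axis='samples'")
        samples, boundaries["samples"] = ordered(m.sample_ids, sample_part)
    if feature_part is not None:
        if feature_part.axis != "features":
            raise ValueError("feature_part must have axis='features'")
        features, boundaries["features"] = ordered(m.feature_ids, feature_part)
    return m.subset(features=features, samples=samples), boundaries
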