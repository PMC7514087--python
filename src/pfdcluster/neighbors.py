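"""Pairwise distances, ordered K-nearest-neighbor sets and the mutual-KNN predicate.

The KNN model underpins every quantity downstream: the common-neighbor sets
ω(i, j) = σ(i) ∩ σ(j), the potential field, the diffusion sums and the
similar-point predicate all read σ(i) from here. Neighbor lists exclude the
point itself and break distance ties by ascending point index, which makes
the whole pipeline reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import PointSet

__all__ = [
    "NeighborModel",
    "pairwise_distances",
    "knn_sets",
    "common_neighbors",
    "is_mutual",
]


@dataclass
class NeighborModel:
    """Ordered K-nearest-neighbor lists σ(i) for every point.

    ``nbr_idx[i]`` holds the K nearest indices to i (self excluded), sorted
    by ascending distance with ties broken by ascending index;
    ``nbr_dist[i]`` holds the matching distances. ``in_sigma`` is the dense
    boolean membership matrix, ``in_sigma[i, j]`` ⟺ j ∈ σ(i).
    """

    K: int
    nbr_idx: np.ndarray
    nbr_dist: np.ndarray

    def __post_init__(self) -> None:
        n = self.nbr_idx.shape[0]
        member = np.zeros((n, n), dtype=bool)
        member[np.arange(n)[:, None], self.nbr_idx] = True
        self.in_sigma = member

    @property
    def n(self) -> int:
        return self.nbr_idx.shape[0]

    def sigma(self, i: int) -> np.ndarray:
        """σ(i): the ordered K nearest neighbors of point i."""
        return self.nbr_idx[i]


def pairwise_distances(P: PointSet | np.ndarray) -> np.ndarray:
    """Full Euclidean distance matrix (exact, O(n²))."""
    X = P.X if isinstance(P, PointSet) else np.asarray(P, dtype=float)
    if np.isnan(X).any():
        raise ValueError("distance computation requires a fully observed matrix")
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(X, metric="euclidean"))


def knn_sets(D: np.ndarray, K: int) -> NeighborModel:
    """Build σ(i) for every point from a distance matrix.

    Ordering within each row is (distance asc, index asc); the point itself
    never appears in its own list.
    """
    n = D.shape[0]
    if not 1 <= K <= n - 1:
        raise ValueError(f"K must satisfy 1 <= K <= n-1 = {n - 1}, got {K}")
    D = D.copy()
    np.fill_diagonal(D, np.inf)  # excludes self even when duplicates exist
    idx = np.arange(n)
    # lexsort: primary key = distance, secondary = point index
    order = np.lexsort((np.broadcast_to(idx, (n, n)), D), axis=1)
    nbr_idx = order[:, :K]
    nbr_dist = np.take_along_axis(D, nbr_idx, axis=1)
    return NeighborModel(K=K, nbr_idx=nbr_idx, nbr_dist=nbr_dist)


def common_neighbors(nm: NeighborModel, i: int, j: int) -> set[int]:
    """ω(i, j) = σ(i) ∩ σ(j)."""
    if i == j:
        raise ValueError("common_neighbors requires i != j")
    return set(nm.nbr_idx[i]) & set(nm.nbr_idx[j])


def is_mutual(nm: NeighborModel, i: int, j: int) -> bool:
    """True iff i and j are K-nearest neighbors of each other."""
    if i == j:
        raise ValueError("is_mutual requires i != j")
    return bool(nm.in_sigma[i, j] and nm.in_sigma[j, i])
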