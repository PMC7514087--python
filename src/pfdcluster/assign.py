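"""Center selection and the two-step label allocation of PFD-DPC.

Step 1 propagates labels from the cluster centers along *similar-point*
edges: a pair (i, j) is similar when it shares strictly more than
⌈(K+1)/2⌉ common K-nearest neighbors. Propagation is a FIFO breadth-first
search seeded with the centers, so a contested point goes to the first
cluster that reaches it.

Step 2 sweeps the remaining points in descending density and assigns each by
majority vote among its K' nearest neighbors' labels, growing K' one at a
time whenever the vote is empty or tied.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .density import PFDParams, PeakStats, peak_stats
from .io import PointSet, impute_mean, minmax_normalize
from .neighbors import NeighborModel, knn_sets, pairwise_distances

__all__ = [
    "ClusterAssignment",
    "similar_threshold",
    "select_centers",
    "is_similar",
    "allocate_similar",
    "allocate_knn_vote",
    "cluster",
]

PHASE_CENTER = "center"
PHASE_SIMILAR = "similar_bfs"
PHASE_VOTE = "knn_vote"


@dataclass
class ClusterAssignment:
    """Final labels, the m center indices and the allocation phase per point."""

    labels: np.ndarray
    centers: np.ndarray
    phase: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def similar_threshold(K: int) -> int:
    """⌈(K+1)/2⌉ — the common-neighbor count a similar pair must exceed."""
    return math.ceil((K + 1) / 2)


def select_centers(gamma: np.ndarray, m: int) -> np.ndarray:
    """The m indices with largest γ, ties by ascending index.

    The returned order is descending γ; position c becomes cluster label c.
    """
    gamma = np.asarray(gamma, dtype=float)
    n = len(gamma)
    if not 1 <= m <= n:
        raise ValueError(f"cluster count m must satisfy 1 <= m <= n = {n}, got {m}")
    order = np.lexsort((np.arange(n), -gamma))
    return order[:m]


def is_similar(nm: NeighborModel, i: int, j: int, K: int | None = None) -> bool:
    """Similar-point predicate: |ω(i, j)| > ⌈(K+1)/2⌉."""
    if i == j:
        raise ValueError("is_similar requires i != j")
    if K is None:
        K = nm.K
    count = int((nm.in_sigma[i] & nm.in_sigma[j]).sum())
    return count > similar_threshold(K)


def allocate_similar(
    nm: NeighborModel, centers: np.ndarray, K: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: FIFO BFS from the centers along similar-point edges.

    Returns partial labels (−1 where unallocated) and phase tags. Contested
    points keep the label of the first element of the queue that claimed
    them (first-claimant-wins).
    """
    if K is None:
        K = nm.K
    n = nm.n
    thr = similar_threshold(K)
    labels = np.full(n, -1, dtype=int)
    phase = np.full(n, "", dtype="<U11")
    queue: deque[int] = deque()
    for c, ci in enumerate(centers):
        labels[ci] = c
        phase[ci] = PHASE_CENTER
        queue.append(int(ci))
    while queue:
        e = queue.popleft()
        unalloc = np.flatnonzero(labels < 0)
        if unalloc.size == 0:
            break
        counts = nm.in_sigma[unalloc] @ nm.in_sigma[e].astype(int)
        for j in unalloc[counts > thr]:  # unalloc is ascending-index already
            labels[j] = labels[e]
            phase[j] = PHASE_SIMILAR
            queue.append(int(j))
    return labels, phase


def allocate_knn_vote(
    nm: NeighborModel,
    D: np.ndarray,
    labels: np.ndarray,
    rho: np.ndarray,
    K: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 2: majority vote among the K' nearest neighbors, in rounds.

    Each round sweeps the unallocated points in descending ρ (ties by
    ascending index) and assigns every point whose K' nearest neighbors
    contain a unique plurality of already-assigned labels — votes see every
    label assigned so far, including earlier assignments of the same round,
    so labels spread outward from the labeled regions. A point with no
    labeled neighbor, or a tied vote, simply waits for the next round; only
    when a whole round assigns nothing is the window K' enlarged by one.
    This keeps every vote as local as the labeling front allows — growing
    K' per point instead would let points deep inside unlabeled territory
    poll far-away regions and import their labels. If even K' = n−1 cannot
    produce a unique plurality the point takes the label of its nearest
    labeled point.
    """
    if K is None:
        K = nm.K
    labels = labels.copy()
    if not (labels >= 0).any():
        raise ValueError("KNN voting needs at least one labeled point")
    n = len(labels)
    phase = np.full(n, "", dtype="<U11")
    idx = np.arange(n)
    Dw = D.copy()
    np.fill_diagonal(Dw, np.inf)
    # full neighbor ranking per point, (distance asc, index asc)
    ranking = np.lexsort((np.broadcast_to(idx, (n, n)), Dw), axis=1)[:, : n - 1]

    Kp = K
    while (labels < 0).any() and Kp <= n - 1:
        pending = np.flatnonzero(labels < 0)
        pending = pending[np.lexsort((pending, -rho[pending]))]
        assigned_any = False
        for i in pending:
            votes = labels[ranking[i, :Kp]]
            votes = votes[votes >= 0]
            if votes.size == 0:
                continue
            counts = np.bincount(votes)
            winners = np.flatnonzero(counts == counts.max())
            if len(winners) == 1:
                labels[i] = int(winners[0])
                phase[i] = PHASE_VOTE
                assigned_any = True
        if not assigned_any:
            Kp += 1
    for i in np.flatnonzero(labels < 0):  # exhausted K': nearest labeled point
        labeled = np.flatnonzero(labels >= 0)
        best = labeled[np.lexsort((labeled, D[i, labeled]))[0]]
        labels[i] = int(labels[best])
        phase[i] = PHASE_VOTE
    return labels, phase


def cluster(
    P: PointSet,
    params: PFDParams,
    m: int,
    normalize: bool = True,
) -> tuple[ClusterAssignment, PeakStats]:
    """Run the full PFD-DPC pipeline on a point set.

    preprocess → distance matrix → θ → Θ → ρ → δ/γ → m top-γ centers →
    similar-point BFS → KNN majority vote. Deterministic for fixed input.

    Parameters
    ----------
    P:
        Input points; missing cells are mean-imputed when ``normalize``.
    params:
        PFD similarity parameters (K, diffusion layers k, ...).
    m:
        Number of clusters; the m largest-γ points become the centers.
    normalize:
        Apply mean imputation and per-feature min–max scaling first
        (the standard preprocessing for the benchmark comparisons).
    """
    n = P.n
    if not 1 <= m <= n:
        raise ValueError(f"cluster count m must satisfy 1 <= m <= n = {n}, got {m}")
    if params.K >= n:
        raise ValueError(f"K = {params.K} must be < n = {n}")
    if normalize:
        if P.has_missing:
            P, _ = impute_mean(P)
        P, _ = minmax_normalize(P)
    elif P.has_missing:
        raise ValueError("input has missing cells; impute first or set normalize=True")

    D = pairwise_distances(P)
    nm = knn_sets(D, params.K)
    _, stats = peak_stats(nm, D, params)
    centers = select_centers(stats.gamma, m)
    labels, phase1 = allocate_similar(nm, centers, params.K)
    if (labels < 0).any():
        labels, phase2 = allocate_knn_vote(nm, D, labels, stats.rho, params.K)
        phase1[phase2 != ""] = phase2[phase2 != ""]
    assignment = ClusterAssignment(labels=labels, centers=centers, phase=phase1)
    return assignment, stats
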