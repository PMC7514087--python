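"""Potential-field-diffusion (PFD) similarity and the density peak statistics.

The core idea: treat each point as a unit mass whose "potential" is felt by
the common K-nearest neighbors it shares with another point. For a mutual
KNN pair (i, j) with common-neighbor set ω(i, j),

    θ(i, j) = |ω(i, j)|² / Σ_{p∈ω(i,j)} (d_ip² + d_jp²)

measures how tightly the pair is embedded in shared structure. The field is
then *diffused* k layers through the KNN graph: S_k(i) sums the squared edge
lengths of every directed length-k neighbor path starting at i
(i → x₁ → … → x_k with x₁∈σ(i), x_{t+1}∈σ(x_t); paths may revisit nodes).
The PFD similarity is the product

    Θ(i, j) = θ(i, j) · S_k(i)        (0 for non-mutual pairs),

so points sitting in sparse regions — whose neighbor paths are long — get
their similarity boosted and low-density clusters are not drowned out by
dense ones. Local density ρ_i sums the K largest Θ(i, ·), δ_i is the
distance to the nearest strictly denser point, and γ_i = ρ_i·δ_i ranks
cluster-center candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .neighbors import NeighborModel

__all__ = [
    "PFDParams",
    "SimilarityField",
    "PeakStats",
    "potential_field",
    "theta_matrix",
    "diffusion_sum",
    "diffusion_sums",
    "pfd_similarity",
    "similarity_field",
    "local_density",
    "nearest_denser",
    "decision_values",
    "peak_stats",
    "export_decision_graph",
]

#: Range outside which the neighbor count K is unusual for this method
#: (below 4 the similar-point threshold degenerates and allocation can stall).
RECOMMENDED_K_RANGE = (4, 50)
#: Diffusion layers beyond 3 buy little and cost K^k path mass per layer.
RECOMMENDED_k_RANGE = (1, 3)


@dataclass
class PFDParams:
    """Parameters of the PFD similarity.

    Parameters
    ----------
    K:
        Neighbor count of the KNN graph (also the cardinality of the top-Θ
        set defining ρ). Typical working range 4–50.
    k:
        Number of diffusion layers (length of the neighbor paths in S_k).
        Typical working range 1–3.
    eps_floor:
        Lower bound on the θ denominator, guarding duplicate points whose
        summed squared distances vanish.
    diffusion:
        When False the diffusion factor S_k is replaced by 1, i.e. Θ = θ.
        This is the no-diffusion ablation variant.
    symmetrize:
        When True, Θ is replaced by (Θ(i,j) + Θ(j,i)) / 2. Off by default:
        the definition reads the diffusion sum from i only.
    """

    K: int
    k: int = 1
    eps_floor: float = 1e-12
    diffusion: bool = True
    symmetrize: bool = False

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.eps_floor <= 0:
            raise ValueError("eps_floor must be > 0")


@dataclass
class SimilarityField:
    """θ, diffusion sums S_k and Θ over all pairs (dense storage).

    ``theta`` and ``Theta`` are n×n with zeros wherever the pair is not
    mutual-KNN; each has at most K nonzero entries per row.
    """

    theta: np.ndarray
    S: np.ndarray
    Theta: np.ndarray


@dataclass
class PeakStats:
    """Per-point density peak statistics ρ, δ, parent and γ = ρ·δ.

    ``parent[i]`` is the nearest strictly denser point (the arg-min of δ),
    or −1 for density maxima, which take δ = max of the other points' δ.
    """

    rho: np.ndarray
    delta: np.ndarray
    parent: np.ndarray
    gamma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gamma = self.rho * self.delta


def potential_field(
    nm: NeighborModel, D: np.ndarray, i: int, j: int, eps_floor: float = 1e-12
) -> float:
    """θ(i, j): cumulative common-neighbor potential of a mutual-KNN pair.

    Zero when i and j are not mutual K-nearest neighbors or share no
    common neighbor.
    """
    if i == j:
        raise ValueError("potential_field requires i != j")
    if not (nm.in_sigma[i, j] and nm.in_sigma[j, i]):
        return 0.0
    common = nm.in_sigma[i] & nm.in_sigma[j]
    c = int(common.sum())
    if c == 0:
        return 0.0
    denom = float((D[i, common] ** 2 + D[j, common] ** 2).sum())
    return c * c / max(denom, eps_floor)


def theta_matrix(nm: NeighborModel, D: np.ndarray, eps_floor: float = 1e-12) -> np.ndarray:
    """Dense θ over all pairs; symmetric, zero off the mutual-KNN graph."""
    n = nm.n
    theta = np.zeros((n, n))
    D2 = D * D
    mutual = nm.in_sigma & nm.in_sigma.T
    for i in range(n):
        for j in nm.nbr_idx[i]:
            if j <= i or not mutual[i, j]:
                continue
            common = nm.in_sigma[i] & nm.in_sigma[j]
            c = int(common.sum())
            if c == 0:
                continue
            denom = float((D2[i, common] + D2[j, common]).sum())
            theta[i, j] = theta[j, i] = c * c / max(denom, eps_floor)
    return theta


def diffusion_sums(nm: NeighborModel, D: np.ndarray, k: int) -> np.ndarray:
    """S_k(i) for every i: total squared-length mass of all K^k neighbor paths.

    Computed by the recursion
        S_1(i) = Σ_{m∈σ(i)} d_im²
        S_t(i) = Σ_{m∈σ(i)} (d_im² · K^{t−1} + S_{t−1}(m)),
    which is exact because each first edge (i, m) is shared by the K^{t−1}
    continuations through m.
    """
    if k < 1:
        raise ValueError("diffusion layers k must be >= 1")
    first_edge = (nm.nbr_dist**2).sum(axis=1)  # S_1
    S = first_edge.copy()
    for t in range(2, k + 1):
        S = first_edge * nm.K ** (t - 1) + S[nm.nbr_idx].sum(axis=1)
    return S


def diffusion_sum(nm: NeighborModel, D: np.ndarray, i: int, k: int) -> float:
    """S_k for a single point (see :func:`diffusion_sums`)."""
    return float(diffusion_sums(nm, D, k)[i])


def pfd_similarity(
    nm: NeighborModel, D: np.ndarray, i: int, j: int, params: PFDParams
) -> float:
    """Θ(i, j) = θ(i, j) · S_k(i) for mutual pairs, else 0."""
    th = potential_field(nm, D, i, j, params.eps_floor)
    if th == 0.0:
        return 0.0
    if not params.diffusion:
        return th
    return th * diffusion_sum(nm, D, i, params.k)


def similarity_field(nm: NeighborModel, D: np.ndarray, params: PFDParams) -> SimilarityField:
    """Compute θ, S_k and Θ over the whole dataset."""
    theta = theta_matrix(nm, D, params.eps_floor)
    S = diffusion_sums(nm, D, params.k)
    Theta = theta * S[:, None] if params.diffusion else theta.copy()
    if params.symmetrize:
        Theta = 0.5 * (Theta + Theta.T)
    return SimilarityField(theta=theta, S=S, Theta=Theta)


def local_density(sf: SimilarityField, K: int) -> np.ndarray:
    """ρ_i: sum of the K largest Θ(i, ·) (ties by ascending index).

    Θ(i, ·) has at most K nonzero entries (one per mutual neighbor in σ(i)),
    so this equals the sum of all nonzero PFD similarities of i; the
    explicit top-K selection keeps the definition honest for any field.
    """
    n = sf.Theta.shape[0]
    idx = np.arange(n)
    rho = np.empty(n)
    for i in range(n):
        row = sf.Theta[i]
        order = np.lexsort((idx, -row))
        top = order[order != i][:K]
        rho[i] = row[top].sum()
    return rho


def nearest_denser(rho: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """δ_i = min distance to a strictly denser point; parent = the arg-min.

    Density maxima (no strictly denser point) get parent −1 and
    δ = max over the other points' δ values; when every point is a maximum
    (all densities equal) δ falls back to the maximum pairwise distance.
    """
    n = len(rho)
    delta = np.zeros(n)
    parent = np.full(n, -1, dtype=int)
    if n == 1:
        return delta, parent
    is_max = rho >= rho.max()
    for i in np.flatnonzero(~is_max):
        denser = rho > rho[i]
        cand = np.flatnonzero(denser)
        dists = D[i, cand]
        best = cand[np.lexsort((cand, dists))[0]]
        delta[i] = D[i, best]
        parent[i] = best
    maxima = np.flatnonzero(is_max)
    if len(maxima) < n:
        delta[maxima] = delta[~is_max].max()
    else:
        delta[:] = D[~np.eye(n, dtype=bool)].max()
    return delta, parent


def decision_values(rho: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """γ_i = ρ_i · δ_i, the cluster-center decision value."""
    rho = np.asarray(rho, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if rho.shape != delta.shape:
        raise ValueError("rho and delta must have the same length")
    return rho * delta


def peak_stats(nm: NeighborModel, D: np.ndarray, params: PFDParams) -> tuple[SimilarityField, PeakStats]:
    """End-to-end: similarity field → ρ → δ/parent → γ."""
    sf = similarity_field(nm, D, params)
    rho = local_density(sf, params.K)
    delta, parent = nearest_denser(rho, D)
    return sf, PeakStats(rho=rho, delta=delta, parent=parent)


def export_decision_graph(stats: PeakStats, path: str | Path) -> None:
    """Write (index, ρ, δ, γ) as TSV, γ-descending, γ-ties by ascending index."""
    n = len(stats.rho)
    order = np.lexsort((np.arange(n), -stats.gamma))
    lines = ["#index\trho\tdelta\tgamma"]
    for i in order:
        lines.append(
            f"{i}\t{float(stats.rho[i])!r}\t{float(stats.delta[i])!r}\t{float(stats.gamma[i])!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
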