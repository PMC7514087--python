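"""Baseline density peak clustering (DPC).

The classic algorithm: local density ρ from a cutoff or Gaussian kernel at
bandwidth dc, distance δ to the nearest strictly denser point, centers by
γ = ρ·δ, single-pass allocation in descending density (each point inherits
its nearest-denser parent's label), and the border/halo rule that flags
points below the maximum border density of their cluster as noise.

Kept here both as a comparison baseline and because PFD-DPC reuses its
δ/γ machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assign import select_centers
from .density import decision_values, nearest_denser
from .io import PointSet, impute_mean, minmax_normalize
from .neighbors import pairwise_distances

__all__ = [
    "DPCParams",
    "DPCResult",
    "chi",
    "dc_from_percent",
    "dpc_density",
    "dpc_delta",
    "dpc_gamma",
    "dpc_assign",
    "dpc_halo",
    "dpc_cluster",
]


@dataclass
class DPCParams:
    """Cutoff-distance configuration.

    ``dc_mode="percent"`` reads ``dc_value`` as a percentile position in the
    sorted list of pairwise distances (the usual "neighbors ≈ 1–2% of the
    sample" heuristic); ``"absolute"`` uses it as a distance directly.
    """

    dc_value: float
    dc_mode: str = "percent"
    kernel: str = "cutoff"

    def __post_init__(self) -> None:
        if self.dc_mode not in ("percent", "absolute"):
            raise ValueError(f"unknown dc_mode {self.dc_mode!r}")
        if self.kernel not in ("cutoff", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.dc_value <= 0:
            raise ValueError("dc_value must be > 0")
        if self.dc_mode == "percent" and not 0 < self.dc_value < 100:
            raise ValueError("percent dc_value must lie in (0, 100)")


@dataclass
class DPCResult:
    labels: np.ndarray
    halo: np.ndarray
    rho: np.ndarray
    delta: np.ndarray
    centers: np.ndarray
    gamma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gamma = self.rho * self.delta


def chi(x: float) -> int:
    """Indicator of the cutoff kernel: 1 for x < 0, 0 for x >= 0."""
    return 1 if x < 0 else 0


def dc_from_percent(D: np.ndarray, p: float) -> float:
    """Resolve a percent dc to an absolute distance.

    Takes the value at 1-based position round(p/100 · M) (clamped to
    [1, M]) in the ascending sorted list of the M = n(n−1)/2 pairwise
    distances.
    """
    n = D.shape[0]
    if n < 2:
        raise ValueError("dc_from_percent needs at least two points")
    if not 0 < p < 100:
        raise ValueError("percent must lie in (0, 100)")
    pair = np.sort(D[np.triu_indices(n, k=1)])
    M = len(pair)
    pos = int(np.clip(round(p / 100 * M), 1, M))
    return float(pair[pos - 1])


def resolve_dc(D: np.ndarray, params: DPCParams) -> float:
    if params.dc_mode == "absolute":
        return params.dc_value
    return dc_from_percent(D, params.dc_value)


def dpc_density(D: np.ndarray, params: DPCParams, dc: float | None = None) -> np.ndarray:
    """ρ by cutoff count (d_ij < dc, strict) or Gaussian kernel exp(−(d/dc)²)."""
    if dc is None:
        dc = resolve_dc(D, params)
    off = ~np.eye(D.shape[0], dtype=bool)
    if params.kernel == "cutoff":
        return ((D < dc) & off).sum(axis=1).astype(float)
    return (np.exp(-((D / dc) ** 2)) * off).sum(axis=1)


def dpc_delta(rho: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """δ and nearest-denser parent; same contract as the PFD version."""
    return nearest_denser(rho, D)


def dpc_gamma(rho: np.ndarray, delta: np.ndarray) -> np.ndarray:
    return decision_values(rho, delta)


def dpc_assign(
    rho: np.ndarray, parent: np.ndarray, centers: np.ndarray, D: np.ndarray | None = None
) -> np.ndarray:
    """Descending-density sweep: each non-center inherits its parent's label.

    Processing in descending ρ guarantees the parent is labeled first. A
    non-center density maximum (parent −1) falls back to its nearest center,
    which needs the distance matrix.
    """
    n = len(rho)
    labels = np.full(n, -1, dtype=int)
    for c, ci in enumerate(centers):
        labels[ci] = c
    order = np.lexsort((np.arange(n), -rho))
    for i in order:
        if labels[i] >= 0:
            continue
        if parent[i] >= 0 and labels[parent[i]] >= 0:
            labels[i] = labels[parent[i]]
        else:
            if D is None:
                raise ValueError(
                    "point with no denser parent is not a center; need D for fallback"
                )
            centers_arr = np.asarray(centers)
            best = centers_arr[np.lexsort((centers_arr, D[i, centers_arr]))[0]]
            labels[i] = labels[best]
    return labels


def dpc_halo(labels: np.ndarray, rho: np.ndarray, D: np.ndarray, dc: float) -> np.ndarray:
    """Flag halo (noise) points.

    Per cluster: the border set is the points lying within dc of some point
    of another cluster; the cluster's core threshold is the maximum border
    density (0 when the border is empty); members with ρ strictly below the
    threshold are halo.
    """
    n = len(labels)
    halo = np.zeros(n, dtype=bool)
    near = (D < dc) & ~np.eye(n, dtype=bool)
    other = labels[None, :] != labels[:, None]
    is_border = (near & other).any(axis=1)
    for c in np.unique(labels):
        members = labels == c
        border = members & is_border
        if not border.any():
            continue
        threshold = rho[border].max()
        halo[members & (rho < threshold)] = True
    return halo


def dpc_cluster(
    P: PointSet,
    params: DPCParams,
    m: int,
    normalize: bool = True,
    compute_halo: bool = True,
) -> DPCResult:
    """Full baseline DPC run: ρ → δ/γ → m top-γ centers → sweep → halo."""
    if not 1 <= m <= P.n:
        raise ValueError(f"cluster count m must satisfy 1 <= m <= n = {P.n}, got {m}")
    if normalize:
        if P.has_missing:
            P, _ = impute_mean(P)
        P, _ = minmax_normalize(P)
    D = pairwise_distances(P)
    dc = resolve_dc(D, params)
    rho = dpc_density(D, params, dc)
    delta, parent = dpc_delta(rho, D)
    gamma = dpc_gamma(rho, delta)
    centers = select_centers(gamma, m)
    labels = dpc_assign(rho, parent, centers, D)
    halo = dpc_halo(labels, rho, D, dc) if compute_halo else np.zeros(P.n, dtype=bool)
    return DPCResult(labels=labels, halo=halo, rho=rho, delta=delta, centers=centers)
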