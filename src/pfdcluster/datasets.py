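"""Seeded synthetic stand-ins for the classic clustering shape benchmarks.

Each generator emulates the structure of a well-known benchmark at its
published size, with ground-truth labels and full determinism (same spec →
byte-identical output):

- ``jain_moons``     — two crescents of unequal density (Jain-like, n=373)
- ``spiral3``        — three interleaved Archimedean spiral arms (n=312)
- ``ring_blobs``     — a C-shaped ring enclosing two Gaussian blobs
                       (Pathbased-like, n=300)
- ``gauss_grid``     — 15 small isotropic Gaussians on a 5×3 grid
                       (R15-like, n=600)
- ``aggregation7``   — 7 Gaussian blobs of uneven sizes (n=788)
- ``highdim_blobs``  — 16 well-separated Gaussians in 512 dimensions
                       (DIM512-like, n=1024)

The generators reproduce the *character* of the originals (density
imbalance, winding arms, ring-around-blobs topology), not their exact
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PointSet

__all__ = ["FixtureSpec", "generate", "SHAPES"]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic benchmark.

    ``noise`` scales the shape's default jitter (1.0 = default); ``shuffle``
    permutes point order (for order-insensitivity experiments). ``d`` is
    honored by ``highdim_blobs`` only; the plane shapes are 2-D.
    """

    shape: str
    n: int | None = None
    d: int | None = None
    seed: int = 0
    noise: float = 1.0
    shuffle: bool = False
    n_clusters: int | None = field(default=None)


def _split_sizes(n: int, weights: np.ndarray) -> np.ndarray:
    """Partition n into len(weights) parts proportional to weights."""
    raw = weights / weights.sum() * n
    sizes = np.floor(raw).astype(int)
    # distribute the remainder to the largest fractional parts
    for i in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    return sizes


def _arc_band(
    n: int,
    rows: int,
    r0: float,
    width: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
    jitter: float,
) -> np.ndarray:
    """n points on a circular band, jittered-grid sampled in (angle, radius).

    The hand-digitized shape benchmarks are locally evenly spread (no two
    points nearly coincide), which iid sampling does not reproduce; a
    jittered grid matches that character and keeps the density fields smooth.
    """
    rows = min(rows, n)
    rr = np.linspace(r0 - width / 2, r0 + width / 2, rows)
    dr = width / max(rows - 1, 1)
    base, extra = divmod(n, rows)
    chunks = []
    for row in range(rows):
        cols = base + (1 if row < extra else 0)
        if cols == 0:
            continue
        tt = np.linspace(lo, hi, cols, endpoint=False)
        dt = (hi - lo) / cols
        t = tt + rng.uniform(0.0, dt, cols) * jitter
        r = rr[row] + rng.uniform(-dr / 2, dr / 2, cols) * jitter
        chunks.append(np.c_[r * np.cos(t), r * np.sin(t)])
    return np.vstack(chunks)


def _jain_moons(n: int, rng: np.random.Generator, noise: float) -> tuple[np.ndarray, np.ndarray]:
    # two concentric crescent bands; sparse outer : dense inner ≈ 1 : 2 in
    # point count over a similar area, so the outer moon is the low-density one
    n_sparse = n // 3
    n_dense = n - n_sparse
    dense = _arc_band(n_dense, 5, 1.0, 0.2, 0.05 * np.pi, 0.95 * np.pi, rng, noise)
    sparse = _arc_band(n_sparse, 3, 2.0, 0.2, 0.10 * np.pi, 0.90 * np.pi, rng, noise)
    X = np.vstack([dense, sparse])
    y = np.r_[np.zeros(n_dense, dtype=int), np.ones(n_sparse, dtype=int)]
    return X, y


def _spiral3(n: int, rng: np.random.Generator, noise: float) -> tuple[np.ndarray, np.ndarray]:
    # three Archimedean arms r = b·t, points evenly spaced in *arc length*
    # (s ∝ t² for this curve) with jittered positions along the arm
    sizes = _split_sizes(n, np.ones(3))
    b, lo, hi = 0.18, 0.5 * np.pi, 2.5 * np.pi
    Xs, ys = [], []
    for arm, sz in enumerate(sizes):
        s = np.linspace(lo**2, hi**2, sz)
        t = np.sqrt(s)
        t = t + rng.uniform(0.0, (hi - lo) / sz, sz) * 0.5 * noise
        r = b * t
        phi = 2.0 * np.pi * arm / 3.0
        Xs.append(np.c_[r * np.cos(t + phi), r * np.sin(t + phi)])
        ys.append(np.full(sz, arm, dtype=int))
    return np.vstack(Xs), np.concatenate(ys)


def _ring_blobs(n: int, rng: np.random.Generator, noise: float) -> tuple[np.ndarray, np.ndarray]:
    sizes = _split_sizes(n, np.array([110.0, 95.0, 95.0]))
    n_ring, n_b1, n_b2 = sizes
    # C-shaped ring (300° of arc, opening at the bottom) sampled evenly
    # along the arc with jitter, enclosing two Gaussian blobs
    lo, hi = np.deg2rad(-60.0), np.deg2rad(240.0)
    t = np.linspace(lo, hi, n_ring) + rng.uniform(0.0, (hi - lo) / n_ring, n_ring) * 0.5 * noise
    r = 1.0 + rng.normal(0.0, 0.02 * noise, n_ring)
    ring = np.c_[r * np.cos(t), r * np.sin(t)]
    b1 = np.array([-0.38, -0.18]) + rng.normal(0.0, 0.09 * noise, (n_b1, 2))
    b2 = np.array([0.38, -0.18]) + rng.normal(0.0, 0.09 * noise, (n_b2, 2))
    X = np.vstack([ring, b1, b2])
    y = np.r_[
        np.zeros(n_ring, dtype=int),
        np.ones(n_b1, dtype=int),
        np.full(n_b2, 2, dtype=int),
    ]
    return X, y


def _gauss_grid(n: int, rng: np.random.Generator, noise: float) -> tuple[np.ndarray, np.ndarray]:
    centers = np.array([(x, y) for y in range(3) for x in range(5)], dtype=float)
    sizes = _split_sizes(n, np.ones(15))
    Xs, ys = [], []
    for c, sz in enumerate(sizes):
        Xs.append(centers[c] + rng.normal(0.0, 0.05 * noise, (sz, 2)))
        ys.append(np.full(sz, c, dtype=int))
    return np.vstack(Xs), np.concatenate(ys)


def _aggregation7(n: int, rng: np.random.Generator, noise: float) -> tuple[np.ndarray, np.ndarray]:
    # uneven cluster sizes in the spirit of the 7-blob aggregation benchmark
    weights = np.array([45.0, 170.0, 102.0, 273.0, 34.0, 130.0, 34.0])
    centers = np.array(
        [
            (0.8, 1.0),
            (2.8, 3.6),
            (5.6, 3.4),
            (8.4, 3.6),
            (0.8, 3.8),
            (4.2, 1.0),
            (7.0, 1.0),
        ]
    )
    sizes = _split_sizes(n, weights)
    Xs, ys = [], []
    for c, sz in enumerate(sizes):
        Xs.append(centers[c] + rng.normal(0.0, 0.28 * noise, (sz, 2)))
        ys.append(np.full(sz, c, dtype=int))
    return np.vstack(Xs), np.concatenate(ys)


def _highdim_blobs(
    n: int, d: int, rng: np.random.Generator, noise: float, n_clusters: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    # center scale 10 × within-cluster σ per coordinate; in d dimensions the
    # inter-center distances concentrate near 10·sqrt(2d) ≫ within-cluster spread
    centers = rng.normal(0.0, 10.0, (n_clusters, d))
    sizes = _split_sizes(n, np.ones(n_clusters))
    Xs, ys = [], []
    for c, sz in enumerate(sizes):
        Xs.append(centers[c] + rng.normal(0.0, 1.0 * noise, (sz, d)))
        ys.append(np.full(sz, c, dtype=int))
    return np.vstack(Xs), np.concatenate(ys)


_DEFAULT_N = {
    "jain_moons": 373,
    "spiral3": 312,
    "ring_blobs": 300,
    "gauss_grid": 600,
    "aggregation7": 788,
    "highdim_blobs": 1024,
}

SHAPES = tuple(_DEFAULT_N)


def generate(spec: FixtureSpec) -> PointSet:
    """Materialize a :class:`FixtureSpec` into a labeled :class:`PointSet`."""
    if spec.shape not in _DEFAULT_N:
        raise ValueError(f"unknown shape {spec.shape!r}; choose from {SHAPES}")
    n = spec.n if spec.n is not None else _DEFAULT_N[spec.shape]
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "jain_moons":
        X, y = _jain_moons(n, rng, spec.noise)
    elif spec.shape == "spiral3":
        X, y = _spiral3(n, rng, spec.noise)
    elif spec.shape == "ring_blobs":
        X, y = _ring_blobs(n, rng, spec.noise)
    elif spec.shape == "gauss_grid":
        X, y = _gauss_grid(n, rng, spec.noise)
    elif spec.shape == "aggregation7":
        X, y = _aggregation7(n, rng, spec.noise)
    else:
        d = spec.d if spec.d is not None else 512
        m = spec.n_clusters if spec.n_clusters is not None else 16
        X, y = _highdim_blobs(n, d, rng, spec.noise, m)
    if spec.shuffle:
        perm = rng.permutation(len(X))
        X, y = X[perm], y[perm]
    return PointSet(X=X, y_true=y, source=f"synthetic:{spec.shape}(n={n},seed={spec.seed})")
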