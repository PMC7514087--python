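import numpy as np
import pytest

from pfdcluster import PFDParams, PointSet, knn_sets, pairwise_distances


@pytest.fixture(scope="session")
def line4():
    """Four collinear points at 0, 1, 3, 7 with K=2 — the worked micro-example."""
    P = PointSet(np.array([[0.0], [1.0], [3.0], [7.0]]))
    D = pairwise_distances(P)
    nm = knn_sets(D, 2)
    return P, D, nm


@pytest.fixture(scope="session")
def blobs60():
    """Two well-separated isotropic Gaussian blobs, 30 points each."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.3, (30, 2))
    b = np.array([8.0, 8.0]) + rng.normal(0.0, 0.3, (30, 2))
    X = np.vstack([a, b])
    y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
    return PointSet(X, y_true=y)


def enumerate_diffusion_sum(nm, D, i, k):
    """Brute-force oracle for S_k(i): enumerate all K^k neighbor paths
    i → x1 → ... → xk and sum the squared edge lengths along each path."""
    import itertools

    total = 0.0
    frontier = [(i, 0.0)]
    for _ in range(k):
        nxt = []
        for node, acc in frontier:
            for m in nm.nbr_idx[node]:
                nxt.append((int(m), acc + D[node, m] ** 2))
        frontier = nxt
    return sum(acc for _, acc in frontier)


@pytest.fixture
def diffusion_oracle():
    return enumerate_diffusion_sum


def random_instance(rng, n=None, d=2, K=None):
    """Small random point set + neighbor model for property tests."""
    n = n or int(rng.integers(4, 13))
    K = K or int(rng.integers(1, min(4, n - 1) + 1))
    X = rng.normal(0.0, 1.0, (n, d))
    P = PointSet(X)
    D = pairwise_distances(P)
    return P, D, knn_sets(D, K)
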