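import numpy as np
import pytest

from pfdcluster import (
    PFDParams,
    PointSet,
    decision_values,
    diffusion_sum,
    knn_sets,
    local_density,
    nearest_denser,
    pairwise_distances,
    peak_stats,
    pfd_similarity,
    potential_field,
    similarity_field,
)
from pfdcluster.density import diffusion_sums, export_decision_graph
from conftest import enumerate_diffusion_sum, random_instance


class TestPotentialField:
    def test_non_mutual_pair_zero(self, line4):
        _, D, nm = line4
        assert potential_field(nm, D, 0, 3) == 0.0

    def test_line_pair_01(self, line4):
        _, D, nm = line4
        assert potential_field(nm, D, 0, 1) == pytest.approx(1 / 13)

    def test_line_pair_02(self, line4):
        _, D, nm = line4
        assert potential_field(nm, D, 0, 2) == pytest.approx(0.2)

    def test_symmetry(self, line4):
        _, D, nm = line4
        assert potential_field(nm, D, 1, 0) == potential_field(nm, D, 0, 1)

    def test_duplicate_points_guarded_by_floor(self):
        X = np.array([[0.0], [0.0], [0.0], [5.0]])
        D = pairwise_distances(PointSet(X))
        nm = knn_sets(D, 2)
        th = potential_field(nm, D, 0, 1, eps_floor=1e-12)
        assert np.isfinite(th) and th > 0


class TestDiffusionSum:
    def test_one_layer(self, line4):
        _, D, nm = line4
        assert diffusion_sum(nm, D, 0, 1) == pytest.approx(10.0)

    def test_two_layers_three_points(self):
        X = np.array([[0.0], [1.0], [3.0]])
        D = pairwise_distances(PointSet(X))
        nm = knn_sets(D, 1)
        # single path 0 -> 1 -> 0 contributes 1 + 1
        assert diffusion_sum(nm, D, 0, 2) == pytest.approx(2.0)

    def test_two_layers_line(self, line4):
        _, D, nm = line4
        # paths 0->1->0, 0->1->2, 0->2->1, 0->2->0 give 2 + 5 + 13 + 18
        assert diffusion_sum(nm, D, 0, 2) == pytest.approx(38.0)

    def test_invalid_layers(self, line4):
        _, D, nm = line4
        with pytest.raises(ValueError):
            diffusion_sum(nm, D, 0, 0)

    def test_recursion_matches_path_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            _, D, nm = random_instance(rng)
            k = int(rng.integers(1, 4))
            S = diffusion_sums(nm, D, k)
            i = int(rng.integers(nm.n))
            assert S[i] == pytest.approx(enumerate_diffusion_sum(nm, D, i, k), abs=1e-9)


class TestPfdSimilarity:
    def test_non_mutual_zero(self, line4):
        _, D, nm = line4
        assert pfd_similarity(nm, D, 0, 3, PFDParams(K=2, k=1)) == 0.0

    def test_line_values(self, line4):
        _, D, nm = line4
        p = PFDParams(K=2, k=1)
        assert pfd_similarity(nm, D, 0, 2, p) == pytest.approx(2.0)
        assert pfd_similarity(nm, D, 0, 1, p) == pytest.approx(10 / 13)

    def test_ablation_drops_diffusion_factor(self, line4):
        _, D, nm = line4
        p = PFDParams(K=2, k=1, diffusion=False)
        assert pfd_similarity(nm, D, 0, 2, p) == pytest.approx(0.2)

    def test_field_zero_off_mutual_graph(self):
        rng = np.random.default_rng(12)
        _, D, nm = random_instance(rng, n=10, K=3)
        sf = similarity_field(nm, D, PFDParams(K=3, k=2))
        mutual = nm.in_sigma & nm.in_sigma.T
        assert np.all(sf.Theta[~mutual] == 0.0)
        assert np.all(sf.theta >= 0) and np.all(sf.Theta >= 0) and np.all(sf.S >= 0)


class TestLocalDensity:
    def test_line_rho0(self, line4):
        _, D, nm = line4
        sf = similarity_field(nm, D, PFDParams(K=2, k=1))
        rho = local_density(sf, 2)
        assert rho[0] == pytest.approx(36 / 13)

    def test_isolated_point_zero_density(self):
        # last point is nobody's mutual neighbor
        X = np.array([[0.0], [0.1], [0.2], [50.0]])
        D = pairwise_distances(PointSet(X))
        nm = knn_sets(D, 1)
        sf = similarity_field(nm, D, PFDParams(K=1, k=1))
        rho = local_density(sf, 1)
        assert rho[3] == 0.0

    def test_matches_brute_force_top_K(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            _, D, nm = random_instance(rng)
            sf = similarity_field(nm, D, PFDParams(K=nm.K, k=2))
            rho = local_density(sf, nm.K)
            for i in range(nm.n):
                row = np.delete(sf.Theta[i], i)
                expected = np.sort(row)[::-1][: nm.K].sum()
                assert rho[i] == pytest.approx(expected, abs=1e-9)


class TestNearestDenser:
    def test_two_points(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        delta, parent = nearest_denser(np.array([2.0, 1.0]), D)
        assert delta.tolist() == [4.0, 4.0]
        assert parent.tolist() == [-1, 0]

    def test_three_point_line(self):
        X = np.array([[0.0], [1.0], [3.0]])
        D = pairwise_distances(PointSet(X))
        delta, parent = nearest_denser(np.array([3.0, 1.0, 2.0]), D)
        assert delta.tolist() == [3.0, 1.0, 3.0]
        assert parent.tolist() == [-1, 0, 0]

    def test_all_equal_densities(self):
        X = np.array([[0.0], [1.0], [5.0]])
        D = pairwise_distances(PointSet(X))
        delta, parent = nearest_denser(np.ones(3), D)
        assert np.all(parent == -1)
        assert np.all(delta == 5.0)

    def test_single_point(self):
        delta, parent = nearest_denser(np.array([1.0]), np.zeros((1, 1)))
        assert delta.tolist() == [0.0] and parent.tolist() == [-1]

    def test_parent_strictly_denser(self):
        rng = np.random.default_rng(14)
        _, D, _ = random_instance(rng, n=12)
        rho = rng.random(12)
        delta, parent = nearest_denser(rho, D)
        for i in range(12):
            if parent[i] >= 0:
                assert rho[parent[i]] > rho[i]
                assert delta[i] == D[i, parent[i]]


class TestDecisionValues:
    def test_elementwise_product(self):
        np.testing.assert_array_equal(
            decision_values(np.array([3.0, 1.0, 2.0]), np.array([3.0, 1.0, 3.0])),
            [9.0, 1.0, 6.0],
        )

    def test_zero_density_zero_gamma(self):
        assert decision_values(np.array([0.0]), np.array([5.0]))[0] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            decision_values(np.ones(2), np.ones(3))


class TestExportDecisionGraph:
    def test_sorted_and_round_trips(self, tmp_path):
        rng = np.random.default_rng(15)
        _, D, nm = random_instance(rng, n=8, K=3)
        _, stats = peak_stats(nm, D, PFDParams(K=3, k=1))
        path = tmp_path / "dg.tsv"
        export_decision_graph(stats, path)
        data = np.loadtxt(path)
        assert data.shape == (8, 4)
        assert np.all(np.diff(data[:, 3]) <= 0)  # gamma descending
        order = data[:, 0].astype(int)
        np.testing.assert_allclose(data[:, 1], stats.rho[order], rtol=0, atol=0)
        np.testing.assert_allclose(data[:, 3], stats.gamma[order], rtol=0, atol=0)


class TestInvariances:
    def test_similarity_scale_invariance(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(30, 2))
        params = PFDParams(K=4, k=2)
        D1 = pairwise_distances(PointSet(X))
        nm1 = knn_sets(D1, 4)
        sf1 = similarity_field(nm1, D1, params)
        c = 3.7
        D2 = pairwise_distances(PointSet(c * X))
        nm2 = knn_sets(D2, 4)
        sf2 = similarity_field(nm2, D2, params)
        # theta scales by c^-2, S by c^2, their product is scale-free
        np.testing.assert_allclose(sf2.Theta, sf1.Theta, rtol=1e-9)
        np.testing.assert_allclose(sf2.theta, sf1.theta / c**2, rtol=1e-9)
        np.testing.assert_allclose(sf2.S, sf1.S * c**2, rtol=1e-9)

    def test_delta_gamma_scale_linearly(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(25, 2))
        params = PFDParams(K=5, k=1)
        D1 = pairwise_distances(PointSet(X))
        _, st1 = peak_stats(knn_sets(D1, 5), D1, params)
        c = 0.25
        D2 = pairwise_distances(PointSet(c * X))
        _, st2 = peak_stats(knn_sets(D2, 5), D2, params)
        np.testing.assert_allclose(st2.rho, st1.rho, rtol=1e-9)
        np.testing.assert_allclose(st2.delta, c * st1.delta, rtol=1e-9)
        np.testing.assert_allclose(st2.gamma, c * st1.gamma, rtol=1e-9)
        np.testing.assert_array_equal(st2.parent, st1.parent)
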