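import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tau3dquant.phantom import make_point_pattern
from tau3dquant.pointstats import (
    cluster_analysis,
    dense_cells,
    neighbouring_cells,
    nn_distances,
    nni,
    paired_sim_vs_obs_test,
    per_hundred,
    split_components,
)

from conftest import brute_force_nn

SIX_POINTS = np.array(
    [[0, 0, 0], [5, 0, 0], [100, 0, 0], [108, 0, 0], [200, 0, 0], [300, 0, 0]],
    dtype=float,
)


def _box_mask(n=20):
    return np.ones((n, n, n), dtype=bool)


class TestNNDistances:
    def test_two_points(self):
        d = nn_distances(np.array([[0, 0, 0], [10, 0, 0.0]]))
        np.testing.assert_allclose(d, [10, 10])

    def test_collinear_hand_example(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [25, 0, 0.0]])
        np.testing.assert_allclose(nn_distances(pts), [10, 10, 15])

    def test_brute_force_oracle_200_points(self, rng):
        pts = rng.uniform(0, 500, size=(200, 3))
        np.testing.assert_allclose(nn_distances(pts), brute_force_nn(pts))

    def test_duplicates_flagged_zero(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [5, 0, 0.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            d = nn_distances(pts)
        assert d[0] == 0 and d[1] == 0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            nn_distances(np.array([[0, 0, 0.0]]))


class TestNNI:
    def test_csr_input_near_one(self):
        mask = _box_mask()
        vs = (25.0, 25.0, 25.0)
        hits = 0
        for seed in range(20):
            pts = make_point_pattern(mask, vs, 500, "CSR", seed=1000 + seed)
            res = nni(pts, mask, vs, n_sims=100, seed=seed)
            hits += 0.95 <= res.nni <= 1.05
        assert hits >= 19  # >= 95% of 20 seeds

    def test_clustered_input_below_one(self, small_masks):
        mask = small_masks.mask("core")
        vs = (8.0, 8.0, 8.0)
        pts = make_point_pattern(mask, vs, mode="thomas", seed=3, n_parents=40,
                                 offspring_per_parent=5, sigma_um=30)
        res = nni(pts, mask, vs, n_sims=50, seed=0)
        assert res.nni < 1.0

    def test_lattice_above_one(self):
        mask = _box_mask(24)
        vs = (20.0, 20.0, 20.0)
        pts = make_point_pattern(mask, vs, mode="lattice", spacing_um=60.0)
        res = nni(pts, mask, vs, n_sims=50, seed=0)
        assert res.nni > 1.0

    def test_points_outside_mask_listed(self):
        mask = _box_mask(5)
        pts = np.array([[10, 10, 10], [999.0, 0, 0]])
        with pytest.raises(ValueError, match="outside the mask.*1"):
            nni(pts, mask, (10, 10, 10), n_sims=1)

    def test_seeded_reproducible(self):
        mask = _box_mask(10)
        vs = (10.0, 10.0, 10.0)
        pts = make_point_pattern(mask, vs, 50, "CSR", seed=7)
        a = nni(pts, mask, vs, n_sims=10, seed=5)
        b = nni(pts, mask, vs, n_sims=10, seed=5)
        assert a.nni == b.nni
        np.testing.assert_array_equal(a.sim_means_um, b.sim_means_um)

    def test_monotone_clustering_response(self, small_masks):
        # NNI decreases as cluster dispersion shrinks (Wilcoxon signed-rank
        # on paired per-seed differences between adjacent sigma levels)
        from scipy.stats import wilcoxon

        mask = small_masks.mask("core")
        vs = (8.0, 8.0, 8.0)
        nnis = {}
        for sigma in (100.0, 50.0, 25.0):
            vals = []
            for seed in range(20):
                pts = make_point_pattern(mask, vs, mode="thomas", seed=seed,
                                         n_parents=40, offspring_per_parent=5,
                                         sigma_um=sigma)
                vals.append(nni(pts, mask, vs, n_sims=20, seed=seed).nni)
            nnis[sigma] = np.array(vals)
        for hi, lo in ((100.0, 50.0), (50.0, 25.0)):
            stat = wilcoxon(nnis[hi], nnis[lo], alternative="greater")
            assert stat.pvalue < 0.01


class TestPairedTest:
    def test_identical_vectors(self):
        t, p = paired_sim_vs_obs_test(np.arange(5.0), np.arange(5.0))
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference(self):
        t, p = paired_sim_vs_obs_test(np.array([2.0, 3, 4, 5]),
                                      np.array([1.0, 2, 3, 4]))
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_hand_computed_five_pairs(self):
        # d = [1..5]: t = 3 / (sqrt(2.5)/sqrt(5)); frozen closed-form values
        obs = np.array([10.0, 12, 14, 16, 18])
        sim = np.array([9.0, 10, 11, 12, 13])
        t, p = paired_sim_vs_obs_test(obs, sim)
        assert t == pytest.approx(4.242640687119285)
        assert p == pytest.approx(0.01323559956368269)

    def test_bad_shapes(self):
        with pytest.raises(ValueError):
            paired_sim_vs_obs_test(np.arange(3.0), np.arange(4.0))
        with pytest.raises(ValueError):
            paired_sim_vs_obs_test(np.array([1.0]), np.array([2.0]))


class TestDenseCells:
    def test_two_points_never_dense(self):
        flags, thr = dense_cells(np.array([[0, 0, 0], [8.0, 0, 0]]))
        assert thr == pytest.approx(6.0)
        assert not flags.any()  # d < 0.75 d is false

    def test_six_point_worked_example(self):
        flags, thr = dense_cells(SIX_POINTS)
        assert thr == pytest.approx(27.25)
        np.testing.assert_array_equal(flags,
                                      [True, True, True, True, False, False])

    def test_default_factor_is_75_percent(self):
        import inspect

        sig = inspect.signature(dense_cells)
        assert sig.parameters["factor"].default == 0.75

    def test_invalid_factor(self):
        for bad in (0.0, -0.5, 1.2):
            with pytest.raises(ValueError, match="factor"):
                dense_cells(SIX_POINTS, factor=bad)


class TestSplitComponents:
    def test_six_point_two_duos(self):
        flags, thr = dense_cells(SIX_POINTS)
        res = split_components(SIX_POINTS, flags, thr)
        assert res.duo_count == 2
        assert res.minigroup_count == 0
        assert res.large_group_count == 0
        assert res.component_id[0] == res.component_id[1]
        assert res.component_id[2] == res.component_id[3]
        assert res.component_id[0] != res.component_id[2]
        assert np.all(res.component_id[4:] == -1)

    def test_chain_of_five_is_one_minigroup(self):
        pts = np.array([[10.0 * i, 0, 0] for i in range(5)])
        flags = np.ones(5, dtype=bool)
        res = split_components(pts, flags, link_threshold_um=12.0)
        assert res.minigroup_count == 1
        assert res.duo_count == 0
        assert res.component_sizes == {0: 5}

    def test_empty_dense_set(self):
        res = split_components(SIX_POINTS, np.zeros(6, bool), 10.0)
        assert res.duo_count == res.minigroup_count == res.large_group_count == 0
        assert np.all(res.component_id == -1)

    def test_large_group_counted_separately(self):
        pts = np.array([[4.0 * i, 0, 0] for i in range(12)])
        res = split_components(pts, np.ones(12, bool), 5.0)
        assert res.large_group_count == 1
        assert res.minigroup_count == 0

    def test_strict_link_inequality(self):
        pts = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        res = split_components(pts, np.ones(2, bool), 10.0)
        assert res.duo_count == 0  # distance == threshold is not linked

    def test_component_invariants_on_random_patterns(self, rng):
        for _ in range(25):
            pts = rng.uniform(0, 200, size=(60, 3))
            flags, thr = dense_cells(pts)
            res = split_components(pts, flags, thr)
            sizes = list(res.component_sizes.values())
            assert all(s >= 2 for s in sizes)
            n_comp = res.duo_count + res.minigroup_count + res.large_group_count
            assert n_comp == len(sizes)
            assert (res.component_id >= 0).sum() == flags.sum()

    def test_brute_force_components_oracle(self, rng):
        # union-find over explicit all-pairs adjacency as the oracle
        for _ in range(10):
            pts = rng.uniform(0, 150, size=(40, 3))
            flags, thr = dense_cells(pts)
            res = split_components(pts, flags, thr)
            idx = np.flatnonzero(flags)
            parent = {i: i for i in idx}

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for a in idx:
                for b in idx:
                    if a < b and np.linalg.norm(pts[a] - pts[b]) < thr:
                        parent[find(a)] = find(b)
            oracle = {}
            for i in idx:
                oracle.setdefault(find(i), set()).add(i)
            got = {}
            for i in idx:
                got.setdefault(res.component_id[i], set()).add(i)
            assert sorted(map(sorted, oracle.values())) == sorted(
                map(sorted, got.values())
            )


class TestNeighbouringCells:
    def test_zero_reference_only_coincident(self):
        pts = np.array([[0.0, 0, 0], [0.0, 0, 0], [50.0, 0, 0]])
        flags = np.ones(3, bool)
        with pytest.warns(UserWarning):
            out = neighbouring_cells(pts, flags, 0.0)
        assert out[0] and out[1] and not out[2]

    def test_six_point_example_reference_6(self):
        flags, _ = dense_cells(SIX_POINTS)
        out = neighbouring_cells(SIX_POINTS, flags, 6.0)
        np.testing.assert_array_equal(out,
                                      [True, True, False, False, False, False])

    def test_subset_of_dense_on_random_patterns(self, rng):
        for _ in range(100):
            pts = rng.uniform(0, 100, size=(30, 3))
            flags, _ = dense_cells(pts)
            out = neighbouring_cells(pts, flags, rng.uniform(0, 50))
            assert not np.any(out & ~flags)

    def test_negative_reference_rejected(self):
        with pytest.raises(ValueError):
            neighbouring_cells(SIX_POINTS, np.ones(6, bool), -1.0)


class TestPerHundred:
    def test_examples(self):
        assert per_hundred(3, 150) == pytest.approx(2.0)
        assert per_hundred(0, 10) == 0.0

    def test_zero_cells_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(per_hundred(3, 0))

    def test_random_cross_check(self, rng):
        count = int(rng.integers(0, 50))
        n = int(rng.integers(1, 500))
        assert per_hundred(count, n) == pytest.approx(100.0 * count / n)


class TestClusterAnalysis:
    def test_full_pipeline_on_worked_example(self):
        res = cluster_analysis(SIX_POINTS, th_mean_nn_um=6.0)
        assert res.duo_count == 2
        assert res.duos_per_100 == pytest.approx(100.0 * 2 / 6)
        assert res.neighbouring_flags.sum() == 2
        assert res.neighbouring_per_100 == pytest.approx(100.0 * 2 / 6)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 100, size=(25, 3))
    perm = rng.permutation(25)
    a = cluster_analysis(pts)
    b = cluster_analysis(pts[perm])
    assert a.dense_threshold_um == pytest.approx(b.dense_threshold_um)
    np.testing.assert_array_equal(a.dense_flags[perm], b.dense_flags)
    assert a.duo_count == b.duo_count
    assert a.minigroup_count == b.minigroup_count
    assert sorted(a.component_sizes.values()) == sorted(b.component_sizes.values())
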