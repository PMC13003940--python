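import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbss import metrics
from cbss.metrics import (
    best_partition,
    bh_fdr,
    binarize_by_density,
    cross_joint_isi,
    detrend_despike,
    exhaustive_partition,
    fisher_z,
    group_tests,
    isi,
    joint_isi,
    ks_statistic,
    modularity_over_density,
    modularity_q,
    spatial_fnc,
    temporal_fnc,
    tmap,
    tmap_summary,
)


def _scaled_permutation(n, rng):
    P = np.zeros((n, n))
    perm = rng.permutation(n)
    P[np.arange(n), perm] = rng.uniform(0.5, 3.0, n) * rng.choice([-1, 1], n)
    return P


class TestIsi:
    def test_identity_is_zero(self):
        assert isi(np.eye(5)) == 0.0

    def test_scaled_permutation_is_zero(self, rng):
        for _ in range(10):
            assert isi(_scaled_permutation(6, rng)) == 0.0

    def test_all_ones_is_one(self):
        assert isi(np.ones((7, 7))) == pytest.approx(1.0)

    def test_zero_row_raises(self):
        G = np.eye(4)
        G[2, 2] = 0.0
        with pytest.raises(ValueError):
            isi(G)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 8), st.integers(0, 1000))
    def test_bounded_and_permutation_invariant(self, n, seed):
        rng = np.random.default_rng(seed)
        G = rng.uniform(0.05, 1.0, (n, n))
        v = isi(G)
        assert 0.0 <= v <= 1.0
        perm = rng.permutation(n)
        assert isi(G[perm][:, perm]) == pytest.approx(v, abs=1e-12)


class TestJointIsi:
    def test_common_permutation_is_zero(self, rng):
        P = _scaled_permutation(5, rng)
        assert joint_isi([P, 2.0 * P, -P]) == 0.0

    def test_single_subject_reduces_to_isi(self, rng):
        G = rng.uniform(0.1, 1.0, (4, 4))
        assert joint_isi([G]) == pytest.approx(isi(G))

    def test_conflicting_permutations_evaluated_on_mean(self):
        # two subjects aligned to different permutations: the mean absolute
        # matrix is no longer a permutation, hand-evaluated 3x3 case
        G1 = np.eye(3)
        G2 = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mean = (G1 + G2) / 2.0
        assert joint_isi([G1, G2]) == pytest.approx(isi(mean))
        assert joint_isi([G1, G2]) > 0.0


class TestCrossJointIsi:
    def test_identical_runs_are_zero(self, rng):
        W = [rng.standard_normal((4, 4)) + 2 * np.eye(4) for _ in range(3)]
        rep = cross_joint_isi([W, [w.copy() for w in W]])
        assert np.allclose(rep.pairwise, 0.0, atol=1e-12)

    def test_equivalent_runs_are_zero(self, rng):
        # runs differing by one consistent permutation + scaling across
        # subjects are BSS-equivalent
        W = [rng.standard_normal((4, 4)) + 2 * np.eye(4) for _ in range(3)]
        P = _scaled_permutation(4, rng)
        rep = cross_joint_isi([W, [P @ w for w in W]], n_constrained=2)
        assert np.allclose(rep.pairwise, 0.0, atol=1e-10)

    def test_per_run_average_is_mean_of_pairwise(self, rng):
        runs = [
            [rng.standard_normal((3, 3)) + 2 * np.eye(3) for _ in range(2)]
            for _ in range(3)
        ]
        rep = cross_joint_isi(runs)
        for i in range(3):
            expected = np.delete(rep.pairwise[i], i).mean()
            assert rep.per_run[i] == pytest.approx(expected)

    def test_needs_two_runs(self, rng):
        with pytest.raises(ValueError):
            cross_joint_isi([[np.eye(3)]])


class TestDetrendDespike:
    def test_linear_ramp_removed(self):
        out = detrend_despike(np.linspace(0, 5, 40))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_spike_clipped_others_kept(self):
        rng = np.random.default_rng(1)
        x = 0.1 * rng.standard_normal(50)
        x[25] = 30.0  # far beyond the 3-MAD fence of the noise floor
        out = detrend_despike(x)
        inliers = np.delete(np.arange(50), 25)
        assert out[25] < 2.0  # spike pulled down to the fence
        # inliers only shifted by the (spike-induced) linear trend removal
        assert np.max(np.abs(out[inliers] - x[inliers])) < 1.5

    def test_near_identity_on_clean_noise(self, rng):
        x = rng.standard_normal(200)
        out = detrend_despike(x)
        assert np.corrcoef(out, x)[0, 1] > 0.99

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            detrend_despike(np.arange(5.0))


class TestTemporalFnc:
    def test_duplicated_and_negated_columns(self, rng):
        base = rng.standard_normal(100)
        tc = np.column_stack([base, base, -base])
        F = temporal_fnc(tc, preprocess=False)
        assert F.values[0, 1] == pytest.approx(1.0)
        assert F.values[0, 2] == pytest.approx(-1.0)

    def test_fisher_transform_value(self):
        assert fisher_z(np.array(0.5)) == pytest.approx(0.5493, abs=1e-4)

    def test_fisher_z_is_odd_and_inverse_consistent(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        np.testing.assert_allclose(fisher_z(-r), -fisher_z(r), atol=1e-12)
        np.testing.assert_allclose(np.tanh(fisher_z(r)), r, atol=1e-12)

    def test_fisher_kept_finite_on_perfect_correlation(self, rng):
        base = rng.standard_normal(64)
        F = temporal_fnc(np.column_stack([base, base]), fisher=True, preprocess=False)
        assert np.isfinite(F.values).all()


class TestSpatialFnc:
    def test_identical_maps(self, rng):
        m = rng.standard_normal(500)
        F = spatial_fnc(np.vstack([m, m]))
        assert F.values[0, 1] == pytest.approx(1.0)

    def test_threshold_off_equals_plain_pearson(self, rng):
        maps = rng.standard_normal((3, 400))
        F = spatial_fnc(maps, z_thresh=0.0)
        np.testing.assert_allclose(F.values, np.corrcoef(maps), atol=1e-9)

    def test_matches_direct_pearson_of_thresholded_maps(self, rng):
        maps = rng.standard_normal((2, 1000))
        maps[0, :100] += 5.0
        maps[1, 500:600] += 5.0
        F = spatial_fnc(maps, z_thresh=2.0)
        z = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
        z[np.abs(z) < 2.0] = 0.0
        assert F.values[0, 1] == pytest.approx(np.corrcoef(z)[0, 1], abs=1e-9)


class TestBinarizeByDensity:
    def test_edge_count(self, rng):
        F = np.abs(rng.standard_normal((10, 10)))
        F = (F + F.T) / 2
        A = binarize_by_density(F, 0.4)
        assert A.sum() // 2 == 18  # ceil(0.4 * 45)

    def test_full_density_keeps_all_positive(self, rng):
        F = rng.standard_normal((6, 6))
        F = (F + F.T) / 2
        A = binarize_by_density(F, 1.0)
        iu = np.triu_indices(6, 1)
        assert A[iu].sum() == (F[iu] > 0).sum()

    def test_symmetric_zero_diagonal(self, rng):
        F = rng.standard_normal((8, 8))
        A = binarize_by_density((F + F.T) / 2, 0.5)
        assert np.array_equal(A, A.T) and np.all(np.diag(A) == 0)


class TestModularity:
    @staticmethod
    def _two_triangles():
        A = np.zeros((6, 6), int)
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            A[i, j] = A[j, i] = 1
        return A

    def test_two_triangles_q(self):
        assert modularity_q(self._two_triangles(), [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        A = np.ones((5, 5), int) - np.eye(5, dtype=int)
        assert modularity_q(A, np.zeros(5)) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_nonpositive(self, rng):
        A = (rng.random((7, 7)) < 0.5).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        A[0, 1] = A[1, 0] = 1
        assert modularity_q(A, np.arange(7)) <= 1e-12

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError):
            modularity_q(np.zeros((4, 4)), np.zeros(4))

    def test_best_partition_recovers_triangles(self):
        res = best_partition(self._two_triangles(), seed=0)
        assert res.Q == pytest.approx(0.5)
        assert len(set(res.partition[:3])) == 1 and len(set(res.partition[3:])) == 1

    def test_best_partition_matches_exhaustive_on_bridged_cliques(self):
        A = np.zeros((8, 8), int)
        for grp in (range(4), range(4, 8)):
            for i in grp:
                for j in grp:
                    if i != j:
                        A[i, j] = 1
        A[3, 4] = A[4, 3] = 1
        assert best_partition(A, seed=1).Q == pytest.approx(exhaustive_partition(A).Q)

    def test_seeded_determinism(self, rng):
        A = (rng.random((10, 10)) < 0.4).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        A[0, 1] = A[1, 0] = 1
        r1 = best_partition(A, seed=5)
        r2 = best_partition(A, seed=5)
        assert np.array_equal(r1.partition, r2.partition) and r1.Q == r2.Q

    def test_block_structure_found_over_density_grid(self, rng):
        # two strong blocks: the density sweep finds the block partition
        F = 0.05 * rng.standard_normal((10, 10))
        F[:5, :5] += 0.8
        F[5:, 5:] += 0.8
        F = (F + F.T) / 2
        np.fill_diagonal(F, 1.0)
        res = modularity_over_density(F, seed=0)
        direct = best_partition(binarize_by_density(F, res.link_density), seed=0)
        assert res.Q >= direct.Q - 0.02
        assert res.Q > 0.3

    def test_unstructured_fnc_low_q(self, rng):
        F = 0.02 * rng.standard_normal((10, 10))
        F = (F + F.T) / 2
        np.fill_diagonal(F, 1.0)
        assert modularity_over_density(F, seed=0).Q < 0.45

    def test_grid_refinement_never_decreases_max(self, rng):
        F = rng.standard_normal((9, 9))
        F = (F + F.T) / 2
        coarse = modularity_over_density(F, np.array([0.3, 0.6]), seed=0).Q
        fine = modularity_over_density(F, np.array([0.2, 0.3, 0.45, 0.6, 0.7]), seed=0).Q
        assert fine >= coarse - 1e-12


class TestStatistics:
    def test_ks_identical_and_disjoint(self, rng):
        x = rng.standard_normal(50)
        assert ks_statistic(x, x) == 0.0
        assert ks_statistic(np.arange(5.0), np.arange(10.0, 15.0)) == 1.0

    def test_ks_hand_case(self):
        assert ks_statistic(np.array([1.0, 2, 3]), np.array([2.0, 3, 4])) == pytest.approx(1 / 3)

    def test_bh_hand_case(self):
        mask = bh_fdr(np.array([0.01, 0.02, 0.04, 0.5]), q=0.05)
        assert mask.sum() == 2 and mask[0] and mask[1]

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 500))
    def test_bh_monotone_in_q(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 20)
        assert np.all(bh_fdr(p, 0.01) <= bh_fdr(p, 0.05))

    def test_identical_groups_no_rejections(self, rng):
        a = rng.standard_normal((3, 4))
        vals = np.vstack([a, a])
        labels = np.array([0] * 3 + [1] * 3)
        res = group_tests(vals, labels, kind="two-sample")
        np.testing.assert_allclose(res.t, 0.0, atol=1e-12)
        assert res.n_significant == 0

    def test_one_sample_hand_value(self):
        res = group_tests(np.array([[1.0], [2.0], [3.0]]), kind="one-sample")
        assert res.t[0] == pytest.approx(3.464, abs=1e-3)

    def test_paired_matches_scipy(self, rng):
        from scipy import stats

        a = rng.standard_normal((6, 3))
        b = a + 0.5 + 0.1 * rng.standard_normal((6, 3))
        vals = np.vstack([a, b])
        labels = np.array([0] * 6 + [1] * 6)
        res = group_tests(vals, labels, kind="paired")
        t_ref = stats.ttest_rel(a, b, axis=0).statistic
        np.testing.assert_allclose(res.t, t_ref, atol=1e-12)


class TestTmap:
    def test_identical_subjects_capped(self):
        maps = np.tile(np.array([1.0, -2.0, 0.0]), (4, 1))
        t = tmap(maps)
        assert t[0] == 1e6 and t[1] == -1e6 and t[2] == 0.0

    def test_hand_value(self):
        t = tmap(np.array([[1.0], [2.0], [3.0]]))
        assert t[0] == pytest.approx(3.464, abs=1e-3)

    def test_summary_hand_case(self):
        # 2 voxels, 3 subjects: t = (3.464, -3.464); z-scores (+1, -1)
        maps = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        t = tmap(maps)
        out = tmap_summary(t, [0.5, 1.5])
        assert out[0.5] == pytest.approx(np.abs(t).mean())
        assert np.isnan(out[1.5])
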