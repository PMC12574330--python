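import numpy as np
import pytest

from patchvar import (
    GenerationError,
    ParameterError,
    SimulationSpec,
    apply_dropout,
    emulate_2d_benchmark,
    evaluate_power_fdr,
    make_grid_3d,
    mark_spots,
    nodule_centers,
    random_walk_centers,
    simulate_benchmark,
    simulate_density_matrix,
)
from patchvar.simulation import (
    PATTERNS_3D_CONTINUOUS,
    _beta_counts_pmf,
    _upper_tail_pmf,
    simulate_null_benchmark,
)


class TestGrids:
    def test_continuous_grid_2250_spots(self):
        g = make_grid_3d("continuous")
        assert g.n_spots == 2250 and g.n_dims == 3

    def test_discrete_grid_9000_spots(self):
        g = make_grid_3d("discrete")
        assert g.n_spots == 9000
        assert g.coords[:, :2].min() >= 0 and g.coords[:, :2].max() <= 30

    def test_z_levels_are_integers_one_to_ten(self):
        for kind in ("continuous", "discrete"):
            z = np.unique(make_grid_3d(kind).coords[:, 2])
            np.testing.assert_array_equal(z, np.arange(1.0, 11.0))


class TestRandomWalkCenters:
    @pytest.mark.parametrize("pattern", PATTERNS_3D_CONTINUOUS)
    def test_fixed_step_length(self, pattern):
        centers = random_walk_centers(pattern, step=2.0, n_steps=8, seed=0)
        steps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        np.testing.assert_allclose(steps, 2.0, atol=1e-12)

    def test_monotonicity_constraints(self):
        strand = random_walk_centers("curved_strand", seed=1)
        assert (np.diff(strand[:, 0]) >= 0).all() and (np.diff(strand[:, 1]) >= 0).all()
        layer = random_walk_centers("tissue_layer", seed=1)
        assert (np.diff(layer[:, 0]) >= 0).all()

    def test_seed_reproducibility(self):
        a = random_walk_centers("irregular_aggregate", seed=7)
        b = random_walk_centers("irregular_aggregate", seed=7)
        np.testing.assert_array_equal(a, b)

    def test_stays_in_bounds(self):
        lo, hi = np.array([1.0, 1.0, 1.0]), np.array([15.0, 15.0, 10.0])
        for seed in range(5):
            c = random_walk_centers("curved_strand", seed=seed, bounds=(lo, hi))
            assert (c >= lo).all() and (c <= hi).all()

    def test_impossible_bounds_raise(self):
        tight = (np.zeros(3), np.full(3, 0.5))  # box smaller than one step
        with pytest.raises(GenerationError):
            random_walk_centers("curved_strand", step=2.0, seed=0, bounds=tight)


class TestNoduleCenters:
    def test_sixteen_centers_on_jittered_lattice(self):
        c = nodule_centers(seed=3)
        assert c.shape == (16, 3)
        lattice = np.array(
            [[x, y, 5.5] for x in (3, 11, 19, 27) for y in (3, 11, 19, 27)], float
        )
        jitter = c - lattice
        assert (np.abs(jitter) <= 2.0).all()

    def test_seeded(self):
        np.testing.assert_array_equal(nodule_centers(seed=5), nodule_centers(seed=5))


class TestMarkSpots:
    def test_center_spot_marked_and_radius_monotone(self):
        grid = make_grid_3d("discrete")
        centers = nodule_centers(seed=0)
        near_center = np.vstack([centers[0], grid.coords[0]])
        mask = mark_spots(near_center, centers, 1.5)
        assert mask[0]  # a spot exactly at a center is inside the closed ball
        small = mark_spots(grid, centers, 1.5)
        large = mark_spots(grid, centers, 2.5)
        assert (small <= large).all() and small.sum() < large.sum()

    def test_matches_brute_force(self):
        grid = make_grid_3d("continuous")
        centers = random_walk_centers("curved_strand", seed=2)
        mask = mark_spots(grid, centers, 2.0)
        d = np.linalg.norm(
            grid.coords[:, None, :] - centers[None, :, :], axis=2
        ).min(axis=1)
        np.testing.assert_array_equal(mask, d <= 2.0)


class TestUpperTailCalibration:
    def test_tail_mean_hits_fold_change_target(self):
        values, probs = _beta_counts_pmf()
        base_mean = values @ probs
        for fc in (2.0, 2.5, 3.0):
            tail = _upper_tail_pmf(values, probs, fc)
            assert values @ tail == pytest.approx(fc * base_mean, rel=1e-12)
            assert tail.min() >= 0 and tail.sum() == pytest.approx(1.0)

    def test_unachievable_fold_change_raises(self):
        values, probs = _beta_counts_pmf()
        with pytest.raises(GenerationError):
            _upper_tail_pmf(values, probs, 5.0)  # target mean > support max 10


class TestSimulateExpression:
    def _sim(self, **kw):
        spec = SimulationSpec(
            pattern="curved_strand", fold_change=kw.pop("fold_change", 3.0),
            noise_sigma=kw.pop("noise_sigma", 0.0),
            dropout_rate=kw.pop("dropout_rate", 0.0),
            n_svf=kw.pop("n_svf", 50), n_null=kw.pop("n_null", 150),
            seed=kw.pop("seed", 0),
        )
        return simulate_benchmark(spec)

    def test_feature_counts_and_truth(self):
        out = self._sim(n_svf=100, n_null=900)
        assert out.expression.n_features == 1000
        assert out.truth.sum() == 100 and out.truth[:100].all()

    def test_realized_fold_change_near_target(self):
        ratios = []
        for seed in range(3):
            out = self._sim(seed=seed, fold_change=3.0)
            X = np.asarray(out.expression.values.todense())[out.truth]
            marked = X[:, out.marked_spots].mean()
            unmarked = X[:, ~out.marked_spots].mean()
            ratios.append(marked / unmarked)
        assert 2.7 <= np.mean(ratios) <= 3.3

    def test_null_rows_are_permutations_of_svf_rows(self):
        out = self._sim(n_svf=20, n_null=60)
        X = np.asarray(out.expression.values.todense())
        svf_multisets = {tuple(sorted(row)) for row in X[:20]}
        for row in X[20:]:
            assert tuple(sorted(row)) in svf_multisets

    def test_integer_counts(self):
        out = self._sim(noise_sigma=1.0)
        data = out.expression.values.data
        np.testing.assert_array_equal(data, np.rint(data))
        assert data.min() >= 0

    def test_fully_null_mode_destroys_truth(self):
        out = simulate_null_benchmark(n_features=200, n_spots=100, seed=0)
        assert not out.truth.any()
        assert out.expression.n_features == 200


class TestApplyDropout:
    def test_zero_rate_identity(self):
        X = simulate_density_matrix(20, 50, 0.3, seed=0)
        assert apply_dropout(X, 0.0) is X

    def test_exact_fraction_zeroed_on_dense_feature(self):
        import scipy.sparse as sp

        from patchvar import ExpressionMatrix

        X = ExpressionMatrix(
            sp.csr_matrix(np.ones((1, 100))), ["g"], [f"s{i}" for i in range(100)]
        )
        out = apply_dropout(X, 0.3, seed=1)
        assert out.values.nnz == 70

    def test_nonzero_count_never_increases(self):
        X = simulate_density_matrix(50, 200, 0.4, seed=2)
        out = apply_dropout(X, 0.2, seed=3)
        before = np.diff(X.values.indptr)
        after = np.diff(out.values.indptr)
        assert (after <= before).all()

    def test_rate_out_of_range_rejected(self):
        X = simulate_density_matrix(5, 20, 0.5, seed=0)
        with pytest.raises(ParameterError):
            apply_dropout(X, 0.8)


class TestDensityMatrix:
    def test_realized_density_close_to_request(self):
        X = simulate_density_matrix(2000, 2000, 0.0005, seed=4)
        realized = X.values.nnz / (2000 * 2000)
        assert abs(realized - 0.0005) / 0.0005 <= 0.05

    def test_values_in_support(self):
        X = simulate_density_matrix(100, 100, 0.05, seed=5)
        data = X.values.data
        assert np.array_equal(data, np.rint(data))
        assert data.min() >= 1 and data.max() <= 10

    def test_seed_contract(self):
        a = simulate_density_matrix(50, 50, 0.1, seed=6)
        b = simulate_density_matrix(50, 50, 0.1, seed=6)
        assert (a.values != b.values).nnz == 0


class TestEmulate2D:
    @pytest.mark.parametrize("pattern", ["hotspot_2d", "streak_2d", "ring_2d"])
    def test_layout_and_counts(self, pattern):
        spec = SimulationSpec(pattern=pattern, fold_change=3.0, n_svf=50, n_null=150, seed=0)
        out = emulate_2d_benchmark(spec)
        assert out.coords.n_spots == 260 and out.coords.n_dims == 2
        assert out.expression.n_features == 200
        assert 0 < out.marked_spots.sum() < 260

    def test_fold_change_grid_accepted(self):
        for fc in (3.0, 4.0, 5.0):
            spec = SimulationSpec(pattern="hotspot_2d", fold_change=fc,
                                  noise_sigma=0.0, n_svf=20, n_null=0, seed=1)
            out = emulate_2d_benchmark(spec)
            assert out.expression.n_features == 20

    def test_higher_fc_larger_contrast(self):
        def contrast(fc, seed):
            spec = SimulationSpec(pattern="hotspot_2d", fold_change=fc,
                                  noise_sigma=0.0, n_svf=30, n_null=0, seed=seed)
            out = emulate_2d_benchmark(spec)
            X = np.asarray(out.expression.values.todense())
            return X[:, out.marked_spots].mean() / X[:, ~out.marked_spots].mean()

        low = np.mean([contrast(3.0, s) for s in range(5)])
        high = np.mean([contrast(5.0, s) for s in range(5)])
        assert high > low


class TestZStretch:
    def test_only_z_changes(self):
        base = SimulationSpec(pattern="tissue_layer", n_svf=10, n_null=30, seed=2)
        stretched = SimulationSpec(pattern="tissue_layer", n_svf=10, n_null=30,
                                   seed=2, z_stretch=10.0)
        a = simulate_benchmark(base)
        b = simulate_benchmark(stretched)
        np.testing.assert_array_equal(a.coords.coords[:, :2], b.coords.coords[:, :2])
        np.testing.assert_allclose(b.coords.coords[:, 2], a.coords.coords[:, 2] * 10)
        assert (a.expression.values != b.expression.values).nnz == 0
        np.testing.assert_array_equal(a.truth, b.truth)


class TestEvaluatePowerFdr:
    def test_perfect_separation(self):
        p = np.r_[np.zeros(10), np.ones(90)]
        truth = np.r_[np.ones(10, bool), np.zeros(90, bool)]
        curve, auroc = evaluate_power_fdr(p, truth, np.array([0.01, 0.05, 1.0]))
        assert (curve["power"] == 1.0).all()
        assert auroc == 1.0

    def test_matches_brute_force_sweep(self):
        rng = np.random.default_rng(8)
        p = rng.random(1000)
        truth = rng.random(1000) < 0.3
        grid = np.array([0.05, 0.1, 0.3, 0.6])
        curve, _ = evaluate_power_fdr(p, truth, grid)
        n_pos = truth.sum()
        for f, got in zip(grid, curve["power"]):
            best = 0.0
            for t in np.unique(p):
                calls = p <= t
                fdp = (calls & ~truth).sum() / calls.sum()
                if fdp <= f:
                    best = (calls & truth).sum() / n_pos  # thresholds scanned ascending
            assert got == pytest.approx(best)

    def test_degenerate_truth_rejected(self):
        from patchvar import ValidationError

        with pytest.raises(ValidationError):
            evaluate_power_fdr(np.array([0.1, 0.2]), np.array([True, True]))


def test_seeded_benchmarks_bit_reproducible():
    for pattern in ("curved_strand", "isolated_nodules", "hotspot_2d"):
        spec = SimulationSpec(pattern=pattern, n_svf=20, n_null=40, seed=9,
                              fold_change=3.0)
        a = simulate_benchmark(spec)
        b = simulate_benchmark(spec)
        assert (a.expression.values != b.expression.values).nnz == 0
        np.testing.assert_array_equal(a.coords.coords, b.coords.coords)
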