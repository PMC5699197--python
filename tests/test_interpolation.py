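import numpy as np
import pytest

from nitraqua.interpolation import (
    InterpolatorSpec,
    OrdinaryKriging,
    ThinPlateSpline,
    VariogramModel,
    empirical_semivariogram,
    fit_variogram_model,
    idw_predict,
    krige_ordinary,
    make_interpolator,
    natural_neighbor_predict,
    natural_neighbor_weights,
    predict_grid,
    spline_tps_predict,
    _tps_kernel,
)
from nitraqua.synthetic import simulate_gaussian_field

from conftest import make_table

SPECS = [
    InterpolatorSpec(method="idw"),
    InterpolatorSpec(method="kriging", variogram=VariogramModel("spherical", 0.0, 10.0, 500.0)),
    InterpolatorSpec(method="spline"),
    InterpolatorSpec(method="natural_neighbor"),
]


class TestEmpiricalSemivariogram:
    def test_constant_field_gamma_zero(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.uniform(0, 100, (20, 2)), np.full(20, 7.0))
        emp = empirical_semivariogram(t, n_bins=5, max_lag=100.0)
        assert np.all(emp.gammas[emp.counts > 0] == 0.0)

    def test_single_pair(self):
        t = make_table([(0.0, 0.0), (10.0, 0.0)], [0.0, 2.0])
        emp = empirical_semivariogram(t, n_bins=1, max_lag=20.0)
        assert emp.counts[0] == 1
        assert emp.gammas[0] == pytest.approx(2.0)  # (1/2) * 2^2

    def test_empty_bins_reported(self):
        t = make_table([(0.0, 0.0), (10.0, 0.0)], [0.0, 2.0])
        emp = empirical_semivariogram(t, n_bins=4, max_lag=40.0)
        assert emp.counts[3] == 0 and np.isnan(emp.gammas[3])

    def test_pure_nugget_field(self):
        # iid noise: gamma should sit near the noise variance at all lags
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 1000, (300, 2))
        sigma2 = 4.0
        z = 20.0 + rng.normal(0, np.sqrt(sigma2), 300)
        emp = empirical_semivariogram(make_table(xy, z), n_bins=6, max_lag=500.0)
        ok = emp.counts > 100
        assert np.all(np.abs(emp.gammas[ok] - sigma2) < 0.8)

    def test_coincident_points_rejected(self):
        t = make_table([(0.0, 0.0), (0.0, 0.0)], [1.0, 2.0])
        with pytest.raises(ValueError, match="coincident"):
            empirical_semivariogram(t, 3, 10.0)


class TestFitVariogram:
    def test_exact_spherical_recovery(self):
        truth = VariogramModel("spherical", 1.0, 9.0, 800.0)
        lags = np.linspace(50, 1500, 12)
        fit = fit_variogram_model(lags, truth.gamma(lags), np.full(12, 40), "spherical")
        assert fit.nugget == pytest.approx(1.0, abs=1e-6)
        assert fit.partial_sill == pytest.approx(9.0, abs=1e-6)
        assert fit.range_m == pytest.approx(800.0, abs=1e-3)

    def test_flat_gamma_is_pure_nugget(self):
        lags = np.linspace(100, 1000, 8)
        fit = fit_variogram_model(lags, np.full(8, 3.0), np.full(8, 30), "spherical")
        assert fit.nugget == pytest.approx(3.0, abs=1e-6)
        assert fit.partial_sill == pytest.approx(0.0, abs=1e-6)

    def test_range_recovery_from_simulated_field(self):
        # single-realization range estimates are noisy, so the check is
        # on the median over fixed seeds
        truth = VariogramModel("spherical", 1.0, 9.0, 800.0)
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            xy = rng.uniform(0, 4000, (200, 2))
            z = 20.0 + simulate_gaussian_field(xy, truth, 900 + seed)
            emp = empirical_semivariogram(make_table(xy, z), n_bins=16, max_lag=1200.0)
            fit = fit_variogram_model(emp.lags, emp.gammas, emp.counts, "spherical")
            errs.append(abs(fit.range_m - 800.0) / 800.0)
        assert np.median(errs) < 0.25

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            fit_variogram_model(np.array([1.0, 2.0]), np.array([1.0, 1.0]),
                                np.array([5, 5]), "spherical")

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        lags = np.linspace(10, 500, 10)
        g = rng.uniform(1, 5, 10)
        c = rng.integers(5, 50, 10)
        f1 = fit_variogram_model(lags, g, c)
        f2 = fit_variogram_model(lags, g, c)
        assert f1 == f2


class TestOrdinaryKriging:
    VG = VariogramModel("spherical", 0.0, 10.0, 500.0)

    def test_single_sample(self):
        t = make_table([(0.0, 0.0)], [13.0])
        pred, _ = krige_ordinary(t, self.VG, (100.0, 100.0))
        assert pred == pytest.approx(13.0)

    def test_equidistant_pair_symmetry(self):
        t = make_table([(0.0, 0.0), (100.0, 0.0)], [10.0, 30.0])
        ok = OrdinaryKriging(t.xy, t.nitrate, self.VG)
        w, _ = ok.weights((50.0, 0.0))
        assert w == pytest.approx([0.5, 0.5])
        assert ok.predict((50.0, 0.0))[0] == pytest.approx(20.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        t = make_table(rng.uniform(0, 1000, (15, 2)), rng.uniform(5, 50, 15))
        ok = OrdinaryKriging(t.xy, t.nitrate, self.VG)
        for target in rng.uniform(-200, 1200, (20, 2)):
            w, _ = ok.weights(tuple(target))
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exact_at_samples_zero_nugget(self):
        rng = np.random.default_rng(5)
        t = make_table(rng.uniform(0, 1000, (8, 2)), rng.uniform(5, 50, 8))
        for s in t:
            pred, var = krige_ordinary(t, self.VG, (s.x, s.y))
            assert pred == pytest.approx(s.nitrate, abs=1e-6)
            assert var == pytest.approx(0.0, abs=1e-6)

    def test_matches_covariance_form_oracle(self):
        # independent route: solve the kriging equations in covariance
        # form, C w + mu 1 = c, sum(w) = 1, with C = sill - gamma
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 1000, (5, 2))
        z = rng.uniform(5, 50, 5)
        t = make_table(xy, z)
        vg = VariogramModel("exponential", 1.0, 8.0, 400.0)
        target = (432.0, 521.0)

        sill = vg.sill
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        C = sill - np.asarray(vg.gamma(d))
        np.fill_diagonal(C, sill)
        d0 = np.sqrt(((xy - target) ** 2).sum(-1))
        c0 = sill - np.asarray(vg.gamma(d0))
        A = np.zeros((6, 6))
        A[:5, :5] = C
        A[:5, 5] = 1.0
        A[5, :5] = 1.0
        sol = np.linalg.solve(A, np.concatenate([c0, [1.0]]))
        expected = float(sol[:5] @ z)

        pred, _ = krige_ordinary(t, vg, target)
        assert pred == pytest.approx(expected, abs=1e-8)

    def test_duplicates_preaveraged(self):
        t = make_table([(0.0, 0.0), (0.0, 0.0), (100.0, 0.0)], [10.0, 20.0, 30.0])
        ok = OrdinaryKriging(t.xy, t.nitrate, self.VG)
        pred, _ = ok.predict((0.0, 0.0))
        assert pred == pytest.approx(15.0)


class TestIdw:
    def test_hand_computation(self):
        t = make_table([(0.0, 0.0), (1.0, 0.0)], [10.0, 20.0])
        # distances 0.25 and 0.75: weights 16 and 16/9, ratio 9:1
        assert idw_predict(t, 2.0, (0.25, 0.0)) == pytest.approx(11.0)

    def test_midpoint_is_mean(self):
        t = make_table([(0.0, 0.0), (10.0, 0.0)], [10.0, 30.0])
        for p in (0.5, 1.0, 2.0, 5.0):
            assert idw_predict(t, p, (5.0, 0.0)) == pytest.approx(20.0)

    def test_exact_on_sample(self, random_table):
        s = random_table[3]
        assert idw_predict(random_table, 2.0, (s.x, s.y)) == s.nitrate

    def test_k_nearest_restriction(self):
        t = make_table([(0.0, 0.0), (1.0, 0.0), (100.0, 0.0)], [10.0, 20.0, 1000.0])
        full = idw_predict(t, 2.0, (0.5, 0.1))
        k2 = idw_predict(t, 2.0, (0.5, 0.1), n_neighbors=2)
        assert k2 < full  # far high-valued point excluded
        assert 10.0 <= k2 <= 20.0


class TestThinPlateSpline:
    def test_plane_reproduction(self):
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 100, (8, 2))
        z = 20.0 + 0.3 * xy[:, 0] + 0.1 * xy[:, 1]
        t = make_table(xy, z)
        for target in [(10.0, 10.0), (50.0, 77.0), (120.0, -5.0)]:
            expected = 20.0 + 0.3 * target[0] + 0.1 * target[1]
            assert spline_tps_predict(t, 0.0, target) == pytest.approx(expected, abs=1e-6)

    def test_exact_interpolation(self, random_table):
        tps = ThinPlateSpline(random_table.xy, random_table.nitrate)
        for s in random_table:
            assert tps.predict((s.x, s.y)) == pytest.approx(s.nitrate, abs=1e-6)

    def test_matches_generic_solver_oracle(self):
        rng = np.random.default_rng(10)
        xy = rng.uniform(0, 50, (10, 2))
        z = rng.uniform(0, 10, 10)
        # independent route: assemble the same exact-interpolation system
        # and solve by least squares instead of the direct solver
        K = _tps_kernel(np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1)))
        P = np.column_stack([np.ones(10), xy])
        A = np.zeros((13, 13))
        A[:10, :10] = K
        A[:10, 10:] = P
        A[10:, :10] = P.T
        coef, *_ = np.linalg.lstsq(A, np.concatenate([z, np.zeros(3)]), rcond=None)
        target = (21.3, 34.7)
        r = np.sqrt(((xy - target) ** 2).sum(-1))
        expected = float(coef[:10] @ _tps_kernel(r) + coef[10]
                         + coef[11] * target[0] + coef[12] * target[1])
        assert spline_tps_predict(make_table(xy, z), 0.0, target) == pytest.approx(
            expected, abs=1e-8
        )

    def test_collinear_rejected(self):
        t = make_table([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            spline_tps_predict(t, 0.0, (0.5, 0.5))


class TestNaturalNeighbor:
    def test_coincident_target(self, random_table):
        s = random_table[2]
        assert natural_neighbor_predict(random_table, (s.x, s.y)) == s.nitrate

    def test_equilateral_centroid_equal_weights(self):
        h = np.sqrt(3.0)
        t = make_table([(0.0, 0.0), (2.0, 0.0), (1.0, h)], [1.0, 2.0, 3.0])
        idx, w = natural_neighbor_weights(t, (1.0, h / 3.0))
        assert len(w) == 3
        assert w == pytest.approx([1 / 3, 1 / 3, 1 / 3], abs=1e-9)

    def test_outside_hull_is_nodata(self, random_table):
        assert np.isnan(natural_neighbor_predict(random_table, (1e6, 1e6)))

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_weights_match_pixel_counting_oracle(self, seed):
        # discretized-area oracle: nearest-site rasterization before and
        # after inserting the target; stolen pixel counts approximate
        # the Sibson weights
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0.0, 1.0, (8, 2))
        t = make_table(xy, np.arange(8.0))
        target = np.array([0.5, 0.5]) + rng.uniform(-0.05, 0.05, 2)

        idx, w = natural_neighbor_weights(t, tuple(target))

        res = 1000  # 0.1% of the unit extent
        g = (np.arange(res) + 0.5) / res
        X, Y = np.meshgrid(g, g)
        pix = np.column_stack([X.ravel(), Y.ravel()])
        d_sites = ((pix[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        before = np.argmin(d_sites, axis=1)
        d_tgt = ((pix - target) ** 2).sum(-1)
        taken = d_tgt < d_sites.min(axis=1)
        stolen_counts = np.bincount(before[taken], minlength=8).astype(float)
        oracle = stolen_counts / stolen_counts.sum()

        ours = np.zeros(8)
        ours[idx] = w
        assert np.max(np.abs(ours - oracle)) < 0.01

    def test_convexity(self, random_table):
        z = random_table.nitrate
        rng = np.random.default_rng(31)
        lo, hi = random_table.xy.min(0), random_table.xy.max(0)
        for _ in range(10):
            target = rng.uniform(lo, hi)
            v = natural_neighbor_predict(random_table, tuple(target))
            if not np.isnan(v):
                assert z.min() - 1e-9 <= v <= z.max() + 1e-9


class TestSharedProperties:
    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.method)
    def test_constant_field_reproduced(self, spec):
        rng = np.random.default_rng(40)
        t = make_table(rng.uniform(0, 1000, (10, 2)), np.full(10, 23.5))
        predict = make_interpolator(t, spec)
        for target in rng.uniform(100, 900, (5, 2)):
            v = predict(tuple(target))
            if not np.isnan(v):
                assert v == pytest.approx(23.5, abs=1e-6)

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.method)
    def test_exact_at_sample_locations(self, spec, random_table):
        predict = make_interpolator(random_table, spec)
        for s in random_table:
            assert predict((s.x, s.y)) == pytest.approx(s.nitrate, abs=1e-6)

    @pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.method)
    def test_translation_invariance(self, spec, random_table):
        shift = np.array([12345.0, -9876.0])
        shifted = make_table(random_table.xy + shift, random_table.nitrate)
        p1 = make_interpolator(random_table, spec)
        p2 = make_interpolator(shifted, spec)
        rng = np.random.default_rng(41)
        lo, hi = random_table.xy.min(0), random_table.xy.max(0)
        for _ in range(5):
            target = rng.uniform(lo, hi)
            v1, v2 = p1(tuple(target)), p2(tuple(target + shift))
            if np.isnan(v1):
                assert np.isnan(v2)
            else:
                assert v1 == pytest.approx(v2, abs=1e-9 * max(1.0, abs(v1)))


class TestPredictGrid:
    def test_constant_surface(self):
        rng = np.random.default_rng(50)
        t = make_table(rng.uniform(0, 1000, (8, 2)), np.full(8, 15.0))
        s = predict_grid(t, InterpolatorSpec(method="idw"), 5, 5, 0.0, 0.0, 200.0)
        assert np.allclose(s.values, 15.0)

    def test_idw_bounded_by_samples(self, random_table):
        s = predict_grid(random_table, InterpolatorSpec(method="idw"),
                         20, 20, 0.0, 0.0, 50.0)
        z = random_table.nitrate
        finite = s.values[s.mask]
        assert np.all(finite >= z.min() - 1e-9) and np.all(finite <= z.max() + 1e-9)

    def test_kriging_exact_at_coincident_cells(self):
        # sample placed exactly on a cell centre, zero-nugget kriging
        t = make_table([(150.0, 150.0), (450.0, 250.0), (250.0, 450.0)],
                       [10.0, 20.0, 30.0])
        spec = InterpolatorSpec(
            method="kriging",
            variogram=VariogramModel("spherical", 0.0, 10.0, 600.0),
        )
        s = predict_grid(t, spec, 6, 6, 0.0, 0.0, 100.0)
        # cell centre (150, 150) is row nrows-2? compute: rows north-down
        X, Y = s.cell_centers()
        r, c = np.argwhere((X == 150.0) & (Y == 150.0))[0]
        assert s.values[r, c] == pytest.approx(10.0, abs=1e-6)

    def test_nn_outside_hull_nodata(self):
        t = make_table([(400.0, 400.0), (600.0, 400.0), (500.0, 600.0)],
                       [1.0, 2.0, 3.0])
        s = predict_grid(t, InterpolatorSpec(method="natural_neighbor"),
                         10, 10, 0.0, 0.0, 100.0)
        assert np.any(~s.mask)  # corners are outside the triangle
        assert np.any(s.mask)
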