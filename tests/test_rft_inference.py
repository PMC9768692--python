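import numpy as np
import pytest
from scipy import integrate, ndimage, special, stats

from geostatmap.core_grid import ObservationTable
from geostatmap.glm_engine import DesignSpec, build_design, fit_mass_univariate
from geostatmap.rft_inference import (
    SignificanceMap,
    conjunction,
    ec_density_t,
    estimate_fwhm,
    estimate_fwhm_from_responses,
    expected_ec,
    fwe_threshold,
    resel_counts,
    standardize_residuals,
    threshold_map,
)


def smoothed_noise_stack(rng, n_scans=30, size=128, fwhm=8.0):
    """Pseudo-residual stack: white Gaussian noise smoothed to a known FWHM,
    unit-normalized per cell."""
    sigma = fwhm / np.sqrt(8 * np.log(2))
    raw = rng.normal(size=(n_scans, size, size))
    sm = np.stack([ndimage.gaussian_filter(f, sigma, mode="wrap") for f in raw])
    return sm / np.sqrt((sm**2).sum(axis=0))


class TestStandardizeResiduals:
    def _fit(self, rng):
        X = rng.normal(size=(10, 2))
        locs = np.column_stack([np.linspace(1, 9, 10)] * 2)
        obs = ObservationTable(locs, X, ["a", "b"])
        d = build_design(obs, DesignSpec(("a", "b")))
        return fit_mass_univariate(rng.normal(size=(10, 4, 4)), d)

    def test_unit_norm_per_cell(self, rng):
        u = standardize_residuals(self._fit(rng))
        np.testing.assert_allclose((u**2).sum(axis=0), 1.0, atol=1e-12)

    def test_response_scaling_cancels(self, rng):
        X = rng.normal(size=(10, 2))
        locs = np.column_stack([np.linspace(1, 9, 10)] * 2)
        obs = ObservationTable(locs, X, ["a", "b"])
        d = build_design(obs, DesignSpec(("a", "b")))
        Y3 = rng.normal(size=(10, 4, 4))
        u1 = standardize_residuals(fit_mass_univariate(Y3, d))
        u2 = standardize_residuals(fit_mass_univariate(7.0 * Y3, d))
        np.testing.assert_allclose(u1, u2, atol=1e-12)

    def test_degenerate_cells_flagged_nan(self):
        # identical responses under a saturated two-condition design leave
        # zero residuals everywhere
        locs = np.column_stack([np.linspace(1, 9, 4)] * 2)
        obs = ObservationTable(locs, np.array([[0.0], [1.0], [0.0], [1.0]]),
                               ["z"])
        from geostatmap.glm_engine import one_hot_conditions

        d = build_design(one_hot_conditions(obs), DesignSpec(("cond_0", "cond_1")))
        fit = fit_mass_univariate(np.full((4, 2, 2), 0.3), d)
        u = standardize_residuals(fit)
        assert np.isnan(u).all()


class TestEstimateFwhm:
    def test_recovers_applied_smoothness(self):
        rng = np.random.default_rng(11)
        est = [estimate_fwhm(smoothed_noise_stack(rng, fwhm=8.0)) for _ in range(3)]
        fx = np.mean([e.fwhm_x for e in est])
        fy = np.mean([e.fwhm_y for e in est])
        assert fx == pytest.approx(8.0, rel=0.10)
        assert fy == pytest.approx(8.0, rel=0.10)

    def test_monotone_in_applied_smoothness(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        e8 = estimate_fwhm(smoothed_noise_stack(rng1, fwhm=8.0))
        e16 = estimate_fwhm(smoothed_noise_stack(rng2, fwhm=16.0))
        assert e16.fwhm_x > e8.fwhm_x and e16.fwhm_y > e8.fwhm_y

    def test_rigid_shift_leaves_estimate_nearly_unchanged(self):
        rng = np.random.default_rng(7)
        u = smoothed_noise_stack(rng, fwhm=8.0)
        e0 = estimate_fwhm(u)
        e1 = estimate_fwhm(np.roll(u, (0, 9, 17), axis=(0, 1, 2)))
        assert e1.fwhm_x == pytest.approx(e0.fwhm_x, rel=0.02)
        assert e1.fwhm_y == pytest.approx(e0.fwhm_y, rel=0.02)

    def test_flat_residuals_degenerate(self):
        u = np.ones((5, 8, 8)) / np.sqrt(5)
        with pytest.raises(ValueError, match="degenerate smoothness"):
            estimate_fwhm(u)

    def test_reduced_route_matches_residual_route(self, rng):
        X = rng.normal(size=(20, 3))
        locs = np.column_stack([np.linspace(1, 9, 20)] * 2)
        obs = ObservationTable(locs, X, ["a", "b", "c"])
        d = build_design(obs, DesignSpec(("a", "b", "c")))
        Y3 = rng.normal(size=(20, 10, 12))
        mask = np.ones((10, 12), bool)
        mask[:2, :3] = False
        fit = fit_mass_univariate(Y3, d, mask=mask)
        e1 = estimate_fwhm(standardize_residuals(fit), mask=mask)
        e2 = estimate_fwhm_from_responses(Y3, d.X, mask=mask)
        assert e2.fwhm_x == pytest.approx(e1.fwhm_x, rel=1e-9)
        assert e2.fwhm_y == pytest.approx(e1.fwhm_y, rel=1e-9)


class TestReselCounts:
    def test_full_rectangle(self):
        mask = np.ones((120, 120), bool)
        r0, r1, r2 = resel_counts(mask, 12.0, 12.0)
        assert (r0, r1, r2) == (1.0, 20.0, 100.0)

    def test_fwhm_equal_to_side_gives_one_resel(self):
        mask = np.ones((50, 50), bool)
        assert resel_counts(mask, 50.0, 50.0)[2] == pytest.approx(1.0)

    def test_doubling_fwhm_scales_counts(self):
        mask = np.ones((64, 80), bool)
        _, r1a, r2a = resel_counts(mask, 8.0, 8.0)
        _, r1b, r2b = resel_counts(mask, 16.0, 16.0)
        assert r1b == pytest.approx(r1a / 2)
        assert r2b == pytest.approx(r2a / 4)

    def test_irregular_mask_euler_characteristic(self):
        mask = np.ones((40, 40), bool)
        mask[10:20, 10:20] = False  # a hole: EC = 0
        r0, _, r2 = resel_counts(mask, 5.0, 5.0)
        assert r0 == 0.0
        assert r2 == pytest.approx((1600 - 100) / 25.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            resel_counts(np.zeros((5, 5), bool), 2.0, 2.0)


class TestEcDensities:
    def test_dimension_zero_is_student_upper_tail(self):
        assert ec_density_t(0.0, 10, 0) == pytest.approx(0.5)
        for t, nu in [(1.3, 5), (2.7, 30), (4.1, 100)]:
            assert ec_density_t(t, nu, 0) == pytest.approx(stats.t.sf(t, nu))

    def test_dimension_one_at_zero(self):
        assert ec_density_t(0.0, 7, 1) == pytest.approx(0.26503, abs=1e-4)

    def test_dimension_two_vanishes_at_zero(self):
        assert ec_density_t(0.0, 7, 2) == 0.0

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            ec_density_t(1.0, 7, 3)

    def test_upper_tail_against_quadrature_oracle(self, rng):
        # high-precision quadrature of the explicit Student density
        for _ in range(50):
            t = float(rng.uniform(0.0, 5.0))
            nu = int(rng.integers(3, 200))
            const = np.exp(
                special.gammaln((nu + 1) / 2) - special.gammaln(nu / 2)
            ) / np.sqrt(nu * np.pi)
            val, _ = integrate.quad(
                lambda x: const * (1 + x * x / nu) ** (-(nu + 1) / 2), t, np.inf
            )
            assert ec_density_t(t, nu, 0) == pytest.approx(val, abs=1e-8)


class TestFweThreshold:
    def test_point_domain_reduces_to_student_quantile(self):
        thr = fwe_threshold(0.05, 30, (1.0, 0.0, 0.0), 1)
        assert thr == pytest.approx(stats.t.isf(0.05, 30), abs=1e-6)

    def test_threshold_increases_with_search_volume(self):
        a = fwe_threshold(0.05, 100, (1.0, 20.0, 100.0), 10000)
        b = fwe_threshold(0.05, 100, (1.0, 20.0, 1000.0), 10000)
        assert b > a

    def test_decreasing_in_alpha(self):
        t1 = fwe_threshold(0.01, 50, (1.0, 10.0, 50.0), 5000)
        t2 = fwe_threshold(0.05, 50, (1.0, 10.0, 50.0), 5000)
        assert t1 > t2

    def test_never_exceeds_bonferroni(self):
        for resels in [(1.0, 20.0, 100.0), (1.0, 200.0, 5000.0)]:
            thr = fwe_threshold(0.05, 60, resels, 14400)
            assert thr <= stats.t.isf(0.05 / 14400, 60) + 1e-12

    def test_against_independent_bisection_oracle(self):
        alpha, nu, resels = 0.05, 1596, (1.0, 20.0, 100.0)
        lo, hi = 1.0, 50.0
        for _ in range(200):  # bisection to ~1e-12
            mid = 0.5 * (lo + hi)
            if expected_ec(mid, nu, resels) > alpha:
                lo = mid
            else:
                hi = mid
        t_bisect = 0.5 * (lo + hi)
        thr = fwe_threshold(alpha, nu, resels, 10**9)  # Bonferroni far above
        assert thr == pytest.approx(t_bisect, abs=1e-9)

    def test_two_tailed_uses_half_alpha(self):
        one = fwe_threshold(0.05, 40, (1.0, 10.0, 40.0), 4000, tails="one")
        two = fwe_threshold(0.05, 40, (1.0, 10.0, 40.0), 4000, tails="two")
        assert two == pytest.approx(
            fwe_threshold(0.025, 40, (1.0, 10.0, 40.0), 4000, tails="one")
        )
        assert two > one


class TestThresholdMap:
    def test_zero_map_is_empty(self):
        sm = threshold_map(np.zeros((5, 5)), 3.0)
        assert not sm.significant.any()

    def test_one_tailed_ignores_negative_extremes(self):
        t = np.full((4, 4), -50.0)
        assert not threshold_map(t, 3.0, tails="one").significant.any()

    def test_two_tailed_is_symmetric(self):
        t = np.zeros((3, 3))
        t[0, 0], t[2, 2] = 3.01, -3.01
        sm = threshold_map(t, 3.0, tails="two")
        assert sm.significant[0, 0] and sm.significant[2, 2]
        assert sm.n_significant == 2

    def test_mask_excludes_cells(self):
        t = np.full((3, 3), 10.0)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        sm = threshold_map(t, 3.0, mask=mask)
        assert sm.n_significant == 1

    def test_significant_must_be_inside_mask(self):
        with pytest.raises(ValueError, match="within the mask"):
            SignificanceMap(3.0, 0.05, "one", np.zeros((2, 2), bool),
                            np.ones((2, 2), bool))


class TestConjunction:
    def _sig(self, arr):
        arr = np.asarray(arr, bool)
        return SignificanceMap(3.0, 0.05, "one", np.ones_like(arr, bool), arr)

    def test_idempotent(self, rng):
        m = self._sig(rng.random((6, 6)) > 0.5)
        assert np.array_equal(conjunction([m, m]), m.significant)

    def test_empty_absorbs(self, rng):
        m = self._sig(rng.random((6, 6)) > 0.5)
        empty = self._sig(np.zeros((6, 6), bool))
        assert not conjunction([m, empty]).any()

    def test_three_maps_single_common_cell(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        c = np.zeros((4, 4), bool)
        a[1, 1] = a[0, 0] = True
        b[1, 1] = b[3, 3] = True
        c[1, 1] = c[2, 0] = True
        out = conjunction([self._sig(a), self._sig(b), self._sig(c)])
        assert out.sum() == 1 and out[1, 1]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="different grids"):
            conjunction([self._sig(np.zeros((3, 3), bool)),
                         self._sig(np.zeros((4, 4), bool))])
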