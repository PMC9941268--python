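"""Cubic lactate-curve fitting and LT1/LT2 detection against oracles."""

import numpy as np
import pytest

from vlt2model.errors import (
    DegenerateCurveError,
    InsufficientDataError,
    NoFirstRiseError,
)
from vlt2model.lactate import (
    LactateFit,
    fit_lactate_polynomial,
    locate_LT1,
    locate_LT2,
)


def fit_from_coefficients(c0, c1, c2, c3, v_lo=2.0, v_hi=4.4):
    return LactateFit(
        coefficients=(c0, c1, c2, c3), v_lo=v_lo, v_hi=v_hi,
        r_squared=1.0, n_points=6,
    )


def random_admissible_fit(rng):
    """Cubic fitted to a noisy convex rising curve on the protocol grid."""
    speeds = np.arange(2.4, 4.01, 0.4)
    la = 1.0 + 0.15 * (speeds - 2.4) + np.exp(1.8 * (speeds - 3.3))
    la = la + rng.normal(0, 0.1, speeds.size)
    la = np.maximum.accumulate(np.maximum(la, 0.1))
    return fit_lactate_polynomial(list(zip(speeds, la)))


class TestFit:
    def test_exact_cubic_recovered(self):
        c = (0.8, 0.1, 0.05, 0.2)
        v = np.array([2.4, 2.8, 3.2, 3.6, 4.0, 4.4])
        la = c[0] + c[1] * v + c[2] * v**2 + c[3] * v**3
        fit = fit_lactate_polynomial(list(zip(v, la)))
        assert fit.coefficients == pytest.approx(c, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert (fit.v_lo, fit.v_hi) == (2.4, 4.4)

    def test_matches_normal_equations_oracle(self, rng):
        """Seven noisy points vs an explicit (XᵀX)⁻¹Xᵀy solve."""
        v = np.array([2.4, 2.8, 3.2, 3.6, 4.0, 4.4, 4.8])
        la = 1.0 + np.exp(1.2 * (v - 3.5)) + rng.normal(0, 0.2, v.size)
        la = np.abs(la)
        fit = fit_lactate_polynomial(list(zip(v, la)))
        X = np.column_stack([np.ones_like(v), v, v**2, v**3])
        beta = np.linalg.solve(X.T @ X, X.T @ la)
        assert fit.coefficients == pytest.approx(tuple(beta), abs=1e-8)

    def test_three_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_lactate_polynomial([(2.4, 1.0), (2.8, 1.5), (3.2, 3.0)])

    def test_repeated_single_speed_insufficient(self):
        pts = [(2.4, x) for x in (1.0, 1.1, 1.2, 1.3)]
        with pytest.raises(InsufficientDataError):
            fit_lactate_polynomial(pts)


class TestLT1:
    def test_analytic_quadratic(self):
        # la = 1 + 0.5(v − 2.4)²: slope (v − 2.4) = 1 at v = 3.4
        fit = fit_from_coefficients(1 + 0.5 * 2.4**2, -2.4, 0.5, 0.0)
        v1, la1 = locate_LT1(fit)
        assert v1 == pytest.approx(3.4, abs=1e-12)
        assert la1 == pytest.approx(1 + 0.5, abs=1e-12)

    def test_matches_grid_oracle(self, rng):
        for _ in range(20):
            fit = random_admissible_fit(rng)
            try:
                v1, _ = locate_LT1(fit)
            except NoFirstRiseError:
                continue
            grid = np.arange(fit.v_lo, fit.v_hi, 1e-4)
            sl = np.asarray(fit.derivative(grid))
            # upward crossings of the slope criterion
            crossing = (sl[:-1] < 1.0) & (sl[1:] >= 1.0)
            if not crossing.any():
                # criterion already exceeded at the domain edge with slope
                # rising: the crossing clips to the edge
                assert sl[0] >= 1.0 - 1e-6
                continue
            assert abs(v1 - grid[:-1][crossing][0]) < 1e-3

    def test_monotone_decreasing_curve_fails(self):
        fit = fit_from_coefficients(10.0, -0.5, 0.0, 0.0)
        with pytest.raises(NoFirstRiseError):
            locate_LT1(fit)

    def test_slope_criterion_is_absolute_not_scale_invariant(self):
        """Rescaling all lactates moves the slope-1.00 point (guards units:
        the criterion is absolute, not shape-relative)."""
        speeds = np.arange(2.4, 4.01, 0.4)
        la = 1.0 + np.exp(2.2 * (speeds - 3.2))
        fit = fit_lactate_polynomial(list(zip(speeds, la)))
        fit_half = fit_lactate_polynomial(list(zip(speeds, 0.5 * la)))
        v1, _ = locate_LT1(fit)
        v1_scaled, _ = locate_LT1(fit_half)
        assert v1_scaled > v1 + 0.05  # shallower curve reaches slope 1 later


class TestLT2:
    def test_symmetric_parabola_peaks_at_center(self):
        # la = (v − 3)², chord between v=2 and v=4 at equal heights
        fit = fit_from_coefficients(9.0, -6.0, 1.0, 0.0)
        th = locate_LT2(fit, (2.0, float(fit(2.0))), (4.0, float(fit(4.0))))
        assert th.v_lt2 == pytest.approx(3.0, abs=1e-9)
        assert th.dmax_distance == pytest.approx(1.0, abs=1e-9)  # horizontal chord

    def test_interior_maximum_and_positive_distance(self, rng):
        for _ in range(20):
            fit = random_admissible_fit(rng)
            try:
                lt1 = locate_LT1(fit)
            except NoFirstRiseError:
                continue
            peak = (fit.v_hi, float(fit(fit.v_hi)) + 2.0)
            th = locate_LT2(fit, lt1, peak)
            assert lt1[0] < th.v_lt2 < peak[0]
            assert th.dmax_distance > 0

    def test_matches_grid_oracle(self, rng):
        for _ in range(20):
            fit = random_admissible_fit(rng)
            try:
                lt1 = locate_LT1(fit)
            except NoFirstRiseError:
                continue
            peak = (fit.v_hi + 0.4, float(fit(fit.v_hi + 0.4)) + 1.5)
            th = locate_LT2(fit, lt1, peak)
            v1, la1 = lt1
            m = (peak[1] - la1) / (peak[0] - v1)
            grid = np.arange(v1 + 1e-4, peak[0], 1e-4)
            dev = (la1 + m * (grid - v1)) - np.asarray(fit(grid))
            # interior local maxima of the sag (parallel-tangent points)
            local = (
                (dev[1:-1] >= dev[:-2]) & (dev[1:-1] >= dev[2:])
            ).nonzero()[0] + 1
            assert local.size
            assert abs(th.v_lt2 - grid[local[np.argmax(dev[local])]]) < 1e-3

    def test_curve_above_chord_is_degenerate(self):
        # concave curve bulging above the chord: no sag below it
        fit = fit_from_coefficients(-9.0, 6.0, -1.0, 0.0)  # −(v−3)²
        with pytest.raises(DegenerateCurveError):
            locate_LT2(fit, (2.0, float(fit(2.0))), (4.0, float(fit(4.0))))

    def test_translation_equivariance(self, rng):
        """Shifting all speeds by Δ shifts both thresholds by Δ (1e-9)."""
        speeds = np.arange(2.4, 4.01, 0.4)
        la = 1.0 + 0.1 * (speeds - 2.4) + np.exp(1.5 * (speeds - 3.4))
        delta = 1.25
        for sign in (1, -1):
            d = sign * delta
            fit = fit_lactate_polynomial(list(zip(speeds, la)))
            fit_s = fit_lactate_polynomial(list(zip(speeds + d, la)))
            lt1 = locate_LT1(fit)
            lt1_s = locate_LT1(fit_s)
            assert lt1_s[0] - lt1[0] == pytest.approx(d, abs=1e-9)
            peak = (4.4, float(fit(4.4)) + 1.0)
            peak_s = (4.4 + d, peak[1])
            th = locate_LT2(fit, lt1, peak)
            th_s = locate_LT2(fit_s, lt1_s, peak_s)
            assert th_s.v_lt2 - th.v_lt2 == pytest.approx(d, abs=1e-9)
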