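"""Lactate–speed curve fitting and threshold detection.

The blood-lactate concentrations measured at the end of each completed stage
are fitted against running speed with a third-order polynomial.  Two
thresholds are then derived from the fitted curve:

* **LT1** — the first rise of lactate above baseline, defined as the
  smallest speed at which the slope of the fitted curve equals the slope
  criterion (default 1.00 mmol·L⁻¹ per m·s⁻¹) while the slope is still
  increasing (ascending limb).
* **LT2** — the modified maximal-deviation (Dmax) point: the speed, between
  LT1 and the peak lactate point, at which the fitted curve lies furthest
  (perpendicular distance, raw axis units) below the straight chord joining
  the LT1 point and the peak lactate point.

The peak lactate point defaults to the highest speed attained paired with
the larger of the final-stage and post-test lactate concentrations; a
"fitted" policy (curve value at top speed) is available.  When the top
attained speed comes from an uncompleted final stage it lies one protocol
increment beyond the fitted domain and the cubic is extrapolated to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigError,
    DegenerateCurveError,
    InsufficientDataError,
    NoFirstRiseError,
)
from .types import TestSession

#: default LT1 slope criterion, mmol·L⁻¹ per m·s⁻¹
SLOPE_CRITERION = 1.00

_GRID_STEP = 1e-4  # m/s, fallback grid for the maximizer


@dataclass(frozen=True)
class LactateFit:
    """Cubic la(v) = c0 + c1·v + c2·v² + c3·v³ with its fit diagnostics."""

    coefficients: tuple[float, float, float, float]  # (c0, c1, c2, c3)
    v_lo: float
    v_hi: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise InsufficientDataError(
                f"cubic lactate fit needs >= 4 points, got {self.n_points}"
            )
        if not self.v_lo < self.v_hi:
            raise ValueError("fit domain must have v_lo < v_hi")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def __call__(self, v: float | np.ndarray) -> float | np.ndarray:
        c0, c1, c2, c3 = self.coefficients
        return c0 + v * (c1 + v * (c2 + v * c3))

    def derivative(self, v: float | np.ndarray) -> float | np.ndarray:
        _, c1, c2, c3 = self.coefficients
        return c1 + 2 * c2 * v + 3 * c3 * v**2


@dataclass(frozen=True)
class Thresholds:
    """LT1 and LT2 locations on a fitted lactate curve."""

    v_lt1: float  # m/s
    la_lt1: float  # mmol/L
    v_lt2: float  # m/s
    la_lt2: float  # mmol/L
    dmax_distance: float  # perpendicular distance, raw axis units
    peak_point: tuple[float, float]  # (v_peak m/s, la_peak mmol/L)

    def __post_init__(self) -> None:
        if not self.v_lt1 < self.v_lt2 < self.peak_point[0]:
            raise ValueError(
                f"threshold ordering violated: LT1 {self.v_lt1} < LT2 "
                f"{self.v_lt2} < peak {self.peak_point[0]} required"
            )
        if not self.dmax_distance > 0:
            raise ValueError("dmax_distance must be positive")


def fit_lactate_polynomial(
    points: Iterable[tuple[float, float]],
) -> LactateFit:
    """Ordinary least-squares cubic fit of lactate on speed.

    Requires at least four distinct speeds.  The fit domain is
    [min speed, max speed] of the input points.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (speed, lactate) pairs")
    v, la = pts[:, 0], pts[:, 1]
    if np.any(la < 0):
        raise ValueError("lactate concentrations must be non-negative")
    if len(np.unique(v)) < 4:
        raise InsufficientDataError(
            f"cubic lactate fit needs >= 4 distinct speeds, got {len(np.unique(v))}"
        )
    X = np.vander(v, 4, increasing=True)
    beta, _, rank, _ = np.linalg.lstsq(X, la, rcond=None)
    if rank < 4:
        raise InsufficientDataError("degenerate design: speeds are collinear")
    resid = la - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((la - la.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return LactateFit(
        coefficients=tuple(float(b) for b in beta),
        v_lo=float(v.min()),
        v_hi=float(v.max()),
        r_squared=min(r2, 1.0),
        n_points=len(v),
    )


def _slope_roots(fit: LactateFit, slope: float) -> np.ndarray:
    """Real solutions of la'(v) = slope, ascending."""
    _, c1, c2, c3 = fit.coefficients
    # 3*c3*v^2 + 2*c2*v + (c1 - slope) = 0
    if abs(c3) < 1e-14:
        if abs(c2) < 1e-14:
            return np.array([])
        return np.array([(slope - c1) / (2 * c2)])
    roots = np.roots([3 * c3, 2 * c2, c1 - slope])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real)


def locate_LT1(
    fit: LactateFit, slope_criterion: float = SLOPE_CRITERION
) -> tuple[float, float]:
    """First speed where the fitted slope reaches the criterion on a rising limb.

    Returns ``(v_lt1, la_lt1)``.  Raises :class:`NoFirstRiseError` if no
    qualifying root lies in the fit domain.
    """
    _, c1, c2, c3 = fit.coefficients
    tol = 1e-9
    for v in _slope_roots(fit, slope_criterion):
        if fit.v_lo - tol <= v <= fit.v_hi + tol:
            # second derivative > 0: slope is increasing (ascending limb)
            if 2 * c2 + 6 * c3 * v > 0:
                v = float(np.clip(v, fit.v_lo, fit.v_hi))
                return v, float(fit(v))
    raise NoFirstRiseError(
        f"no speed in [{fit.v_lo:.2f}, {fit.v_hi:.2f}] with rising slope "
        f"= {slope_criterion}"
    )


def locate_LT2(
    fit: LactateFit,
    lt1: tuple[float, float],
    peak_point: tuple[float, float],
) -> Thresholds:
    """Modified maximal-deviation point between LT1 and the peak lactate point.

    Maximizes the perpendicular distance from the fitted curve to the chord
    through the LT1 and peak points, in raw axis units.  The stationary
    points of the vertical deviation (where the curve slope equals the chord
    slope) are solved analytically; a 1e-4 m·s⁻¹ grid is the fallback.  Ties
    between equal maxima resolve to the smaller speed.
    """
    v1, la1 = lt1
    vp, lap = peak_point
    if not v1 < vp:
        raise ValueError(f"LT1 speed {v1} must lie below peak speed {vp}")
    m = (lap - la1) / (vp - v1)

    def deviation(v: np.ndarray | float) -> np.ndarray | float:
        # chord minus curve: positive where the curve sags below the chord
        return (la1 + m * (np.asarray(v) - v1)) - np.asarray(fit(v))

    candidates = [v for v in _slope_roots(fit, m) if v1 < v < vp]
    best_v, best_d = None, 0.0
    for v in sorted(candidates):
        d = float(deviation(v))
        if d > best_d + 1e-15:
            best_v, best_d = float(v), d
    if best_v is None:
        # fallback: interior local maxima of the deviation on a fine grid
        # (the boundary at the peak point is not a curve maximum — the
        # measured peak lactate generally sits above the fitted curve)
        grid = np.arange(v1 + _GRID_STEP, vp, _GRID_STEP)
        if grid.size >= 3:
            devs = np.asarray(deviation(grid))
            interior = (
                (devs[1:-1] >= devs[:-2]) & (devs[1:-1] >= devs[2:])
            ).nonzero()[0] + 1
            if interior.size:
                i = interior[int(np.argmax(devs[interior]))]
                if devs[i] > 0:
                    best_v, best_d = float(grid[i]), float(devs[i])
    if best_v is None:
        raise DegenerateCurveError(
            "lactate curve lies on or above the LT1-peak chord throughout"
        )
    return Thresholds(
        v_lt1=v1,
        la_lt1=la1,
        v_lt2=best_v,
        la_lt2=float(fit(best_v)),
        dmax_distance=best_d / float(np.hypot(1.0, m)),
        peak_point=(vp, lap),
    )


def peak_lactate_point(
    session: TestSession, fit: LactateFit, policy: str = "measured"
) -> tuple[float, float]:
    """Peak lactate point anchoring the Dmax chord.

    ``measured`` (default): highest speed attained with the larger of the
    final-stage and post-test lactate.  ``fitted``: the fitted curve's value
    at the highest speed attained.
    """
    v_top = session.top_speed
    if policy == "measured":
        la = max(session.stages[-1].lactate, session.post_test_lactate)
    elif policy == "fitted":
        la = float(fit(v_top))
    else:
        raise ConfigError(f"unknown peak-point policy {policy!r}")
    return v_top, la


def detect_thresholds(
    session: TestSession,
    slope_criterion: float = SLOPE_CRITERION,
    peak_policy: str = "measured",
) -> tuple[LactateFit, Thresholds]:
    """Per-session chain: cubic fit on completed stages, LT1, then LT2."""
    pts: Sequence[tuple[float, float]] = [
        (s.speed, s.lactate) for s in session.completed_stages
    ]
    fit = fit_lactate_polynomial(pts)
    lt1 = locate_LT1(fit, slope_criterion)
    peak = peak_lactate_point(session, fit, peak_policy)
    thresholds = locate_LT2(fit, lt1, peak)
    return fit, thresholds
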