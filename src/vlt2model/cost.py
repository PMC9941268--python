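"""Cost of running, the speed–VO2 regression, and fractional utilization.

Cost of running (C_R) is the oxygen used per kilogram per meter,
``vo2 / (speed · 60)``, evaluated at one of three anchors:

* ``fix``   — the fixed submaximal speed 2.8 m·s⁻¹ (the protocol's second
  stage), VO2 taken from that stage's steady state;
* ``lt1``   — the speed at the first lactate threshold, VO2 (and RER/VE)
  linearly interpolated between the adjacent stage steady states;
* ``pct80`` — the speed at 80% of VO2peak from the linear speed–VO2
  regression over the submaximal stages, with VO2 = 0.8·VO2peak by
  construction.

Oxygen cost is converted to energy cost (J·kg⁻¹·m⁻¹) with the linear
non-protein caloric-equivalent table (4.686 kcal·L⁻¹ at RER 0.707 rising to
5.047 at RER 1.00), RER clamped to that range by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    ConfigError,
    ExtrapolationError,
    ImplausibleUtilizationError,
    InsufficientDataError,
    MissingStageError,
)
from .types import FIXED_COST_SPEED, TestSession
from .units import JOULE_PER_CAL, SEC_PER_MIN

R2_WARNING_LEVEL = 0.92  # submaximal speed-VO2 linearity reported for tests
UTILIZATION_GUARD = 1.05  # LT2% above this is a measurement inconsistency

_RER_LO, _E_LO = 0.707, 4.686  # kcal/L at pure fat oxidation
_RER_HI, _E_HI = 1.000, 5.047  # kcal/L at pure carbohydrate oxidation


@dataclass(frozen=True)
class SpeedVo2Regression:
    """OLS of steady-state VO2 on speed over the submaximal stages."""

    intercept: float  # mL/kg/min
    slope: float  # mL/kg/min per m/s
    r_squared: float
    n_stages: int

    def predict(self, v: float) -> float:
        return self.intercept + self.slope * v


@dataclass(frozen=True)
class CostOfRunning:
    """One cost-of-running determination."""

    method: str  # fix | lt1 | pct80
    anchor_speed: float  # m/s
    vo2_at_anchor: float  # mL/kg/min
    rer_at_anchor: Optional[float]
    oxygen_cost: float  # mL/kg/m
    energy_cost: Optional[float]  # J/kg/m
    ve_at_anchor: Optional[float] = None  # L/min

    def __post_init__(self) -> None:
        if not self.oxygen_cost > 0:
            raise ValueError("oxygen cost must be positive")


def fit_speed_vo2_regression(
    session: TestSession, v_lt2: float
) -> SpeedVo2Regression:
    """Linear regression of VO2 on speed over completed submaximal stages
    (speed <= v_lt2).  Needs at least two such stages."""
    sub = [s for s in session.completed_stages if s.speed <= v_lt2 + 1e-9]
    if len(sub) < 2:
        raise InsufficientDataError(
            f"need >= 2 completed submaximal stages, got {len(sub)}"
        )
    v = np.array([s.speed for s in sub])
    y = np.array([s.vo2 for s in sub])
    slope, intercept = np.polyfit(v, y, 1)
    pred = intercept + slope * v
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return SpeedVo2Regression(
        intercept=float(intercept),
        slope=float(slope),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_stages=len(sub),
    )


def speed_at_fraction(
    reg: SpeedVo2Regression, vo2peak: float, fraction: float = 0.80
) -> float:
    """Speed eliciting ``fraction``·VO2peak on the regression line."""
    if not reg.slope > 0:
        raise ValueError(f"speed-VO2 slope must be positive, got {reg.slope}")
    return (fraction * vo2peak - reg.intercept) / reg.slope


def _interp_channel(session: TestSession, attr: str, v: float) -> Optional[float]:
    """Piecewise-linear interpolation of a stage channel at speed v."""
    pts = [
        (s.speed, getattr(s, attr))
        for s in session.completed_stages
        if getattr(s, attr) is not None
    ]
    if len(pts) < 2:
        return None
    speeds = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    if v < speeds[0] - 1e-9 or v > speeds[-1] + 1e-9:
        raise ExtrapolationError(
            f"anchor speed {v:.3f} outside stage range "
            f"[{speeds[0]:.2f}, {speeds[-1]:.2f}] for channel {attr}"
        )
    return float(np.interp(v, speeds, vals))


def energy_equivalent(rer: float, policy: str = "clip") -> float:
    """Caloric equivalent of oxygen in J per mL as a linear function of RER.

    ``clip`` (default) clamps RER to [0.707, 1.00]; ``extrapolate`` extends
    the line beyond the table.
    """
    if not rer > 0:
        raise ValueError("RER must be positive")
    if policy == "clip":
        rer = min(max(rer, _RER_LO), _RER_HI)
    elif policy != "extrapolate":
        raise ConfigError(f"unknown energy policy {policy!r}")
    kcal_per_l = _E_LO + (rer - _RER_LO) * (_E_HI - _E_LO) / (_RER_HI - _RER_LO)
    return kcal_per_l * JOULE_PER_CAL


def cost_of_running(
    session: TestSession,
    method: str,
    v_lt1: Optional[float] = None,
    vo2peak: Optional[float] = None,
    reg: Optional[SpeedVo2Regression] = None,
    energy_policy: str = "clip",
    fraction: float = 0.80,
) -> CostOfRunning:
    """One cost-of-running determination (see module docstring)."""
    if method == "fix":
        stage = next(
            (
                s
                for s in session.completed_stages
                if abs(s.speed - FIXED_COST_SPEED) < 1e-9
            ),
            None,
        )
        if stage is None:
            raise MissingStageError(
                f"no completed stage at {FIXED_COST_SPEED} m/s in session "
                f"{session.athlete_id}"
            )
        anchor, vo2 = stage.speed, stage.vo2
        rer, ve = stage.rer, stage.ve
    elif method == "lt1":
        if v_lt1 is None:
            raise ValueError("lt1 method requires v_lt1")
        anchor = v_lt1
        vo2 = _interp_channel(session, "vo2", anchor)
        if vo2 is None:
            raise InsufficientDataError("cannot interpolate VO2 at LT1")
        rer = _try_interp(session, "rer", anchor)
        ve = _try_interp(session, "ve", anchor)
    elif method == "pct80":
        if vo2peak is None or reg is None:
            raise ValueError("pct80 method requires vo2peak and the regression")
        anchor = speed_at_fraction(reg, vo2peak, fraction)
        vo2 = fraction * vo2peak
        rer = _try_interp(session, "rer", anchor)
        ve = _try_interp(session, "ve", anchor)
    else:
        raise ConfigError(f"unknown cost-of-running method {method!r}")

    oxygen_cost = vo2 / (anchor * SEC_PER_MIN)
    energy = None if rer is None else oxygen_cost * energy_equivalent(rer, energy_policy)
    return CostOfRunning(
        method=method,
        anchor_speed=float(anchor),
        vo2_at_anchor=float(vo2),
        rer_at_anchor=rer,
        oxygen_cost=float(oxygen_cost),
        energy_cost=energy,
        ve_at_anchor=ve,
    )


def _try_interp(session: TestSession, attr: str, v: float) -> Optional[float]:
    """Interpolate a secondary channel, tolerating slight extrapolation by
    clamping to the nearest stage (RER/VE at the pct80 anchor can sit just
    above the last submaximal stage)."""
    pts = [
        (s.speed, getattr(s, attr))
        for s in session.completed_stages
        if getattr(s, attr) is not None
    ]
    if len(pts) < 2:
        return None
    speeds = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    return float(np.interp(v, speeds, vals))


def vo2_at_speed(session: TestSession, v: float, reg: SpeedVo2Regression) -> float:
    """Steady-state VO2 at an arbitrary speed: interpolated between stages
    inside the completed range, extended with the regression line beyond it
    (the Dmax point can fall between the last completed and the final
    attempted stage)."""
    speeds = [s.speed for s in session.completed_stages]
    if speeds and speeds[0] - 1e-9 <= v <= speeds[-1] + 1e-9:
        vo2 = _interp_channel(session, "vo2", v)
        if vo2 is not None:
            return vo2
    return reg.predict(v)


def fractional_utilization(vo2_at_lt2: float, vo2peak: float) -> float:
    """LT2% — the fraction of VO2peak used at the second lactate threshold."""
    if not (vo2_at_lt2 > 0 and vo2peak > 0):
        raise ValueError("VO2 values must be positive")
    ratio = vo2_at_lt2 / vo2peak
    if ratio > UTILIZATION_GUARD:
        raise ImplausibleUtilizationError(
            f"fractional utilization {ratio:.3f} exceeds plausibility guard "
            f"{UTILIZATION_GUARD}"
        )
    return ratio
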