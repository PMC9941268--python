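"""The endurance-performance model and the per-athlete assembly chain.

The classical model expresses the running speed sustainable at the second
lactate threshold as

    vLT2 = LT2% · VO2peak / (C_R · 60)          [m·s⁻¹]

with LT2% the fractional utilization (fraction of VO2peak at LT2), VO2peak
in mL·kg⁻¹·min⁻¹ and C_R the oxygen cost of running in mL·kg⁻¹·m⁻¹; the
factor 60 bridges the per-minute VO2 to the per-second speed.  The model is
algebraically exact when C_R is the athlete's true cost at vLT2 itself —
accuracy hinges on where C_R is anchored, which is why three determinations
(fixed speed, LT1, 80% VO2peak) are carried side by side.

``assemble_metrics`` runs the whole per-athlete chain (thresholds → VO2peak
→ regression → three C_R → LT2% → three modeled speeds) and converts
athlete-level algorithm failures into flags instead of exceptions, so a
cohort run never aborts on one bad lactate curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from . import cost as cost_mod
from .errors import Vlt2Error
from .gas import apmhr_fox, check_exhaustion, session_vo2peak
from .lactate import SLOPE_CRITERION, detect_thresholds
from .types import PROTOCOL_START_SPEED, AthleteMetrics, TestSession
from .units import SEC_PER_MIN


def calculate_vlt2(lt2_pct: float, vo2peak: float, oxygen_cost: float) -> float:
    """Modeled threshold speed, LT2% · VO2peak / (C_R · 60), in m·s⁻¹.

    ``lt2_pct`` is a fraction (0.87, not 87).  Pure function, no rounding.
    """
    if not (lt2_pct > 0 and vo2peak > 0):
        raise ValueError("LT2% and VO2peak must be positive")
    if not oxygen_cost > 0:
        raise ValueError(f"oxygen cost must be positive, got {oxygen_cost}")
    return lt2_pct * vo2peak / (oxygen_cost * SEC_PER_MIN)


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the per-athlete chain (defaults follow the study protocol)."""

    slope_criterion: float = SLOPE_CRITERION  # mmol/L per m/s
    slope_units: str = "ms"  # "ms" | "kmh" (criterion per km/h, rescaled)
    peak_policy: str = "measured"  # peak lactate point definition
    energy_policy: str = "clip"  # caloric-equivalent handling beyond table
    exhaustion_k: int = 2  # objective criteria required besides volitional
    apmhr_formula: Callable[[float], float] = field(default=apmhr_fox)
    fraction: float = 0.80  # VO2peak fraction for the pct80 anchor

    def slope_criterion_ms(self) -> float:
        if self.slope_units == "ms":
            return self.slope_criterion
        if self.slope_units == "kmh":
            # d la / d v[m/s] = d la / d v[km/h] * 3.6
            return self.slope_criterion * 3.6
        raise ValueError(f"unknown slope units {self.slope_units!r}")


def assemble_metrics(
    session: TestSession, options: AnalysisOptions = AnalysisOptions()
) -> AthleteMetrics:
    """Run the full modeling chain for one session; failures become flags."""
    m = AthleteMetrics(
        athlete_id=session.athlete_id,
        sex=session.sex,
        age=session.age,
        n_completed_stages=session.n_completed,
    )
    flags: list[str] = []

    m.vo2peak = session_vo2peak(session)
    ex = check_exhaustion(
        session,
        apmhr_formula=options.apmhr_formula,
        required_criteria=options.exhaustion_k,
    )
    m.exhaustion_verified = ex.verified
    if not ex.verified:
        flags.append("exhaustion_not_verified")

    thresholds = None
    try:
        _, thresholds = detect_thresholds(
            session,
            slope_criterion=options.slope_criterion_ms(),
            peak_policy=options.peak_policy,
        )
        m.v_lt1 = thresholds.v_lt1
        m.v_lt2 = thresholds.v_lt2
    except Vlt2Error:
        flags.append("invalid_thresholds")

    reg = None
    if thresholds is not None:
        try:
            reg = cost_mod.fit_speed_vo2_regression(session, thresholds.v_lt2)
            if reg.r_squared < cost_mod.R2_WARNING_LEVEL:
                flags.append("low_speed_vo2_r2")
        except Vlt2Error:
            flags.append("no_speed_vo2_regression")

    if reg is not None:
        try:
            m.v80 = cost_mod.speed_at_fraction(reg, m.vo2peak, options.fraction)
            m.v80_in_range = (
                PROTOCOL_START_SPEED - 1e-9 <= m.v80 <= session.top_speed + 1e-9
            )
            if not m.v80_in_range:
                flags.append("v80_out_of_range")
        except Vlt2Error:
            flags.append("v80_failed")

    costs: dict[str, Optional[cost_mod.CostOfRunning]] = {}
    for method in ("fix", "lt1", "pct80"):
        costs[method] = None
        if method == "lt1" and thresholds is None:
            continue
        if method == "pct80" and (reg is None or not m.v80_in_range):
            continue
        try:
            costs[method] = cost_mod.cost_of_running(
                session,
                method,
                v_lt1=m.v_lt1,
                vo2peak=m.vo2peak,
                reg=reg,
                energy_policy=options.energy_policy,
                fraction=options.fraction,
            )
        except Vlt2Error:
            flags.append(f"cr_{method}_failed")

    if costs["fix"] is not None:
        m.cr_fix = costs["fix"].oxygen_cost
        m.cr_fix_J = costs["fix"].energy_cost
        m.ve_at_fix = costs["fix"].ve_at_anchor
    if costs["lt1"] is not None:
        m.cr_lt1 = costs["lt1"].oxygen_cost
        m.cr_lt1_J = costs["lt1"].energy_cost
        m.ve_at_lt1 = costs["lt1"].ve_at_anchor
    if costs["pct80"] is not None:
        m.cr_80 = costs["pct80"].oxygen_cost
        m.cr_80_J = costs["pct80"].energy_cost
        m.ve_at_80 = costs["pct80"].ve_at_anchor

    if thresholds is not None and reg is not None:
        try:
            vo2_lt2 = cost_mod.vo2_at_speed(session, thresholds.v_lt2, reg)
            m.lt2_pct = cost_mod.fractional_utilization(vo2_lt2, m.vo2peak)
        except Vlt2Error:
            flags.append("lt2_pct_failed")

    if m.lt2_pct is not None:
        if m.cr_fix is not None:
            m.cal_lt2_fix = calculate_vlt2(m.lt2_pct, m.vo2peak, m.cr_fix)
        if m.cr_lt1 is not None:
            m.cal_lt2_lt1 = calculate_vlt2(m.lt2_pct, m.vo2peak, m.cr_lt1)
        if m.cr_80 is not None:
            m.cal_lt2_80 = calculate_vlt2(m.lt2_pct, m.vo2peak, m.cr_80)

    m.failure_flags = tuple(flags)
    return m
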