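"""Gas-exchange processing: steady-state averaging, VO2peak, exhaustion.

Spirometric channels are averaged over the last third of each stage so the
stage value reflects a (sub)maximal steady state.  VO2peak is the highest
30-s moving average of the 1-s VO2 series; when only stage-level summaries
exist the maximum stage value is the documented fallback.  Exhaustion is
verified from volitional exhaustion plus objective criteria (peak RER
≥ 1.10, peak HR ≥ 95% of age-predicted maximum, post-test blood lactate
≥ 8 mmol·L⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import InsufficientDataError
from .types import GasSeries, TestSession

RER_CRITERION = 1.10
HR_FRACTION = 0.95  # of age-predicted maximal heart rate
LACTATE_CRITERION = 8.0  # mmol/L
VO2PEAK_WINDOW = 30.0  # s


def apmhr_fox(age: float) -> float:
    """Age-predicted maximal heart rate, 220 − age (default formula)."""
    return 220.0 - age


@dataclass(frozen=True)
class ExhaustionCheck:
    """Per-criterion booleans behind the exhaustion verdict.

    ``None`` marks a criterion that could not be evaluated (missing
    channel); indeterminate criteria are excluded from the count required
    by the conjunction rule.
    """

    rer_met: Optional[bool]
    hr_met: Optional[bool]
    lactate_met: Optional[bool]
    volitional: bool
    verified: bool
    details: dict = field(default_factory=dict)


def stage_steady_state(
    t: np.ndarray, values: np.ndarray, duration: float
) -> float:
    """Mean of the samples falling in the last third of the stage.

    ``t`` is seconds from stage start; samples with t in
    [2·duration/3, duration] enter the mean (rest-break samples, which lie
    beyond ``duration``, are excluded).
    """
    if not duration > 0:
        raise ValueError("stage duration must be positive")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (t >= 2.0 * duration / 3.0) & (t <= duration)
    if not mask.any():
        raise InsufficientDataError("no samples in the final third of the stage")
    return float(values[mask].mean())


def compute_vo2peak(raw_gas: GasSeries, window: float = VO2PEAK_WINDOW) -> float:
    """Highest ``window``-second moving average of the 1-s VO2 series."""
    vo2 = np.asarray(raw_gas.vo2, dtype=float)
    w = int(round(window))
    if vo2.size < w:
        raise InsufficientDataError(
            f"gas series of {vo2.size} samples is shorter than the {w}-s window"
        )
    kernel = np.ones(w) / w
    means = np.convolve(vo2, kernel, mode="valid")
    return float(means.max())


def session_vo2peak(session: TestSession, window: float = VO2PEAK_WINDOW) -> float:
    """VO2peak for a session: 30-s moving average of the raw series when
    present, otherwise the maximum stage steady-state value (documented
    fallback for stage-level-only data)."""
    if session.raw_gas is not None:
        return compute_vo2peak(session.raw_gas, window)
    return max(s.vo2 for s in session.stages)


def check_exhaustion(
    session: TestSession,
    apmhr_formula: Callable[[float], float] = apmhr_fox,
    required_criteria: int = 2,
) -> ExhaustionCheck:
    """Verify exhaustion: volitional plus >= ``required_criteria`` of the
    objective criteria (RER, HR, post-test lactate); all thresholds are
    inclusive.  Missing channels make a criterion indeterminate and shrink
    the pool it is counted against."""
    rers = [s.rer for s in session.stages if s.rer is not None]
    hrs = [s.hr for s in session.stages if s.hr is not None]
    if session.raw_gas is not None and session.raw_gas.hr is not None:
        hrs.extend(float(h) for h in session.raw_gas.hr)

    peak_rer = max(rers) if rers else None
    peak_hr = max(hrs) if hrs else None
    apmhr = apmhr_formula(session.age)

    rer_met = None if peak_rer is None else peak_rer >= RER_CRITERION
    hr_met = None if peak_hr is None else peak_hr >= HR_FRACTION * apmhr
    lactate_met = session.post_test_lactate >= LACTATE_CRITERION

    determinate = [c for c in (rer_met, hr_met, lactate_met) if c is not None]
    needed = min(required_criteria, len(determinate))
    verified = session.volitional_exhaustion and sum(determinate) >= needed
    return ExhaustionCheck(
        rer_met=rer_met,
        hr_met=hr_met,
        lactate_met=lactate_met,
        volitional=session.volitional_exhaustion,
        verified=verified,
        details={
            "peak_rer": peak_rer,
            "rer_criterion": RER_CRITERION,
            "peak_hr": peak_hr,
            "hr_criterion": HR_FRACTION * apmhr,
            "post_test_lactate": session.post_test_lactate,
            "lactate_criterion": LACTATE_CRITERION,
            "required_criteria": required_criteria,
        },
    )
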