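"""Core data model: incremental treadmill step-test sessions and metrics.

A :class:`TestSession` holds one athlete-visit of an incremental treadmill
protocol (fixed start speed, fixed increment, fixed stage duration, short
rest breaks for capillary lactate sampling, run to volitional exhaustion).
Stage-level values are steady-state summaries (spirometric channels averaged
over the last third of each stage); the optional raw gas series carries the
1-s breath data used for the 30-s moving-average VO2peak.

Validation is done eagerly in ``__post_init__`` so malformed records fail at
construction, not deep inside the analysis chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np

from .errors import IntegrityError

PROTOCOL_START_SPEED = 2.4  # m/s, first stage of the step protocol
PROTOCOL_INCREMENT = 0.4  # m/s added per stage
PROTOCOL_STAGE_DURATION = 300.0  # s
FIXED_COST_SPEED = 2.8  # m/s, anchor of the fixed-speed cost method

#: inclusion-criterion labels carried by InclusionReport.failed_criteria
CRITERIA = (
    "age",
    "exhaustion",
    "valid_thresholds",
    "min_stages",
    "v80_in_range",
    "duplicate_visit",
)


@dataclass(frozen=True)
class StageResult:
    """One completed (or attempted) stage of the step test."""

    stage_index: int  # 1-based ordinal
    speed: float  # m/s
    duration: float  # s
    vo2: float  # mL/kg/min, last-third steady-state mean
    rer: Optional[float]  # VCO2/VO2, dimensionless
    ve: Optional[float]  # L/min minute ventilation
    hr: Optional[float]  # bpm
    lactate: float  # mmol/L end-stage capillary sample
    completed: bool = True

    def __post_init__(self) -> None:
        if self.stage_index < 1:
            raise ValueError(f"stage_index must be >= 1, got {self.stage_index}")
        if not self.speed > 0:
            raise ValueError(f"stage speed must be positive, got {self.speed}")
        if not self.duration > 0:
            raise ValueError(f"stage duration must be positive, got {self.duration}")
        if self.rer is not None and not (0.6 <= self.rer <= 1.4):
            raise ValueError(f"RER {self.rer} outside physiological range [0.6, 1.4]")
        if self.lactate < 0:
            raise ValueError(f"lactate must be non-negative, got {self.lactate}")


@dataclass
class GasSeries:
    """Raw breath-gas time series sampled at 1 Hz (t in s from test start)."""

    t: np.ndarray
    vo2: np.ndarray  # mL/kg/min
    vco2: Optional[np.ndarray] = None
    hr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        if self.t.shape != self.vo2.shape:
            raise ValueError("gas series t and vo2 must have equal length")


@dataclass
class TestSession:
    """One athlete's incremental step test to exhaustion."""

    athlete_id: str
    visit_date: date
    age: float  # years
    sex: str  # "male" | "female"
    height: float  # cm
    body_mass: float  # kg
    stages: Sequence[StageResult]
    post_test_lactate: float  # mmol/L, peak post-exercise sample
    volitional_exhaustion: bool = True
    incline_pct: float = 1.0  # treadmill incline simulating air resistance
    raw_gas: Optional[GasSeries] = None

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError(f"session {self.athlete_id}: stages must be non-empty")
        if not self.age > 0:
            raise ValueError(f"session {self.athlete_id}: age must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"session {self.athlete_id}: unknown sex {self.sex!r}")
        self.stages = tuple(sorted(self.stages, key=lambda s: s.stage_index))
        idx = [s.stage_index for s in self.stages]
        if len(set(idx)) != len(idx):
            raise IntegrityError(
                f"session {self.athlete_id}/{self.visit_date}: duplicate stage_index"
            )
        speeds = [s.speed for s in self.stages]
        for lo, hi in zip(speeds, speeds[1:]):
            if not np.isclose(hi - lo, PROTOCOL_INCREMENT, atol=1e-9):
                raise ValueError(
                    f"session {self.athlete_id}: consecutive stage speeds must "
                    f"differ by the protocol increment {PROTOCOL_INCREMENT}, "
                    f"got {lo} -> {hi}"
                )

    @property
    def completed_stages(self) -> tuple[StageResult, ...]:
        return tuple(s for s in self.stages if s.completed)

    @property
    def n_completed(self) -> int:
        return len(self.completed_stages)

    @property
    def top_speed(self) -> float:
        """Highest speed attained (the final stage, completed or not)."""
        return self.stages[-1].speed


@dataclass(frozen=True)
class InclusionReport:
    """Outcome of the cohort inclusion filter for one session."""

    athlete_id: str
    passed: bool
    failed_criteria: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for c in self.failed_criteria:
            if c not in CRITERIA:
                raise ValueError(f"unknown inclusion criterion {c!r}")
        if self.passed != (len(self.failed_criteria) == 0):
            raise ValueError("passed flag inconsistent with failed_criteria")


@dataclass
class AthleteMetrics:
    """Per-athlete outputs of the full modeling chain.

    Houses every symbol of the endurance-performance model: fractional
    utilization (``lt2_pct``, stored as a fraction), VO2peak, the three
    oxygen/energy cost-of-running determinations, and the three modeled
    threshold speeds ``cal_lt2_*``.  ``None`` marks values that could not
    be computed; ``failure_flags`` says why.
    """

    athlete_id: str
    sex: str
    age: float
    vo2peak: Optional[float] = None  # mL/kg/min
    lt2_pct: Optional[float] = None  # fraction of VO2peak at LT2
    v_lt1: Optional[float] = None  # m/s
    v_lt2: Optional[float] = None  # m/s, measured (maximal-deviation method)
    v80: Optional[float] = None  # m/s, speed at 80% VO2peak
    cr_fix: Optional[float] = None  # mL/kg/m
    cr_lt1: Optional[float] = None
    cr_80: Optional[float] = None
    cr_fix_J: Optional[float] = None  # J/kg/m
    cr_lt1_J: Optional[float] = None
    cr_80_J: Optional[float] = None
    cal_lt2_fix: Optional[float] = None  # m/s, modeled thresholds
    cal_lt2_lt1: Optional[float] = None
    cal_lt2_80: Optional[float] = None
    ve_at_lt1: Optional[float] = None  # L/min
    ve_at_80: Optional[float] = None
    ve_at_fix: Optional[float] = None
    exhaustion_verified: bool = False
    v80_in_range: bool = False
    n_completed_stages: int = 0
    included: bool = False
    failure_flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def thresholds_valid(self) -> bool:
        return self.v_lt1 is not None and self.v_lt2 is not None
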