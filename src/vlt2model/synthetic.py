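"""Seeded generator of physiologically structured incremental step tests.

The study population (young squad athletes) is emulated per sex from the
published descriptive statistics: latent VO2peak, oxygen cost of running,
fractional utilization, age, height and body mass are drawn from per-sex
normal distributions (defaults = the cohort means ± SD), truncated at
physiological floors.  From the latent triple the true threshold speed
follows the endurance model, v_LT2 = LT2% · VO2peak / (C · 60), and the
first threshold sits at a configured fraction of it (default 0.84, the
ratio of the published group means 2.84/3.38).

Each session then walks the step protocol (2.4 m·s⁻¹ start, +0.4 m·s⁻¹
per 5-min stage) until the demanded VO2 (= C·60·speed) exceeds the latent
VO2peak; that stage is attempted but not completed.  Stage VO2 is linear in
speed plus Gaussian noise.  Blood lactate follows a convex smoothed-hinge
(softplus) curve, la(v) = la0 + (S/κ)·ln(1 + exp(κ·(v − vh))): flat near
baseline, an exponential rise around the hinge vh, and a bounded maximal
slope S — the shape of measured lactate-performance curves, and
deliberately *not* a cubic, so the downstream polynomial fit is a genuine
approximation rather than a round-trip through its own model family.  The
hinge is placed so the analytic slope equals exactly 1.0 mmol·L⁻¹ per
m·s⁻¹ at the latent first threshold.  Lactate noise is truncated to keep
the sequence non-decreasing; RER and HR ramp to above-criterion peaks and
the post-test lactate exceeds the exhaustion criterion.

Determinism: one master seed; each athlete draws from a substream keyed by
(seed, athlete index), so cohorts are reproducible and individual athletes
are stable under cohort-size changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Optional

import numpy as np

from .errors import GeneratorError
from .types import (
    PROTOCOL_INCREMENT,
    PROTOCOL_STAGE_DURATION,
    PROTOCOL_START_SPEED,
    StageResult,
    TestSession,
)
from .units import SEC_PER_MIN

_MAX_RETRIES = 60  # admissibility redraws per athlete before giving up
_VISIT_DATE = date(2021, 6, 15)  # nominal visit date for synthetic athletes

#: cohort-typical threshold speed anchoring the hinge-sharpness scale
K_REFERENCE_SPEED = 3.4  # m/s


@dataclass(frozen=True)
class SexParams:
    """Per-sex population moments (means ± SD of the latent parameters)."""

    vo2peak_mean: float  # mL/kg/min
    vo2peak_sd: float
    cost_mean: float  # mL/kg/m, true oxygen cost of running
    cost_sd: float
    lt2_pct_mean: float  # fraction of VO2peak at LT2
    lt2_pct_sd: float
    age_mean: float  # years
    age_sd: float
    height_mean: float  # cm
    height_sd: float
    mass_mean: float  # kg
    mass_sd: float


#: cohort descriptives of the male squad athletes
MALE_DEFAULTS = SexParams(
    vo2peak_mean=56.4, vo2peak_sd=5.9,
    cost_mean=0.229, cost_sd=0.018,
    lt2_pct_mean=0.870, lt2_pct_sd=0.029,
    age_mean=15.8, age_sd=1.4,
    height_mean=175.2, height_sd=10.5,
    mass_mean=63.6, mass_sd=14.6,
)

#: cohort descriptives of the female squad athletes
FEMALE_DEFAULTS = SexParams(
    vo2peak_mean=47.3, vo2peak_sd=4.3,
    cost_mean=0.216, cost_sd=0.016,
    lt2_pct_mean=0.870, lt2_pct_sd=0.024,
    age_mean=15.2, age_sd=1.1,
    height_mean=170.9, height_sd=7.3,
    mass_mean=61.2, mass_sd=8.9,
)


@dataclass(frozen=True)
class PopulationConfig:
    """All knobs of the synthetic cohort (defaults = study conditions)."""

    male: SexParams = MALE_DEFAULTS
    female: SexParams = FEMALE_DEFAULTS
    lt1_fraction: float = 0.84  # v_LT1 / v_LT2, ratio of published means
    # lactate-curve shape
    la0_mean: float = 1.0  # mmol/L baseline lactate
    la0_sd: float = 0.15
    k_mean: float = 6.0  # per m/s, hinge sharpness (exponential rise rate)
    k_sd: float = 0.7
    s_max_mean: float = 7.0  # mmol/L per m/s, maximal lactate-curve slope
    s_max_sd: float = 0.7
    post_lactate_bump: float = 1.0  # mmol/L added after exhaustion
    # measurement noise (SD)
    sigma_vo2: float = 1.2  # mL/kg/min per-stage steady-state noise
    sigma_la: float = 0.2  # mmol/L capillary lactate
    sigma_rer: float = 0.02
    sigma_hr: float = 3.0  # bpm
    sigma_ve: float = 4.0  # L/min
    # protocol
    start_speed: float = PROTOCOL_START_SPEED  # m/s
    increment: float = PROTOCOL_INCREMENT  # m/s per stage
    stage_duration: float = PROTOCOL_STAGE_DURATION  # s
    # physiological floors (truncation, not rejection)
    vo2peak_floor: float = 30.0
    cost_floor: float = 0.15
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("sigma_vo2", "sigma_la", "sigma_rer", "sigma_hr", "sigma_ve"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.lt1_fraction < 1:
            raise ValueError("lt1_fraction must be in (0, 1)")

    def params_for(self, sex: str) -> SexParams:
        if sex == "male":
            return self.male
        if sex == "female":
            return self.female
        raise ValueError(f"unknown sex label {sex!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        for sex in ("male", "female"):
            if sex in d and isinstance(d[sex], dict):
                d[sex] = SexParams(**d[sex])
        return cls(**d)


@dataclass(frozen=True)
class AthleteTruth:
    """Latent ground truth behind one synthetic athlete."""

    sex: str
    age: float
    height: float
    body_mass: float
    vo2peak_true: float
    c_true: float  # mL/kg/m
    lt2_pct_true: float
    v_lt2_true: float  # m/s, model-implied threshold speed
    v_lt1_true: float  # m/s
    la0: float  # mmol/L baseline lactate
    k: float  # per m/s, hinge sharpness
    s_max: float  # mmol/L per m/s, maximal curve slope

    def __post_init__(self) -> None:
        if not self.v_lt1_true < self.v_lt2_true:
            raise ValueError("v_lt1_true must lie below v_lt2_true")
        if not 0 < self.lt2_pct_true < 1:
            raise ValueError("lt2_pct_true must be a fraction in (0, 1)")
        if not self.s_max > 1:
            raise ValueError("s_max must exceed the LT1 slope criterion 1.0")

    @property
    def hinge_speed(self) -> float:
        """Hinge location vh such that la'(v_lt1_true) = 1.0 exactly:
        S·sigmoid(κ(v1−vh)) = 1  ⇒  vh = v1 + ln(S−1)/κ."""
        return self.v_lt1_true + np.log(self.s_max - 1.0) / self.k

    def lactate_at(self, v: float | np.ndarray) -> float | np.ndarray:
        """Noise-free lactate curve la(v) = la0 + (S/κ)·softplus(κ(v−vh)).

        Convex and strictly increasing with slope rising from ~0 to S;
        the slope equals 1.0 mmol·L⁻¹ per m·s⁻¹ exactly at v_LT1 by the
        hinge placement.
        """
        z = self.k * (np.asarray(v, dtype=float) - self.hinge_speed)
        return self.la0 + (self.s_max / self.k) * np.logaddexp(0.0, z)

    def demanded_vo2(self, v: float) -> float:
        return self.c_true * v * SEC_PER_MIN


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    return float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, lo, hi))


def sample_athlete_profile(
    config: PopulationConfig, sex: str, rng: np.random.Generator
) -> AthleteTruth:
    """Draw one latent athlete from the per-sex population distributions."""
    p = config.params_for(sex)
    vo2peak = _truncated_normal(rng, p.vo2peak_mean, p.vo2peak_sd, lo=config.vo2peak_floor)
    c = _truncated_normal(rng, p.cost_mean, p.cost_sd, lo=config.cost_floor)
    lt2_pct = _truncated_normal(rng, p.lt2_pct_mean, p.lt2_pct_sd, lo=0.70, hi=0.99)
    # Table-style descriptives characterise the *included* cohort, so ages
    # are drawn below the inclusion cut-off rather than filtered afterwards
    age = _truncated_normal(rng, p.age_mean, p.age_sd, lo=12.0, hi=18.9)
    height = _truncated_normal(rng, p.height_mean, p.height_sd, lo=140.0)
    mass = _truncated_normal(rng, p.mass_mean, p.mass_sd, lo=35.0)
    la0 = _truncated_normal(rng, config.la0_mean, config.la0_sd, lo=0.4)
    # clip ranges keep the chord slope safely below the maximal curve slope
    # so the maximal-deviation point stays interior (see docs/methods.md)
    k = _truncated_normal(rng, config.k_mean, config.k_sd, lo=4.5, hi=7.5)
    s_max = _truncated_normal(rng, config.s_max_mean, config.s_max_sd, lo=5.5, hi=9.0)
    v_lt2 = lt2_pct * vo2peak / (c * SEC_PER_MIN)
    # lactate kinetics track relative intensity, so the hinge width scales
    # with the athlete's speed range: fitter athletes have proportionally
    # broader transitions in absolute speed units
    k = float(np.clip(k * K_REFERENCE_SPEED / v_lt2, 3.0, 8.5))
    return AthleteTruth(
        sex=sex,
        age=age,
        height=height,
        body_mass=mass,
        vo2peak_true=vo2peak,
        c_true=c,
        lt2_pct_true=lt2_pct,
        v_lt2_true=v_lt2,
        v_lt1_true=config.lt1_fraction * v_lt2,
        la0=la0,
        k=k,
        s_max=s_max,
    )


def protocol_speeds(truth: AthleteTruth, config: PopulationConfig) -> tuple[list[float], float]:
    """Completed-stage speeds and the attempted (uncompleted) top speed.

    Stages are completed while the demanded VO2 stays within the latent
    VO2peak; the first stage whose demand exceeds it is attempted but not
    finished.
    """
    completed: list[float] = []
    v = config.start_speed
    while truth.demanded_vo2(v) <= truth.vo2peak_true:
        completed.append(round(v, 10))
        v = config.start_speed + (len(completed)) * config.increment
    return completed, round(v, 10)


def true_post_test_lactate(truth: AthleteTruth, config: PopulationConfig) -> float:
    """Noise-free post-test peak lactate: curve value at the top attained
    speed plus the post-exercise bump, at least the exhaustion criterion."""
    _, v_top = protocol_speeds(truth, config)
    return max(8.0, float(truth.lactate_at(v_top)) + config.post_lactate_bump)


def true_dmax_speed(
    truth: AthleteTruth, config: PopulationConfig, step: float = 1e-4
) -> float:
    """Dense-grid maximal-deviation point of the *generating* curve.

    Independent of the cubic-fit pipeline: uses the analytic lactate curve,
    the latent LT1 point, and the same peak-point convention as a measured
    session (top attained speed, max of end-test curve lactate and the
    post-test value).
    """
    _, v_top = protocol_speeds(truth, config)
    v1 = truth.v_lt1_true
    la1 = float(truth.lactate_at(v1))
    lap = max(float(truth.lactate_at(v_top)), true_post_test_lactate(truth, config))
    m = (lap - la1) / (v_top - v1)
    grid = np.arange(v1 + step, v_top, step)
    dev = (la1 + m * (grid - v1)) - np.asarray(truth.lactate_at(grid))
    # interior maximum of the sag below the chord (the peak *point* lies
    # above the curve, so the boundary deviation is not a curve maximum)
    local = ((dev[1:-1] >= dev[:-2]) & (dev[1:-1] >= dev[2:])).nonzero()[0] + 1
    idx = local[int(np.argmax(dev[local]))] if local.size else int(np.argmax(dev))
    return float(grid[idx])


def simulate_session(
    truth: AthleteTruth,
    config: PopulationConfig,
    rng: np.random.Generator,
    athlete_id: str = "synth-0001",
    visit_date: date = _VISIT_DATE,
) -> TestSession:
    """Simulate one incremental step test for a latent athlete.

    Raises :class:`GeneratorError` when the truth implies fewer than four
    completed stages (the caller retries with a fresh profile).
    """
    completed, v_top = protocol_speeds(truth, config)
    if len(completed) < 4:
        raise GeneratorError(
            f"latent athlete completes only {len(completed)} stages "
            f"(VO2peak/{SEC_PER_MIN:.0f}·C = {truth.vo2peak_true / (SEC_PER_MIN * truth.c_true):.2f} m/s)"
        )
    speeds = completed + [v_top]
    n = len(speeds)
    apmhr = 220.0 - truth.age

    stages: list[StageResult] = []
    prev_la = 0.0
    for i, v in enumerate(speeds):
        is_final = i == n - 1
        progress = i / (n - 1) if n > 1 else 1.0
        if is_final:
            # demand exceeds the latent ceiling: VO2 plateaus at peak
            vo2 = truth.vo2peak_true + rng.normal(0.0, config.sigma_vo2)
        else:
            vo2 = truth.demanded_vo2(v) + rng.normal(0.0, config.sigma_vo2)
        la = float(truth.lactate_at(v)) + rng.normal(0.0, config.sigma_la)
        la = max(la, prev_la, 0.05)  # truncation keeps the sequence monotone
        prev_la = la
        rer = 0.85 + (1.12 - 0.85) * progress + rng.normal(0.0, config.sigma_rer)
        rer = float(np.clip(rer, 0.7, 1.4))
        if is_final:
            rer = max(rer, 1.10)  # objective exhaustion criterion attained
        hr = apmhr * (0.70 + 0.27 * progress) + rng.normal(0.0, config.sigma_hr)
        hr = float(np.clip(hr, 60.0, apmhr))
        if is_final:
            hr = max(hr, 0.955 * apmhr)
        ve = 0.028 * vo2 * truth.body_mass + rng.normal(0.0, config.sigma_ve)
        stages.append(
            StageResult(
                stage_index=i + 1,
                speed=v,
                duration=config.stage_duration if not is_final else config.stage_duration / 2,
                vo2=float(vo2),
                rer=rer,
                ve=float(max(ve, 10.0)),
                hr=hr,
                lactate=la,
                completed=not is_final,
            )
        )

    post_la = true_post_test_lactate(truth, config) + abs(rng.normal(0.0, config.sigma_la))
    post_la = max(post_la, prev_la)
    return TestSession(
        athlete_id=athlete_id,
        visit_date=visit_date,
        age=truth.age,
        sex=truth.sex,
        height=truth.height,
        body_mass=truth.body_mass,
        stages=stages,
        post_test_lactate=float(post_la),
        volitional_exhaustion=True,
    )


def _session_admissible(session: TestSession) -> bool:
    """Whether a simulated session would enter the modeled cohort.

    The published descriptives characterise athletes who *passed* the
    inclusion filter (valid thresholds, exhaustion, stage count, v80 in
    range) with complete modeled values; the generator emulates that
    population by conditioning on admissibility, mirroring the study's own
    screening of its much larger testing pool.
    """
    from .filters import MIN_COMPLETED_STAGES
    from .model import assemble_metrics

    if session.n_completed < MIN_COMPLETED_STAGES:
        return False
    m = assemble_metrics(session)
    return (
        m.exhaustion_verified
        and m.thresholds_valid
        and m.v80_in_range
        and m.cal_lt2_fix is not None
        and m.cal_lt2_lt1 is not None
        and m.cal_lt2_80 is not None
    )


def generate_athlete(
    config: PopulationConfig, sex: str, index: int
) -> tuple[AthleteTruth, TestSession]:
    """Deterministically generate athlete ``index`` (truth + session).

    Substream keyed by (seed, index).  Draws are retried (up to 10 times,
    with a warning) when the latent profile completes fewer than four
    stages or the simulated session is not admissible — the noisy lactate
    points can defeat the slope-criterion LT1 detection, just as in real
    testing pools, and the emulated population is the included cohort.
    """
    rng = np.random.default_rng([config.seed, index])
    last_err: Optional[GeneratorError] = None
    for attempt in range(_MAX_RETRIES):
        truth = sample_athlete_profile(config, sex, rng)
        try:
            session = simulate_session(
                truth, config, rng, athlete_id=f"synth-{index:04d}"
            )
        except GeneratorError as err:
            last_err = err
            continue
        if not _session_admissible(session):
            last_err = GeneratorError(f"athlete {index}: inadmissible session")
            continue
        if attempt:
            warnings.warn(
                f"athlete {index}: redrew profile {attempt} time(s) to obtain "
                "an admissible session",
                stacklevel=2,
            )
        return truth, session
    raise GeneratorError(
        f"athlete {index}: no admissible profile in {_MAX_RETRIES} draws"
    ) from last_err


def generate_cohort(
    config: PopulationConfig, n_male: int, n_female: int
) -> list[TestSession]:
    """Generate a cohort of n_male + n_female sessions (ids synth-0001…)."""
    return [s for _, s in generate_cohort_with_truth(config, n_male, n_female)]


def generate_cohort_with_truth(
    config: PopulationConfig, n_male: int, n_female: int
) -> list[tuple[AthleteTruth, TestSession]]:
    if n_male < 0 or n_female < 0:
        raise ValueError("cohort counts must be non-negative")
    out: list[tuple[AthleteTruth, TestSession]] = []
    for i in range(n_male + n_female):
        sex = "male" if i < n_male else "female"
        out.append(generate_athlete(config, sex, i + 1))
    return out
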