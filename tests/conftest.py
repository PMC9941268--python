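"""Shared fixtures: hand-built sessions and seeded synthetic cohorts."""

from __future__ import annotations

import warnings
from datetime import date

import numpy as np
import pytest

from vlt2model.model import assemble_metrics
from vlt2model.synthetic import (
    FEMALE_DEFAULTS,
    MALE_DEFAULTS,
    PopulationConfig,
    SexParams,
    generate_cohort_with_truth,
)
from vlt2model.types import StageResult, TestSession


def make_session(
    *,
    athlete_id: str = "ath-01",
    visit_date: date = date(2021, 3, 1),
    age: float = 16.0,
    sex: str = "female",
    height: float = 170.0,
    body_mass: float = 60.0,
    speeds=None,
    vo2=None,
    lactate=None,
    rer=None,
    hr=None,
    ve=None,
    completed=None,
    post_test_lactate: float = 9.0,
    volitional: bool = True,
) -> TestSession:
    """Build a protocol-conformant session with overridable channels.

    Defaults describe a plausible 5-stage test (4 completed + 1 attempted)
    of an athlete with oxygen cost 0.21 mL/kg/m and VO2peak ~50.
    """
    if speeds is None:
        speeds = [2.4, 2.8, 3.2, 3.6, 4.0]
    n = len(speeds)
    if vo2 is None:
        vo2 = [0.21 * v * 60 for v in speeds[:-1]] + [50.0]
    if lactate is None:
        lactate = [1.0, 1.3, 2.2, 4.5, 7.5][:n]
    if rer is None:
        rer = [0.85, 0.90, 0.97, 1.04, 1.12][:n]
    if hr is None:
        hr = [140, 155, 170, 185, 198][:n]
    if ve is None:
        ve = [55, 65, 80, 100, 120][:n]
    if completed is None:
        completed = [True] * (n - 1) + [False]
    stages = [
        StageResult(
            stage_index=i + 1,
            speed=speeds[i],
            duration=300.0 if completed[i] else 150.0,
            vo2=vo2[i],
            rer=rer[i],
            ve=ve[i],
            hr=hr[i],
            lactate=lactate[i],
            completed=completed[i],
        )
        for i in range(n)
    ]
    return TestSession(
        athlete_id=athlete_id,
        visit_date=visit_date,
        age=age,
        sex=sex,
        height=height,
        body_mass=body_mass,
        stages=stages,
        post_test_lactate=post_test_lactate,
        volitional_exhaustion=volitional,
    )


def zero_noise_config(seed: int = 7) -> PopulationConfig:
    """Default population with all measurement noise switched off."""
    return PopulationConfig(
        sigma_vo2=0.0, sigma_la=0.0, sigma_rer=0.0, sigma_hr=0.0, sigma_ve=0.0,
        seed=seed,
    )


def degenerate_config(seed: int = 7) -> PopulationConfig:
    """All SDs zero: every athlete equals the per-sex means exactly."""
    def fix(p: SexParams) -> SexParams:
        return SexParams(
            vo2peak_mean=p.vo2peak_mean, vo2peak_sd=0.0,
            cost_mean=p.cost_mean, cost_sd=0.0,
            lt2_pct_mean=p.lt2_pct_mean, lt2_pct_sd=0.0,
            age_mean=p.age_mean, age_sd=0.0,
            height_mean=p.height_mean, height_sd=0.0,
            mass_mean=p.mass_mean, mass_sd=0.0,
        )

    return PopulationConfig(
        male=fix(MALE_DEFAULTS), female=fix(FEMALE_DEFAULTS),
        la0_sd=0.0, k_sd=0.0, s_max_sd=0.0,
        sigma_vo2=0.0, sigma_la=0.0, sigma_rer=0.0, sigma_hr=0.0, sigma_ve=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default-noise cohort of 45 + 55 (study conditions), seed 42."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort_with_truth(PopulationConfig(seed=42), 45, 55)


@pytest.fixture(scope="session")
def default_metrics(default_cohort):
    return [assemble_metrics(s) for _, s in default_cohort]


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free cohort (latent variation only), 20 + 20, seed 7."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort_with_truth(zero_noise_config(seed=7), 20, 20)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
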