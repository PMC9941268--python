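"""Cohort inclusion filter.

Retains the athlete-visits that satisfy all of: age < 19 years, verified
exhaustion, valid LT1/LT2 determination, more than three completed stages,
speed at 80% VO2peak inside the tested speed range (protocol floor up to the
athlete's own top speed), and first visit per athlete only (earliest
visit_date; date ties broken by input order).
"""

from __future__ import annotations

from typing import Sequence

from .types import (
    PROTOCOL_START_SPEED,
    AthleteMetrics,
    InclusionReport,
    TestSession,
)

AGE_LIMIT = 19.0  # years, exclusive upper bound
MIN_COMPLETED_STAGES = 4  # "more than three" fully completed stages
_SPEED_TOL = 1e-9


def filter_cohort(
    sessions: Sequence[TestSession],
    metrics: Sequence[AthleteMetrics],
) -> tuple[list[TestSession], list[InclusionReport]]:
    """Apply the inclusion criteria; returns (retained sessions, reports).

    ``sessions`` and ``metrics`` are paired positionally and must align.
    The filter is idempotent: re-filtering the retained set is a no-op.
    """
    sessions = list(sessions)
    metrics = list(metrics)
    if len(sessions) != len(metrics):
        raise ValueError("sessions and metrics must have equal length")
    for s, m in zip(sessions, metrics):
        if s.athlete_id != m.athlete_id:
            raise ValueError(
                f"session/metrics misalignment: {s.athlete_id} vs {m.athlete_id}"
            )

    # earliest visit per athlete; ties keep first input order
    first_visit: dict[str, int] = {}
    for i, s in enumerate(sessions):
        j = first_visit.get(s.athlete_id)
        if j is None or s.visit_date < sessions[j].visit_date:
            first_visit[s.athlete_id] = i

    retained: list[TestSession] = []
    reports: list[InclusionReport] = []
    for i, (s, m) in enumerate(zip(sessions, metrics)):
        failed: list[str] = []
        if not s.age < AGE_LIMIT:
            failed.append("age")
        if not m.exhaustion_verified:
            failed.append("exhaustion")
        if not m.thresholds_valid:
            failed.append("valid_thresholds")
        if s.n_completed < MIN_COMPLETED_STAGES:
            failed.append("min_stages")
        if m.v80 is None or not (
            PROTOCOL_START_SPEED - _SPEED_TOL <= m.v80 <= s.top_speed + _SPEED_TOL
        ):
            failed.append("v80_in_range")
        if first_visit[s.athlete_id] != i:
            failed.append("duplicate_visit")
        passed = not failed
        reports.append(
            InclusionReport(
                athlete_id=s.athlete_id, passed=passed, failed_criteria=tuple(failed)
            )
        )
        if passed:
            retained.append(s)
    return retained, reports
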