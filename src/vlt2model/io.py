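"""CSV persistence for sessions and metrics.

Canonical dialect: comma separator, dot decimal, UTF-8, ISO-8601 dates, one
stage per row with the session metadata repeated (long format).  Session
floats are written with Python's shortest round-trip repr, so
``write_sessions(read_sessions(f))`` reproduces a canonically written file
byte for byte.  Metrics files are report artifacts and use the rounding
policy instead (speeds 2 dp, costs 3 dp, VO2peak and LT2% 1 dp).
"""

from __future__ import annotations

import math
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError
from .types import AthleteMetrics, StageResult, TestSession
from .units import round_half_away

SESSION_COLUMNS = [
    "athlete_id",
    "visit_date",
    "age",
    "sex",
    "height_cm",
    "body_mass_kg",
    "incline_pct",
    "stage_index",
    "speed_ms",
    "duration_s",
    "vo2_mlkgmin",
    "rer",
    "ve_lmin",
    "hr_bpm",
    "lactate_mmol",
    "completed",
    "post_test_lactate_mmol",
    "volitional_exhaustion",
]

_NUMERIC_SESSION_COLUMNS = [
    "age",
    "height_cm",
    "body_mass_kg",
    "incline_pct",
    "stage_index",
    "speed_ms",
    "duration_s",
    "vo2_mlkgmin",
    "rer",
    "ve_lmin",
    "hr_bpm",
    "lactate_mmol",
    "post_test_lactate_mmol",
]
_OPTIONAL_NUMERIC = {"rer", "ve_lmin", "hr_bpm"}

METRICS_COLUMNS = [
    "athlete_id",
    "sex",
    "age",
    "vo2peak",
    "lt2_pct",
    "v_lt1",
    "v_lt2",
    "cr_fix",
    "cr_lt1",
    "cr_80",
    "cr_fix_J",
    "cr_lt1_J",
    "cr_80_J",
    "cal_lt2_fix",
    "cal_lt2_lt1",
    "cal_lt2_80",
    "included",
    "failed_criteria",
]


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _fmt_round(x: Optional[float], ndigits: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{round_half_away(float(x), ndigits):.{ndigits}f}"


def read_sessions(path: str | Path) -> list[TestSession]:
    """Read a long-format sessions CSV into a list of :class:`TestSession`.

    Raises :class:`SchemaError` naming the first missing column,
    :class:`ParseError` with the 1-based data row number of the first
    non-numeric cell, and :class:`IntegrityError` on a duplicate
    (athlete_id, visit_date, stage_index) triple.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in SESSION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"sessions CSV is missing required column '{col}'")
    if df.empty:
        return []

    for col in _NUMERIC_SESSION_COLUMNS:
        raw = df[col].str.strip()
        # Python's float() is correctly rounded (pandas' fast parser is
        # not), which the lossless round-trip guarantee relies on
        parsed = raw.map(_parse_float)
        bad = parsed.isna() & (raw != "")
        if bad.any():
            row = int(bad.idxmax()) + 1  # 1-based data row
            raise ParseError(
                f"non-numeric value {raw[bad.idxmax()]!r} in column '{col}', data row {row}"
            )
        if (raw == "").any() and col not in _OPTIONAL_NUMERIC:
            row = int((raw == "").idxmax()) + 1
            raise ParseError(f"empty value in required column '{col}', data row {row}")
        df[col] = parsed

    key = df[["athlete_id", "visit_date", "stage_index"]].apply(tuple, axis=1)
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise IntegrityError(f"duplicate (athlete_id, visit_date, stage_index): {dup}")

    sessions: list[TestSession] = []
    # preserve file order of first appearance for downstream tie-breaking
    for (aid, vdate), grp in df.groupby(["athlete_id", "visit_date"], sort=False):
        grp = grp.sort_values("stage_index")
        first = grp.iloc[0]
        stages = [
            StageResult(
                stage_index=int(r.stage_index),
                speed=float(r.speed_ms),
                duration=float(r.duration_s),
                vo2=float(r.vo2_mlkgmin),
                rer=None if math.isnan(r.rer) else float(r.rer),
                ve=None if math.isnan(r.ve_lmin) else float(r.ve_lmin),
                hr=None if math.isnan(r.hr_bpm) else float(r.hr_bpm),
                lactate=float(r.lactate_mmol),
                completed=_parse_bool(r.completed),
            )
            for r in grp.itertuples()
        ]
        sessions.append(
            TestSession(
                athlete_id=str(aid),
                visit_date=date.fromisoformat(str(vdate)),
                age=float(first.age),
                sex=str(first.sex),
                height=float(first.height_cm),
                body_mass=float(first.body_mass_kg),
                incline_pct=float(first.incline_pct),
                stages=stages,
                post_test_lactate=float(first.post_test_lactate_mmol),
                volitional_exhaustion=_parse_bool(first.volitional_exhaustion),
            )
        )
    return sessions


def _parse_float(s: str) -> float:
    if s == "":
        return math.nan
    try:
        return float(s)
    except ValueError:
        return math.nan


def _parse_bool(v: object) -> bool:
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ParseError(f"cannot parse boolean value {v!r}")


def write_sessions(sessions: Iterable[TestSession], path: str | Path) -> None:
    """Write sessions to the canonical long-format CSV (lossless floats)."""
    lines = [",".join(SESSION_COLUMNS)]
    for s in sessions:
        for st in s.stages:
            lines.append(
                ",".join(
                    [
                        s.athlete_id,
                        s.visit_date.isoformat(),
                        _fmt(s.age),
                        s.sex,
                        _fmt(s.height),
                        _fmt(s.body_mass),
                        _fmt(s.incline_pct),
                        str(st.stage_index),
                        _fmt(st.speed),
                        _fmt(st.duration),
                        _fmt(st.vo2),
                        _fmt(st.rer),
                        _fmt(st.ve),
                        _fmt(st.hr),
                        _fmt(st.lactate),
                        str(st.completed),
                        _fmt(s.post_test_lactate),
                        str(s.volitional_exhaustion),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def metrics_to_frame(metrics: Sequence[AthleteMetrics]) -> pd.DataFrame:
    """Unrounded numeric view of metrics for statistics (LT2% as fraction)."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "athlete_id": m.athlete_id,
                "sex": m.sex,
                "age": m.age,
                "vo2peak": m.vo2peak,
                "lt2_pct": m.lt2_pct,
                "v_lt1": m.v_lt1,
                "v_lt2": m.v_lt2,
                "v80": m.v80,
                "cr_fix": m.cr_fix,
                "cr_lt1": m.cr_lt1,
                "cr_80": m.cr_80,
                "cr_fix_J": m.cr_fix_J,
                "cr_lt1_J": m.cr_lt1_J,
                "cr_80_J": m.cr_80_J,
                "cal_lt2_fix": m.cal_lt2_fix,
                "cal_lt2_lt1": m.cal_lt2_lt1,
                "cal_lt2_80": m.cal_lt2_80,
                "included": m.included,
            }
        )
    return pd.DataFrame(rows)


def write_metrics(
    metrics: Sequence[AthleteMetrics],
    path: str | Path,
    failed_criteria: Optional[dict[str, tuple[str, ...]]] = None,
) -> None:
    """Write one report row per athlete, rounded per the report policy.

    LT2% is rendered as a percentage with 1 decimal; speeds get 2 decimals,
    costs 3.  ``failed_criteria`` maps athlete_id to the inclusion criteria
    that athlete failed (empty/absent means none).
    """
    metrics = list(metrics)
    if not metrics:
        raise ValueError("metrics must be non-empty")
    failed_criteria = failed_criteria or {}
    lines = [",".join(METRICS_COLUMNS)]
    for m in metrics:
        lt2_pct = None if m.lt2_pct is None else 100.0 * m.lt2_pct
        lines.append(
            ",".join(
                [
                    m.athlete_id,
                    m.sex,
                    _fmt_round(m.age, 1),
                    _fmt_round(m.vo2peak, 1),
                    _fmt_round(lt2_pct, 1),
                    _fmt_round(m.v_lt1, 2),
                    _fmt_round(m.v_lt2, 2),
                    _fmt_round(m.cr_fix, 3),
                    _fmt_round(m.cr_lt1, 3),
                    _fmt_round(m.cr_80, 3),
                    _fmt_round(m.cr_fix_J, 3),
                    _fmt_round(m.cr_lt1_J, 3),
                    _fmt_round(m.cr_80_J, 3),
                    _fmt_round(m.cal_lt2_fix, 2),
                    _fmt_round(m.cal_lt2_lt1, 2),
                    _fmt_round(m.cal_lt2_80, 2),
                    str(m.included),
                    ";".join(failed_criteria.get(m.athlete_id, ())),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read back a metrics report CSV (LT2% column stays in percent)."""
    df = pd.read_csv(path, dtype={"athlete_id": str, "failed_criteria": str})
    for col in METRICS_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"metrics CSV is missing required column '{col}'")
    return df
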