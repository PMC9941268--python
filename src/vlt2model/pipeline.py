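"""End-to-end cohort pipeline: simulate/read → metrics → filter → reports.

Produces a deterministic report bundle in the output directory:

* ``sessions.csv``      — the analyzed sessions (as simulated or as read)
* ``metrics.csv``       — per-athlete metrics (report rounding policy)
* ``inclusion.csv``     — per-session inclusion verdicts and failed criteria
* ``descriptives.csv``  — cohort descriptives per sex with t-test p-values
* ``agreement.csv``     — bias ± limits of agreement and ICC per C_R method
  and per group (all/male/female)
* ``bland_altman.csv``  — per-athlete (mean, difference) plot data
* ``stepwise.csv``      — per-step selection trace per group
* ``commonality.csv``   — R² partition per group, signed percentages
* ``manifest.json``     — config, seed and config hash for reproducibility

Identical config + seed ⇒ byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as io_mod
from .agreement import agreement, compare_groups
from .errors import Vlt2Error
from .filters import filter_cohort
from .model import AnalysisOptions, assemble_metrics
from .stepwise import commonality_analysis, stepwise_regression
from .synthetic import PopulationConfig, generate_cohort
from .types import AthleteMetrics, TestSession
from .units import round_half_away

_METHODS = {"fix": "cal_lt2_fix", "lt1": "cal_lt2_lt1", "pct80": "cal_lt2_80"}


class EmptyCohortError(Vlt2Error):
    """No session survived the inclusion filter."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    input_path: Optional[Path] = None  # sessions CSV; None → simulate
    simulate: bool = False
    n_male: int = 45
    n_female: int = 55
    seed: int = 42
    population: Optional[PopulationConfig] = None
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    p_enter: float = 0.05
    p_remove: float = 0.10

    def resolved_population(self) -> PopulationConfig:
        if self.population is not None:
            return self.population
        return PopulationConfig(seed=self.seed)


def _config_digest(config: RunConfig) -> tuple[str, dict]:
    pop = config.resolved_population().to_dict()
    payload = {
        "input_path": str(config.input_path) if config.input_path else None,
        "simulate": config.simulate,
        "n_male": config.n_male,
        "n_female": config.n_female,
        "seed": config.seed,
        "population": pop,
        "p_enter": config.p_enter,
        "p_remove": config.p_remove,
        "slope_criterion": config.options.slope_criterion,
        "slope_units": config.options.slope_units,
        "peak_policy": config.options.peak_policy,
        "energy_policy": config.options.energy_policy,
        "exhaustion_k": config.options.exhaustion_k,
        "fraction": config.options.fraction,
    }
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest(), payload


def _fmt(x, nd) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    return f"{round_half_away(float(x), nd):.{nd}f}"


def _write_csv(path: Path, header: Sequence[str], rows: Sequence[Sequence[str]]) -> None:
    lines = [",".join(header)] + [",".join(str(c) for c in r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _metrics_frame(metrics: Sequence[AthleteMetrics]) -> pd.DataFrame:
    df = io_mod.metrics_to_frame(metrics)
    df["lt2_pct_pct"] = df["lt2_pct"] * 100.0
    df["sex_code"] = (df["sex"] == "male").astype(float)
    return df


# descriptive table rows: (label, column, decimals)
_DESCRIPTIVE_ROWS = [
    ("age_y", "age", 1),
    ("vo2peak_mlkgmin", "vo2peak", 1),
    ("cr_fix_mlkgm", "cr_fix", 3),
    ("cr_lt1_mlkgm", "cr_lt1", 3),
    ("cr_80_mlkgm", "cr_80", 3),
    ("cr_fix_Jkgm", "cr_fix_J", 2),
    ("cr_lt1_Jkgm", "cr_lt1_J", 2),
    ("cr_80_Jkgm", "cr_80_J", 2),
    ("lt2_pct", "lt2_pct_pct", 1),
    ("v_lt1_ms", "v_lt1", 2),
    ("v_lt2_ms", "v_lt2", 2),
    ("cal_lt2_fix_ms", "cal_lt2_fix", 2),
    ("cal_lt2_lt1_ms", "cal_lt2_lt1", 2),
    ("cal_lt2_80_ms", "cal_lt2_80", 2),
]


def _descriptives(df: pd.DataFrame) -> list[list[str]]:
    male = df[df.sex == "male"]
    female = df[df.sex == "female"]
    rows = []
    for label, col, nd in _DESCRIPTIVE_ROWS:
        a, m, f = df[col].dropna(), male[col].dropna(), female[col].dropna()
        try:
            _, _, p = compare_groups(m, f)
            p_str = f"{p:.3f}" if p >= 0.001 else "<0.001"
        except Vlt2Error:
            p_str = ""
        rows.append(
            [
                label,
                _fmt(a.mean(), nd), _fmt(a.std(ddof=1), nd),
                _fmt(m.mean(), nd), _fmt(m.std(ddof=1), nd),
                _fmt(f.mean(), nd), _fmt(f.std(ddof=1), nd),
                p_str,
            ]
        )
    return rows


def _agreement_rows(df: pd.DataFrame) -> tuple[list[list[str]], list[list[str]]]:
    groups = {"all": df, "male": df[df.sex == "male"], "female": df[df.sex == "female"]}
    table_rows, point_rows = [], []
    for method, col in _METHODS.items():
        for gname, g in groups.items():
            sub = g.dropna(subset=[col, "v_lt2"])
            if len(sub) < 3:
                continue
            res = agreement(sub[col], sub["v_lt2"])
            table_rows.append(
                [
                    method, gname, str(res.n),
                    _fmt(res.bias, 3), _fmt(res.sd_diff, 3),
                    _fmt(res.loa_low, 3), _fmt(res.loa_high, 3),
                    str(res.loa_pct),
                    _fmt(res.icc, 3), _fmt(res.icc_ci95[0], 3),
                    _fmt(res.icc_ci95[1], 3), res.icc_label,
                ]
            )
            if gname == "all":
                for _, r in sub.iterrows():
                    point_rows.append(
                        [
                            r.athlete_id, method,
                            _fmt((r[col] + r.v_lt2) / 2, 4),
                            _fmt(r[col] - r.v_lt2, 4),
                        ]
                    )
    return table_rows, point_rows


def _stepwise_rows(
    df: pd.DataFrame, p_enter: float, p_remove: float
) -> tuple[list[list[str]], list[list[str]]]:
    """Selection trace and commonality partition per group.

    Dependent variable: the modeled threshold speed from the 80%-VO2peak
    cost (the method carried into the regression analyses); candidates are
    the three physiological predictors plus sex and age.  Commonality is
    computed over the three physiological predictors.
    """
    candidates = ["vo2peak", "cr_80", "lt2_pct_pct", "sex_code", "age"]
    physio = ["vo2peak", "cr_80", "lt2_pct_pct"]
    step_rows, common_rows = [], []
    for gname, g in (
        ("all", df),
        ("male", df[df.sex == "male"]),
        ("female", df[df.sex == "female"]),
    ):
        cand = [c for c in candidates if gname == "all" or c != "sex_code"]
        sub = g.dropna(subset=["cal_lt2_80"] + physio)
        if len(sub) < len(cand) + 3:
            continue
        y = sub["cal_lt2_80"]
        model = stepwise_regression(y, sub[cand], p_enter, p_remove)
        for i, step in enumerate(model.steps, start=1):
            for name, (b, se, sb, t, p) in step.coefficients.items():
                step_rows.append(
                    [
                        gname, str(i), step.action, step.variable, name,
                        _fmt(b, 4), _fmt(se, 4),
                        "" if sb is None else _fmt(sb, 3),
                        _fmt(t, 3), f"{p:.4f}",
                        _fmt(step.r_squared, 3), _fmt(step.adj_r_squared, 3),
                        _fmt(step.f_statistic, 2),
                    ]
                )
        report = commonality_analysis(y, sub[physio])
        for subset in report.subsets:
            common_rows.append(
                [
                    gname, "+".join(subset),
                    f"{report.coefficients[subset]:.6f}",
                    _fmt(report.percents[subset], 1),
                    "suppression" if report.coefficients[subset] < 0 else "",
                ]
            )
        common_rows.append(
            [gname, "total", f"{report.r_squared_full:.6f}", "100.0", ""]
        )
    return step_rows, common_rows


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns a manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate or config.input_path is None:
        sessions = generate_cohort(
            config.resolved_population(), config.n_male, config.n_female
        )
    else:
        sessions = io_mod.read_sessions(config.input_path)
    if not sessions:
        raise EmptyCohortError("no input sessions")
    io_mod.write_sessions(sessions, out / "sessions.csv")

    metrics = [assemble_metrics(s, config.options) for s in sessions]
    retained, reports = filter_cohort(sessions, metrics)
    retained_ids = {id(s) for s in retained}
    failed_map = {r.athlete_id: r.failed_criteria for r in reports}
    for s, m in zip(sessions, metrics):
        m.included = id(s) in retained_ids
    io_mod.write_metrics(metrics, out / "metrics.csv", failed_map)
    _write_csv(
        out / "inclusion.csv",
        ["athlete_id", "passed", "failed_criteria"],
        [[r.athlete_id, str(r.passed), ";".join(r.failed_criteria)] for r in reports],
    )

    included = [m for m in metrics if m.included]
    if not included:
        raise EmptyCohortError("inclusion filter retained no athletes")
    df = _metrics_frame(included)

    _write_csv(
        out / "descriptives.csv",
        ["variable", "all_mean", "all_sd", "male_mean", "male_sd",
         "female_mean", "female_sd", "p_m_vs_f"],
        _descriptives(df),
    )
    agree_rows, point_rows = _agreement_rows(df)
    _write_csv(
        out / "agreement.csv",
        ["method", "group", "n", "bias_ms", "sd_diff_ms", "loa_low_ms",
         "loa_high_ms", "loa_pct", "icc", "icc_ci_low", "icc_ci_high", "label"],
        agree_rows,
    )
    _write_csv(
        out / "bland_altman.csv",
        ["athlete_id", "method", "mean_ms", "difference_ms"],
        point_rows,
    )
    step_rows, common_rows = _stepwise_rows(df, config.p_enter, config.p_remove)
    _write_csv(
        out / "stepwise.csv",
        ["group", "step", "action", "variable", "term", "beta", "se",
         "std_beta", "t", "p", "r_squared", "adj_r_squared", "f"],
        step_rows,
    )
    _write_csv(
        out / "commonality.csv",
        ["group", "subset", "coefficient", "pct_of_r2", "note"],
        common_rows,
    )

    digest, payload = _config_digest(config)
    manifest = {
        "config": payload,
        "config_sha256": digest,
        "n_sessions": len(sessions),
        "n_included": len(included),
        "n_excluded": len(sessions) - len(included),
        "athlete_failure_flags": {
            m.athlete_id: list(m.failure_flags) for m in metrics if m.failure_flags
        },
        "outputs": sorted(
            p.name for p in out.iterdir() if p.suffix in (".csv", ".json")
        ),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
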