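"""Bidirectional stepwise regression and commonality analysis.

Stepwise selection mirrors the classic statistical-package procedure: at
each round the candidate with the smallest partial-F p-value enters if
p ≤ p_enter (ties: larger partial F, then column order), then any retained
predictor with removal p ≥ p_remove is dropped, until nothing changes.

Commonality analysis decomposes the final model's R² into 2^k − 1
components — one per nonempty predictor subset — such that the components
sum to the full-model R² and, for each predictor, the components of all
subsets containing it sum to its squared zero-order correlation with the
response.  Negative common components mark suppression: a predictor that
improves the model by removing irrelevant variance from the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, ConfigError, UndefinedStatisticError

MAX_COMMONALITY_PREDICTORS = 5  # 2^k subset fits; guard against blow-up


@dataclass(frozen=True)
class StepRecord:
    """One entry/removal step of the selection trace."""

    action: str  # "enter" | "remove"
    variable: str
    predictors: tuple[str, ...]  # model after the step
    coefficients: dict  # name -> (beta, se, std_beta, t, p); incl. const
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float


@dataclass(frozen=True)
class StepwiseModel:
    steps: tuple[StepRecord, ...]
    final_predictors: tuple[str, ...]
    final_coefficients: dict  # name -> (beta, se, std_beta, t, p)
    r_squared: float
    adj_r_squared: float


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Least squares with intercept; returns (beta, rss, XtX_inv diagonal)."""
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise CollinearityError("rank-deficient design in stepwise fit")
    resid = y - A @ beta
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(A.T @ A)
    return beta, rss, np.diag(xtx_inv)


def _fit_stats(y: np.ndarray, X: np.ndarray, names: Sequence[str]) -> dict:
    n = len(y)
    p = X.shape[1] if X.ndim == 2 else 0
    beta, rss, xtx_diag = _ols(y, X)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise UndefinedStatisticError("constant response")
    r2 = 1.0 - rss / tss
    df_resid = n - p - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    sigma2 = rss / df_resid
    se = np.sqrt(sigma2 * xtx_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    sy = y.std(ddof=1)
    coefs = {}
    coefs["const"] = (float(beta[0]), float(se[0]), None, float(tvals[0]), float(pvals[0]))
    for j, name in enumerate(names, start=1):
        std_beta = float(beta[j] * X[:, j - 1].std(ddof=1) / sy)
        coefs[name] = (
            float(beta[j]),
            float(se[j]),
            std_beta,
            float(tvals[j]),
            float(pvals[j]),
        )
    if p > 0:
        with np.errstate(divide="ignore"):
            f = (r2 / p) / ((1 - r2) / df_resid) if r2 < 1 else np.inf
        f_p = float(stats.f.sf(f, p, df_resid))
    else:
        f, f_p = np.nan, np.nan
    return {
        "coefficients": coefs,
        "rss": rss,
        "r_squared": r2,
        "adj_r_squared": adj,
        "f": float(f),
        "f_p": f_p,
        "df_resid": df_resid,
    }


def _partial_f(rss_reduced: float, rss_full: float, df_resid_full: int) -> tuple[float, float]:
    """F-test for one added predictor; df = (1, df_resid_full).

    With an (essentially) exact larger model, a predictor that removed
    residual variance has F = ∞ (p = 0) while one that added nothing has
    F = 0 (p = 1) — the 0/0 case must not look significant.
    """
    improvement = rss_reduced - rss_full
    if rss_full <= 1e-12 * max(1.0, rss_reduced):
        return (np.inf, 0.0) if improvement > 1e-12 else (0.0, 1.0)
    f = improvement / (rss_full / df_resid_full)
    return float(f), float(stats.f.sf(f, 1, df_resid_full))


def stepwise_regression(
    y: Sequence[float] | pd.Series,
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseModel:
    """Bidirectional stepwise OLS with F-probability entry/removal criteria."""
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    n, k = Xm.shape
    if n != len(y):
        raise ValueError("response and design lengths differ")
    if n <= k + 1:
        raise ValueError("need more observations than candidates + 1")
    for j, name in enumerate(names):
        if np.ptp(Xm[:, j]) == 0:
            raise CollinearityError(f"constant predictor column '{name}'")

    selected: list[str] = []
    steps: list[StepRecord] = []

    def cols(subset: Sequence[str]) -> np.ndarray:
        idx = [names.index(s) for s in subset]
        return Xm[:, idx]

    while True:
        changed = False
        # entry: candidate with smallest partial-F p (tie: larger F, order)
        current = _fit_stats(y, cols(selected), selected)
        best: Optional[tuple[float, float, int, str]] = None
        for j, cand in enumerate(names):
            if cand in selected:
                continue
            trial = selected + [cand]
            try:
                fit = _fit_stats(y, cols(trial), trial)
            except CollinearityError:
                continue
            f, p = _partial_f(current["rss"], fit["rss"], fit["df_resid"])
            if p <= p_enter and (best is None or (p, -f, j) < (best[0], -best[1], best[2])):
                best = (p, f, j, cand)
        if best is not None:
            selected.append(best[3])
            fit = _fit_stats(y, cols(selected), selected)
            steps.append(
                StepRecord(
                    action="enter",
                    variable=best[3],
                    predictors=tuple(selected),
                    coefficients=fit["coefficients"],
                    r_squared=fit["r_squared"],
                    adj_r_squared=fit["adj_r_squared"],
                    f_statistic=fit["f"],
                    f_pvalue=fit["f_p"],
                )
            )
            changed = True

        # removal: any retained predictor with partial-F p >= p_remove
        while len(selected) > 0:
            full = _fit_stats(y, cols(selected), selected)
            worst: Optional[tuple[float, str]] = None
            for name in selected:
                reduced = [s for s in selected if s != name]
                red = _fit_stats(y, cols(reduced), reduced)
                _, p = _partial_f(red["rss"], full["rss"], full["df_resid"])
                if p >= p_remove and (worst is None or p > worst[0]):
                    worst = (p, name)
            if worst is None:
                break
            selected.remove(worst[1])
            fit = _fit_stats(y, cols(selected), selected)
            steps.append(
                StepRecord(
                    action="remove",
                    variable=worst[1],
                    predictors=tuple(selected),
                    coefficients=fit["coefficients"],
                    r_squared=fit["r_squared"],
                    adj_r_squared=fit["adj_r_squared"],
                    f_statistic=fit["f"],
                    f_pvalue=fit["f_p"],
                )
            )
            changed = True

        if not changed:
            break

    final = _fit_stats(y, cols(selected), selected)
    return StepwiseModel(
        steps=tuple(steps),
        final_predictors=tuple(selected),
        final_coefficients=final["coefficients"],
        r_squared=final["r_squared"],
        adj_r_squared=final["adj_r_squared"],
    )


@dataclass(frozen=True)
class CommonalityReport:
    """R² partition over all nonempty predictor subsets."""

    subsets: tuple[tuple[str, ...], ...]
    coefficients: dict  # subset tuple -> variance component
    percents: dict  # subset tuple -> 100 * component / R²_full
    r_squared_full: float
    zero_order_r: dict  # predictor -> r(x_i, y)

    def unique(self, name: str) -> float:
        return self.coefficients[(name,)]

    def suppression_subsets(self) -> tuple[tuple[str, ...], ...]:
        """Subsets with negative common variance (suppression)."""
        return tuple(s for s, c in self.coefficients.items() if c < 0)


def _subset_r2(y: np.ndarray, Xm: np.ndarray, idx: tuple[int, ...]) -> float:
    if not idx:
        return 0.0
    _, rss, _ = _ols(y, Xm[:, list(idx)])
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss


def commonality_analysis(
    y: Sequence[float] | pd.Series, X: pd.DataFrame, max_predictors: int = MAX_COMMONALITY_PREDICTORS
) -> CommonalityReport:
    """Partition the full-model R² into unique and common components.

    For each nonempty subset S of the k predictors the component is

        C(S) = Σ_{T ⊆ S} (−1)^{|T|+1} · R²(T ∪ (K∖S))        (R²(∅) = 0)

    which satisfies the partition identity Σ_S C(S) = R²_full and, for
    every predictor i, Σ_{S ∋ i} C(S) = r(x_i, y)².
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    k = len(names)
    if k > max_predictors:
        raise ConfigError(
            f"commonality over {k} predictors needs 2^{k} subset fits; "
            f"guard is {max_predictors} (raise max_predictors deliberately)"
        )
    Xm = X.to_numpy(dtype=float)
    full_idx = tuple(range(k))
    _, rss_full, _ = _ols(y, Xm)  # raises CollinearityError if rank-deficient

    r2_cache: dict[tuple[int, ...], float] = {}

    def r2(idx: tuple[int, ...]) -> float:
        idx = tuple(sorted(idx))
        if idx not in r2_cache:
            r2_cache[idx] = _subset_r2(y, Xm, idx)
        return r2_cache[idx]

    r2_full = r2(full_idx)
    subsets: list[tuple[str, ...]] = []
    coefficients: dict = {}
    for size in range(1, k + 1):
        for combo in combinations(range(k), size):
            comp = 0.0
            complement = tuple(i for i in full_idx if i not in combo)
            for tsize in range(0, size + 1):
                for t in combinations(combo, tsize):
                    comp += ((-1) ** (len(t) + 1)) * r2(tuple(set(t) | set(complement)))
            key = tuple(names[i] for i in combo)
            subsets.append(key)
            coefficients[key] = comp
    percents = {
        s: (100.0 * c / r2_full if r2_full else np.nan)
        for s, c in coefficients.items()
    }
    zero_order = {
        name: float(np.corrcoef(Xm[:, j], y)[0, 1]) for j, name in enumerate(names)
    }
    return CommonalityReport(
        subsets=tuple(subsets),
        coefficients=coefficients,
        percents=percents,
        r_squared_full=r2_full,
        zero_order_r=zero_order,
    )
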