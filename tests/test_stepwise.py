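"""Stepwise selection and commonality partition vs independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from vlt2model.errors import CollinearityError, ConfigError
from vlt2model.stepwise import commonality_analysis, stepwise_regression


def oracle_stepwise(y, X, p_enter=0.05, p_remove=0.10):
    """Independent re-implementation of the selection rules using
    statsmodels fits and R²-increment partial-F tests."""
    names = list(X.columns)
    y = np.asarray(y, float)
    n = len(y)
    tss = np.sum((y - y.mean()) ** 2)

    def r2(subset):
        if not subset:
            return 0.0
        model = sm.OLS(y, sm.add_constant(X[list(subset)])).fit()
        return model.rsquared

    def partial_p(small, big):
        df = n - len(big) - 1
        f = (r2(big) - r2(small)) / ((1 - r2(big)) / df)
        return stats.f.sf(f, 1, df)

    sel: list[str] = []
    while True:
        changed = False
        entries = []
        for c in (c for c in names if c not in sel):
            p = partial_p(sel, sel + [c])
            f_inc = r2(sel + [c]) - r2(sel)
            if p <= p_enter:
                entries.append((p, -f_inc, names.index(c), c))
        if entries:
            sel.append(min(entries)[3])
            changed = True
        while sel:
            removals = [
                (partial_p([s for s in sel if s != c], sel), c) for c in sel
            ]
            worst = max(removals)
            if worst[0] >= p_remove:
                sel.remove(worst[1])
                changed = True
            else:
                break
        if not changed:
            return tuple(sel)


class TestStepwise:
    def test_exact_relation_selects_single_predictor(self, rng):
        x1 = rng.normal(0, 1, 50)
        x2 = rng.normal(0, 1, 50)
        y = 2.0 * x1
        X = pd.DataFrame({"x1": x1, "x2": x2})
        model = stepwise_regression(y, X)
        assert model.final_predictors == ("x1",)
        assert model.final_coefficients["x1"][0] == pytest.approx(2.0, abs=1e-10)

    def test_matches_independent_oracle_on_many_datasets(self):
        """Final predictor set equals the oracle's on 50 seeded k=3 problems
        with varied correlation structure."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = 40
            z = r.normal(0, 1, n)
            X = pd.DataFrame(
                {
                    "a": z + r.normal(0, 0.8, n),
                    "b": z + r.normal(0, 0.8, n),
                    "c": r.normal(0, 1, n),
                }
            )
            coefs = r.normal(0, 1, 3) * r.integers(0, 2, 3)
            y = X.to_numpy() @ coefs + r.normal(0, 1.0, n)
            model = stepwise_regression(y, X)
            assert model.final_predictors == oracle_stepwise(y, X), f"seed {seed}"

    def test_permissive_thresholds_reduce_to_full_ols(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(0, 1, (n, 3)), columns=["a", "b", "c"])
        y = X @ [1.0, -0.5, 0.25] + rng.normal(0, 0.5, n)
        model = stepwise_regression(y, X, p_enter=1.0, p_remove=1.1)
        assert set(model.final_predictors) == {"a", "b", "c"}
        ref = sm.OLS(np.asarray(y), sm.add_constant(X)).fit()
        for name in ("a", "b", "c"):
            assert model.final_coefficients[name][0] == pytest.approx(
                ref.params[name], abs=1e-10
            )
            assert model.final_coefficients[name][1] == pytest.approx(
                ref.bse[name], abs=1e-10
            )

    def test_standardized_betas_identity(self, rng):
        n = 50
        X = pd.DataFrame(rng.normal(0, 2, (n, 2)), columns=["a", "b"])
        y = X @ [0.8, -1.2] + rng.normal(0, 1, n)
        model = stepwise_regression(y, X, p_enter=1.0, p_remove=1.1)
        sy = np.asarray(y).std(ddof=1)
        for name in ("a", "b"):
            beta, _, std_beta, _, _ = model.final_coefficients[name]
            assert std_beta == pytest.approx(
                beta * X[name].std(ddof=1) / sy, abs=1e-12
            )

    def test_r_squared_non_decreasing_over_entry_steps(self, rng):
        n = 60
        X = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
        y = X @ [1.0, 0.6, 0.3, 0.0] + rng.normal(0, 1, n)
        model = stepwise_regression(y, X)
        r2s = [s.r_squared for s in model.steps if s.action == "enter"]
        assert all(b >= a for a, b in zip(r2s, r2s[1:]))

    def test_constant_predictor_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(0, 1, 30), "b": np.ones(30)})
        with pytest.raises(CollinearityError):
            stepwise_regression(rng.normal(0, 1, 30), X)


def oracle_commonality(y, X):
    """Solve the commonality linear system M·C = R² directly (numpy route):
    for every nonempty A, R²(A) = Σ_{S: S∩A≠∅} C(S)."""
    from itertools import combinations

    y = np.asarray(y, float)
    names = list(X.columns)
    k = len(names)
    subsets = [
        frozenset(c)
        for size in range(1, k + 1)
        for c in combinations(range(k), size)
    ]

    def r2(idx):
        model = sm.OLS(y, sm.add_constant(X.iloc[:, sorted(idx)])).fit()
        return model.rsquared

    M = np.array(
        [[1.0 if s & a else 0.0 for s in subsets] for a in subsets]
    )
    rhs = np.array([r2(a) for a in subsets])
    C = np.linalg.solve(M, rhs)
    return {
        tuple(names[i] for i in sorted(s)): c for s, c in zip(subsets, C)
    }


class TestCommonality:
    def test_orthogonal_predictors_have_pure_unique_effects(self):
        rng = np.random.default_rng(3)
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)  # exactly orthogonal to x1
        y = 0.7 * x1 + 0.2 * x2 + rng.normal(0, 0.5, n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        rep = commonality_analysis(y, X)
        for name in ("x1", "x2"):
            r = rep.zero_order_r[name]
            assert rep.unique(name) == pytest.approx(r**2, abs=1e-10)
        assert rep.coefficients[("x1", "x2")] == pytest.approx(0.0, abs=1e-10)

    def test_suppression_triple_matches_subset_oracle(self, rng):
        """x2 nearly unrelated to y but correlated with x1: the shared
        component goes negative (suppression), matching the linear-system
        oracle to 1e-10."""
        n = 200
        x2 = rng.normal(0, 1, n)
        x1 = 0.6 * x2 + 0.8 * rng.normal(0, 1, n)
        y = x1 - 0.6 * x2 + rng.normal(0, 0.3, n)  # x2's direct effect cancels
        X = pd.DataFrame({"x1": x1, "x2": x2})
        rep = commonality_analysis(y, X)
        oracle = oracle_commonality(y, X)
        assert rep.coefficients[("x1", "x2")] < 0
        assert ("x1", "x2") in rep.suppression_subsets()
        for key, val in oracle.items():
            assert rep.coefficients[key] == pytest.approx(val, abs=1e-10)

    def test_partition_and_zero_order_identities_many_datasets(self):
        """Components sum to R²_full and per-predictor sums equal squared
        zero-order correlations, over 200 random k=3 datasets (1e-10)."""
        for seed in range(200):
            r = np.random.default_rng(1000 + seed)
            n = 30
            base = r.normal(0, 1, (n, 3))
            mix = r.normal(0, 0.7, (3, 3)) + np.eye(3)
            X = pd.DataFrame(base @ mix, columns=["a", "b", "c"])
            y = X @ r.normal(0, 1, 3) + r.normal(0, 1, n)
            rep = commonality_analysis(y, X)
            total = sum(rep.coefficients.values())
            assert total == pytest.approx(rep.r_squared_full, abs=1e-10)
            for name in ("a", "b", "c"):
                with_i = sum(
                    c for s, c in rep.coefficients.items() if name in s
                )
                assert with_i == pytest.approx(
                    rep.zero_order_r[name] ** 2, abs=1e-10
                ), f"seed {seed}, predictor {name}"

    def test_guard_on_predictor_count(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (40, 6)), columns=list("abcdef"))
        with pytest.raises(ConfigError):
            commonality_analysis(rng.normal(0, 1, 40), X)
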