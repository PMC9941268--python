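"""Agreement statistics vs independent oracles (ANOVA sums, pingouin)."""

import numpy as np
import pandas as pd
import pytest

from vlt2model.agreement import (
    bland_altman,
    compare_groups,
    icc_absolute_agreement,
    icc_label,
    loa_percent,
    pearson_with_label,
)
from vlt2model.errors import PairingError, UndefinedStatisticError


class TestBlandAltman:
    def test_identical_pairs_all_zero(self, rng):
        x = rng.normal(3.4, 0.4, 20)
        bias, sd, lo, hi, pct = bland_altman(x, x)
        assert bias == 0 and sd == 0 and lo == 0 and hi == 0 and pct == 0

    def test_hand_computed_sd(self):
        measured = np.array([3.0, 3.4, 3.8])
        modeled = measured + np.array([-0.1, 0.0, 0.1])
        bias, sd, lo, hi, _ = bland_altman(modeled, measured)
        assert bias == pytest.approx(0.0, abs=1e-15)
        assert sd == pytest.approx(0.1, abs=1e-12)
        assert hi == pytest.approx(0.196, abs=1e-12)
        assert lo == pytest.approx(-0.196, abs=1e-12)

    def test_percent_convention_reproduces_published_values(self):
        # half-widths 0.12 and 0.26 on a criterion mean of 3.38 m/s
        assert loa_percent(0.12, 3.38) == 4
        assert loa_percent(0.26, 3.38) == 8

    def test_length_mismatch(self):
        with pytest.raises(PairingError):
            bland_altman([1, 2, 3], [1, 2])


class TestIcc:
    def test_identical_columns_give_one(self, rng):
        x = rng.normal(3.4, 0.4, 12)
        icc, (lo, hi) = icc_absolute_agreement(np.column_stack([x, x]))
        assert icc == pytest.approx(1.0, abs=1e-12)
        assert lo <= icc <= hi

    def test_matches_anova_sums_oracle(self):
        """4×2 toy matrix vs mean squares computed from explicit sums."""
        x = np.array([[3.1, 3.0], [3.5, 3.6], [3.9, 3.7], [3.3, 3.4]])
        n, k = x.shape
        grand = x.sum() / x.size
        msr = k * sum((r.mean() - grand) ** 2 for r in x) / (n - 1)
        msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
        sse = sum(
            (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
            for i in range(n)
            for j in range(k)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        icc, _ = icc_absolute_agreement(x)
        assert icc == pytest.approx(expected, abs=1e-10)

    def test_constant_offset_reduces_absolute_agreement(self, rng):
        x = rng.normal(3.4, 0.4, 30)
        pairs = np.column_stack([x, x + rng.normal(0, 0.05, 30)])
        shifted = pairs.copy()
        shifted[:, 1] += 0.3
        assert icc_absolute_agreement(shifted)[0] < icc_absolute_agreement(pairs)[0]

    def test_invariant_to_common_shift_and_scale(self, rng):
        pairs = np.column_stack(
            [rng.normal(3.4, 0.4, 25), rng.normal(3.4, 0.4, 25)]
        )
        base, _ = icc_absolute_agreement(pairs)
        shifted, _ = icc_absolute_agreement(pairs + 5.0)
        scaled, _ = icc_absolute_agreement(pairs * 2.5)
        assert shifted == pytest.approx(base, abs=1e-12)
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(3.4, 0.4, 40)
        y = x + rng.normal(0.05, 0.12, 40)
        icc, (lo, hi) = icc_absolute_agreement(np.column_stack([x, y]))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile(["m", "c"], 40),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        ref_lo, ref_hi = ref.loc["ICC(A,1)", "CI95"]  # rounded to 2 dp
        assert lo == pytest.approx(ref_lo, abs=6e-3)
        assert hi == pytest.approx(ref_hi, abs=6e-3)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_absolute_agreement(np.full((5, 2), 3.0))

    def test_interpretation_bands(self):
        assert icc_label(0.3) == "poor"
        assert icc_label(0.6) == "moderate"
        assert icc_label(0.8) == "good"
        assert icc_label(0.95) == "excellent"


class TestPearson:
    def test_perfect_correlation(self, rng):
        x = rng.normal(0, 1, 15)
        r, label = pearson_with_label(x, x)
        assert r == pytest.approx(1.0)
        assert label == "very high"

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(0, 1, 10)
        y = 0.6 * x + rng.normal(0, 0.8, 10)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, _ = pearson_with_label(x, y)
        assert r == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "r,label",
        [(0.1, "negligible"), (0.4, "low"), (0.5, "low"), (-0.6, "moderate"),
         (0.8, "high"), (0.95, "very high")],
    )
    def test_band_labels(self, r, label, rng):
        # construct data with (almost) exactly the requested correlation
        n = 2000
        x = rng.normal(0, 1, n)
        e = rng.normal(0, 1, n)
        e -= np.polyval(np.polyfit(x, e, 1), x)  # orthogonalize
        x = (x - x.mean()) / x.std()
        e = e / e.std()
        y = r * x + np.sqrt(1 - r**2) * e * np.sign(1)
        got_r, got_label = pearson_with_label(x, y)
        assert got_r == pytest.approx(r, abs=1e-9)
        assert got_label == label

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_with_label([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupComparison:
    def test_identical_groups(self):
        t, df, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_pooled_variance_hand_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        expected_t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        t, df, _ = compare_groups(a, b)
        assert t == pytest.approx(expected_t, abs=1e-12)
        assert df == 4

    def test_swapping_groups_flips_sign(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, _, p1 = compare_groups(a, b)
        t2, _, p2 = compare_groups(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_welch_mode_differs_under_heteroscedasticity(self, rng):
        a = rng.normal(0, 0.2, 8)
        b = rng.normal(0.3, 2.0, 30)
        _, df_s, _ = compare_groups(a, b, "student")
        _, df_w, _ = compare_groups(a, b, "welch")
        assert df_w != df_s

    def test_tiny_group_rejected(self):
        with pytest.raises(PairingError):
            compare_groups([1.0], [1.0, 2.0])
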