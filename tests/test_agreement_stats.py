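"""Agreement statistics against independent oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vogcover import (
    ComputationError,
    InputError,
    PairedMeasurements,
    agreement_report,
    bland_altman,
    categorize_differences,
    icc,
    pearson,
)


def _pairs(a, b):
    a = np.asarray(a, float)
    return PairedMeasurements(subject_ids=tuple(range(a.size)),
                              values_a=a, values_b=np.asarray(b, float))


def _icc_oracle(x, model="ICC2"):
    """Scalar-loop ANOVA mean squares, written independently of the
    vectorized implementation."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum((x[i][j] - row[i] - col[j] + grand) ** 2
              for i in range(n) for j in range(k))
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    if model == "ICC2":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if model == "ICC3":
        return (msr - mse) / (msr + (k - 1) * mse)
    msw = (ssc + sse) / (n * (k - 1))
    return (msr - msw) / (msr + (k - 1) * msw)


class TestBlandAltman:
    def test_identical_vectors(self):
        r = bland_altman(_pairs([1, 2, 3], [1, 2, 3]))
        assert r.mean_diff == 0.0
        assert r.loa_halfwidth == 0.0

    def test_closed_form_two_point_case(self):
        # d = {-1, +1}: sd = sqrt(2), half-width = 1.96 * sqrt(2)
        r = bland_altman(_pairs([0.0, 1.0], [1.0, 0.0]))
        assert r.sd_diff == pytest.approx(np.sqrt(2), abs=1e-9)
        assert r.loa_halfwidth == pytest.approx(1.96 * np.sqrt(2), abs=1e-4)
        assert r.loa_halfwidth == pytest.approx(2.77186, abs=1e-4)

    def test_matches_closed_form_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(25, 7, 34)
            b = a + rng.normal(0, 2.5, 34)
            r = bland_altman(_pairs(a, b))
            d = a - b
            mean = d.sum() / d.size
            sd = np.sqrt(((d - mean) ** 2).sum() / (d.size - 1))
            assert r.mean_diff == pytest.approx(mean, abs=1e-9)
            assert r.loa_halfwidth == pytest.approx(1.96 * sd, abs=1e-9)
            assert r.loa_upper - r.mean_diff == pytest.approx(
                r.mean_diff - r.loa_lower, abs=1e-9)

    def test_antisymmetry_under_method_swap(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(20, 5, 30), rng.normal(20, 5, 30)
        r_ab = bland_altman(_pairs(a, b))
        r_ba = bland_altman(_pairs(b, a))
        assert r_ab.mean_diff == pytest.approx(-r_ba.mean_diff, abs=1e-12)
        assert r_ab.loa_halfwidth == pytest.approx(r_ba.loa_halfwidth, abs=1e-12)

    def test_simulated_interobserver_scale(self):
        # differences drawn to have a 4.63 PD LoA half-width; averaging
        # 50 replicates of 34 pairs keeps the Monte Carlo error of the
        # half-width estimate well inside the 25% plausibility band
        rng = np.random.default_rng(42)
        halfwidths = []
        for _ in range(50):
            a = rng.normal(25, 7, 34)
            b = a + rng.normal(0, 4.63 / 1.96, 34)
            halfwidths.append(bland_altman(_pairs(a, b)).loa_halfwidth)
        assert abs(np.mean(halfwidths) - 4.63) / 4.63 < 0.25


class TestICC:
    def test_identical_columns_give_unity(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        value, lo, hi = icc(x)
        assert value == 1.0

    def test_pure_noise_columns_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, size=(200, 2))
        value, _, _ = icc(x)
        assert abs(value) < 0.15

    def test_hand_made_matrix_matches_anova_oracle(self):
        x = np.array([[9.0, 2.0], [45.0, 41.0], [8.0, 13.0],
                      [6.0, 8.0], [8.0, 6.0], [10.0, 12.0]])
        for model in ("ICC1", "ICC2", "ICC3"):
            value, _, _ = icc(x, model=model)
            assert value == pytest.approx(_icc_oracle(x, model), abs=1e-9)

    def test_randomized_matrices_match_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = rng.integers(5, 20)
            k = rng.integers(2, 5)
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 5), size=(n, k))
            x += rng.normal(0, 3, size=(n, 1))  # subject effect
            for model in ("ICC1", "ICC2", "ICC3"):
                value, _, _ = icc(x, model=model)
                assert value == pytest.approx(_icc_oracle(x, model), abs=1e-9)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, size=(15, 3)) + rng.normal(0, 2, size=(15, 1))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score").set_index("Type")
        for model, pg_type in (("ICC1", "ICC(1,1)"), ("ICC2", "ICC(A,1)"),
                               ("ICC3", "ICC(C,1)")):
            value, lo, hi = icc(x, model=model)
            assert value == pytest.approx(ref.loc[pg_type, "ICC"], abs=1e-9)
            ci = ref.loc[pg_type, "CI95"]  # pingouin rounds the CI to 2 dp
            assert lo == pytest.approx(ci[0], abs=0.006)
            assert hi == pytest.approx(ci[1], abs=0.006)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 3, size=(12, 3))
        v1, _, _ = icc(x)
        v2, _, _ = icc(x + 100.0)
        assert v1 == pytest.approx(v2, abs=1e-9)

    def test_incomplete_matrix_rejected(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(InputError):
            icc(x)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(InputError):
            icc(np.array([[1.0, 2.0]]))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        a = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        b = np.array([2.0, 3.0, 2.5, 9.0, 4.0])
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        oracle = cov / (a.std() * b.std())
        assert pearson(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ComputationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCategorizeDifferences:
    def test_clinical_table_counts_and_percentages(self):
        diffs = [0.5] * 28 + [4.0] * 4 + [7.0] * 2
        table = categorize_differences(diffs)
        assert table.counts == (28, 4, 2)
        assert table.percentages == (82.4, 11.7, 5.9)
        assert table.cumulative_below_upper_pct == 94.1

    def test_all_zero_differences(self):
        table = categorize_differences([0.0] * 10)
        assert table.counts == (10, 0, 0)
        assert table.percentages == (100.0, 0.0, 0.0)

    def test_boundary_convention_closed_middle_bin(self):
        table = categorize_differences([2.9, 3.0, 5.0, 5.1])
        assert table.counts == (1, 2, 1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=60))
    def test_counts_sum_to_n_and_percentages_to_100(self, diffs):
        table = categorize_differences(diffs)
        assert sum(table.counts) == table.n == len(diffs)
        assert sum(table.percentages) == pytest.approx(100.0, abs=0.2)


class TestFullReport:
    def test_report_bundles_all_statistics(self):
        rng = np.random.default_rng(2)
        a = rng.normal(25, 7, 34)
        b = a + rng.normal(0, 2, 34)
        r = agreement_report(_pairs(a, b))
        assert r.icc is not None and r.icc_ci_low <= r.icc <= r.icc_ci_high
        assert -1 <= r.pearson_r <= 1
        assert r.n == 34
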