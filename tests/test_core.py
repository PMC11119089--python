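import math

import numpy as np
import pytest

from lrtab import (
    chi2_cdf,
    chi2_sf,
    closed_form_log_lr,
    expansion_diagnostic,
    expected_from_counts,
    expected_from_margins,
    expected_from_probabilities,
    lrt,
    make_table,
    pearson_x2,
    signed_root_x,
    support_s,
    svar,
    variance_x2_test,
    williams_corrected_lrt,
)

# Frozen oracle values: direct evaluation of the defining formulas with
# scipy.special (see comments on each).
LARGE_X2 = 8.080808080808081          # sum (O-E)^2/E, E=[[100,9900],[100,9900]]
LARGE_S = 4.067506778050699           # sum O ln(O/E), same E
SMALL_X2_MARGINS = 3.793891061128102
SMALL_2S_MARGINS = 4.001179335352305
SMALL_X2_PROBS = 3.487583529232511
SMALL_2S_PROBS = 4.497798577839653
SVAR_AT_808 = 2.495304063733498       # (1/2)ln(1/8.08) - (1-8.08)/2
CDF_1_1 = 0.6826894921370859          # chi2 cdf at x=1, df=1


class TestPearsonX2:
    def test_large_trial(self, large_trial):
        res = pearson_x2(large_trial, expected_from_margins(large_trial))
        assert res.statistic == pytest.approx(LARGE_X2, rel=1e-12)
        assert round(res.statistic, 2) == 8.08
        assert res.p_value == pytest.approx(0.004473649256611767, rel=1e-9)
        assert res.tail == "right"

    def test_small_trial_probability_expected(self, small_trial, replication_probs):
        model = expected_from_probabilities(replication_probs, N=2000)
        res = pearson_x2(small_trial, model)
        assert round(res.statistic, 2) == 3.49
        assert res.statistic == pytest.approx(SMALL_X2_PROBS, rel=1e-12)

    def test_perfect_fit(self):
        t = make_table([[5, 5], [5, 5]])
        res = pearson_x2(t, expected_from_margins(t))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_shape_mismatch(self, large_trial, small_trial):
        model = expected_from_margins(small_trial)
        big = make_table([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError, match="shapes differ"):
            pearson_x2(big, model)

    def test_degenerate_model_statistic_zero(self):
        t = make_table([[0, 10], [0, 20]])
        res = pearson_x2(t, expected_from_margins(t))
        assert res.statistic == 0.0
        assert res.degenerate

    def test_observed_against_impossible_cell(self, small_trial):
        model = expected_from_counts([[0.0, 1000.0], [10.0, 990.0]])
        res = pearson_x2(small_trial, model)
        assert math.isinf(res.statistic)
        assert res.infinite
        assert res.p_value == 0.0

    def test_matches_scipy_contingency(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(25):
            t = make_table(rng.integers(1, 200, size=(2, 2)))
            res = pearson_x2(t, expected_from_margins(t))
            ref = chi2_contingency(t.counts, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


class TestSupportS:
    def test_small_trial_margins(self, small_trial):
        res = support_s(small_trial, expected_from_margins(small_trial))
        assert res.S == pytest.approx(SMALL_2S_MARGINS / 2, rel=1e-12)
        assert round(2 * res.S, 2) == 4.00
        assert res.kind == "proportions"

    def test_large_trial(self, large_trial):
        res = support_s(large_trial, expected_from_margins(large_trial))
        assert res.S == pytest.approx(LARGE_S, rel=1e-12)

    def test_perfect_fit_is_zero(self):
        t = make_table([[5, 5], [5, 5]])
        res = support_s(t, expected_from_margins(t))
        assert res.S == 0.0
        assert res.grade.label == "none"

    def test_zero_cells_use_convention(self):
        # 0 ln 0 := 0 keeps S finite with empty cells
        t = make_table([[1, 0], [0, 1]])
        res = support_s(t, expected_from_margins(t))
        assert math.isfinite(res.S)

    def test_impossible_event_gives_infinite_support(self, small_trial):
        model = expected_from_counts([[0.0, 1000.0], [10.0, 990.0]])
        res = support_s(small_trial, model)
        assert res.S == math.inf
        assert res.infinite


class TestLrt:
    def test_large_trial(self, large_trial):
        res = lrt(large_trial, expected_from_margins(large_trial))
        # 2S = 8.135014 exactly; printed 8.13 is a double rounding of 8.135
        assert res.statistic == pytest.approx(2 * LARGE_S, rel=1e-12)
        assert abs(res.statistic - 8.13) <= 0.0055
        assert round(res.p_value, 3) == 0.004

    def test_small_trial_margins(self, small_trial):
        res = lrt(small_trial, expected_from_margins(small_trial))
        assert round(res.statistic, 2) == 4.00
        assert round(res.p_value, 3) == 0.045

    def test_small_trial_probability_expected(self, small_trial, replication_probs):
        model = expected_from_probabilities(replication_probs, N=2000)
        res = lrt(small_trial, model)
        assert round(res.statistic, 2) == 4.50
        assert round(res.p_value, 3) == 0.034

    def test_matches_scipy_g_test(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(25):
            t = make_table(rng.integers(1, 200, size=(2, 2)))
            res = lrt(t, expected_from_margins(t))
            ref = chi2_contingency(
                t.counts, correction=False, lambda_="log-likelihood"
            )
            assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)


class TestClosedFormLogLr:
    def test_equals_support_small_trial(self, small_trial):
        s = support_s(small_trial, expected_from_margins(small_trial)).S
        assert closed_form_log_lr(small_trial) == pytest.approx(s, rel=1e-9)

    def test_identical_rows_zero(self):
        assert closed_form_log_lr(make_table([[5, 5], [5, 5]])) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_table(self):
        # a=d=1, b=c=0: all margins 1, N=2 -> ln LR = 2 ln 2
        assert closed_form_log_lr(make_table([[1, 0], [0, 1]])) == pytest.approx(
            2 * math.log(2), rel=1e-12
        )

    def test_requires_2x2(self):
        with pytest.raises(ValueError, match="2x2"):
            closed_form_log_lr(make_table([[1, 2, 3], [4, 5, 6]]))


class TestExpansionDiagnostic:
    def test_replication_table_valid(self, small_trial, replication_probs):
        model = expected_from_probabilities(replication_probs, N=2000)
        diag = expansion_diagnostic(small_trial, model)
        # |3-8|=5 < 8, |997-992|=5 < 992, |10-12|=2 < 12, |990-988|=2 < 988
        assert diag.valid
        assert diag.offending_cells == ()

    def test_boundary_of_strict_inequality(self):
        # O=0 against E=4: |0-4| = 4 >= 4, not strictly less
        t = make_table([[0, 8], [4, 4]])
        model = expected_from_counts([[4.0, 4.0], [4.0, 4.0]])
        diag = expansion_diagnostic(t, model)
        assert not diag.valid
        assert (0, 0) in diag.offending_cells

    def test_perfect_fit_all_terms_zero(self):
        t = make_table([[5, 5], [5, 5]])
        diag = expansion_diagnostic(t, expected_from_margins(t), max_order=6)
        assert diag.valid
        assert all(term == 0.0 for term in diag.terms)

    def test_leading_term_is_half_x2(self, small_trial, replication_probs):
        model = expected_from_probabilities(replication_probs, N=2000)
        diag = expansion_diagnostic(small_trial, model)
        x2 = pearson_x2(small_trial, model).statistic
        assert diag.terms[0] == pytest.approx(x2 / 2, rel=1e-12)

    def test_partial_sums_converge_to_support(self):
        t = make_table([[45, 55], [55, 45]])
        model = expected_from_margins(t)
        s = support_s(t, model).S
        diag = expansion_diagnostic(t, model, max_order=8)
        errors = [abs(ps - s) for ps in diag.partial_sums]
        assert errors[-1] < errors[0]
        assert errors[-1] < 1e-6

    def test_min_order(self, small_trial):
        with pytest.raises(ValueError, match="max_order"):
            expansion_diagnostic(
                small_trial, expected_from_margins(small_trial), max_order=1
            )


class TestVarianceX2:
    def test_perfect_fit_left_p_zero(self):
        t = make_table([[5, 5], [5, 5]])
        res = variance_x2_test(t, expected_from_margins(t))
        assert res.statistic == 0.0
        assert res.p_value == 0.0
        assert res.tail == "left"

    def test_left_tail_at_critical_value(self):
        # left-tail p at the 5% critical value is 0.95
        assert chi2_cdf(3.841458820694124, 1) == pytest.approx(0.95, abs=1e-9)

    def test_left_tail_at_df(self):
        assert chi2_cdf(1.0, 1) == pytest.approx(CDF_1_1, rel=1e-12)

    def test_statistic_same_as_pearson(self, large_trial):
        model = expected_from_margins(large_trial)
        assert variance_x2_test(large_trial, model).statistic == pytest.approx(
            pearson_x2(large_trial, model).statistic
        )

    def test_tails_sum_to_one(self):
        for x in [0.1, 1.0, 3.84, 10.0, 50.0]:
            for df in [1, 2, 5]:
                assert chi2_sf(x, df) + chi2_cdf(x, df) == pytest.approx(
                    1.0, abs=1e-12
                )


class TestSvar:
    def test_zero_at_x2_equal_df(self):
        for df in range(1, 11):
            assert svar(float(df), df).S == 0.0

    def test_infinite_at_zero(self):
        res = svar(0.0, 1)
        assert res.S == math.inf
        assert res.infinite
        assert res.grade.label == "million_to_one"

    def test_value_at_808(self):
        res = svar(8.08, 1)
        assert res.S == pytest.approx(SVAR_AT_808, rel=1e-12)
        assert res.best_v2 == 8.08

    def test_two_svar_chi2_conversion(self):
        res = svar(8.08, 1)
        chi = res.as_chi2()
        assert chi.name == "svar_x2"
        assert chi.statistic == pytest.approx(2 * SVAR_AT_808, rel=1e-12)
        assert chi.tail == "right"

    def test_negative_x2_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            svar(-1.0, 1)

    def test_nonnegative_everywhere(self):
        grid = np.linspace(0.01, 60, 400)
        for df in range(1, 11):
            vals = [svar(float(x), df).S for x in grid]
            assert min(vals) >= 0.0


class TestWilliamsCorrection:
    def test_negligible_at_moderate_n(self):
        # all margins 100, a=60 -> correction shifts the statistic by < 1%
        t = make_table([[60, 40], [40, 60]])
        raw = lrt(t, expected_from_margins(t)).statistic
        corrected = williams_corrected_lrt(t).statistic
        assert corrected < raw
        assert abs(corrected - raw) / raw < 0.01

    def test_always_shrinks(self, rng):
        for _ in range(20):
            t = make_table(rng.integers(1, 100, size=(2, 2)))
            raw = lrt(t, expected_from_margins(t)).statistic
            corrected = williams_corrected_lrt(t).statistic
            if raw > 0:
                assert corrected < raw

    def test_zero_statistic_unchanged(self):
        assert williams_corrected_lrt(make_table([[50, 50], [50, 50]])).statistic == 0.0

    def test_explicit_q_formula(self):
        t = make_table([[60, 40], [40, 60]])
        raw = lrt(t, expected_from_margins(t)).statistic
        n = 200
        q = 1 + (n / 100 + n / 100 - 1) * (n / 100 + n / 100 - 1) / (6 * n)
        assert williams_corrected_lrt(t).statistic == pytest.approx(raw / q, rel=1e-12)


class TestSignedRootX:
    def test_zero_at_perfect_fit(self):
        t = make_table([[5, 5], [5, 5]])
        assert signed_root_x(t, expected_from_margins(t)) == 0.0

    def test_large_trial_sign_and_magnitude(self, large_trial):
        x = signed_root_x(large_trial, expected_from_margins(large_trial))
        assert x == pytest.approx(-math.sqrt(LARGE_X2), rel=1e-12)

    def test_row_swap_flips_sign(self, large_trial):
        swapped = make_table(large_trial.counts[::-1])
        a = signed_root_x(large_trial, expected_from_margins(large_trial))
        b = signed_root_x(swapped, expected_from_margins(swapped))
        assert b == pytest.approx(-a, rel=1e-12)
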