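import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foveoct.datasets import example_ovr_counts, example_paired_table
from foveoct.diagnostics import (
    McNemarInput,
    MulticlassMarginals,
    OneVsRestCounts,
    macro_summary,
    mcnemar,
    multiclass_agreement,
    per_class_rates,
    round_half_up,
)


def exact_binomial_two_sided(b: int, c: int) -> Fraction:
    """Enumeration oracle: exact fair-coin tail doubling over b + c trials."""
    n = b + c
    pmf = [Fraction(math.comb(n, k), 2**n) for k in range(n + 1)]
    lower = sum(pmf[: b + 1])
    upper = sum(pmf[b:])
    return min(Fraction(1), 2 * min(lower, upper))


def random_confusion_matrix(rng, k=3, n=60):
    m = rng.multinomial(n, rng.dirichlet(np.ones(k * k))).reshape(k, k)
    return m


def marginals_from_matrix(m):
    return MulticlassMarginals(
        classes=tuple(str(i) for i in range(m.shape[0])),
        diagonal=tuple(int(x) for x in np.diag(m)),
        true_totals=tuple(int(x) for x in m.sum(axis=1)),
        pred_totals=tuple(int(x) for x in m.sum(axis=0)),
        n=int(m.sum()),
    )


def labels_from_matrix(m):
    y_true, y_pred = [], []
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            y_true += [i] * m[i, j]
            y_pred += [j] * m[i, j]
    return y_true, y_pred


class TestPerClassRates:
    def test_published_wetamd_noisy_row(self):
        rates = per_class_rates(example_ovr_counts("noisy"))
        wet = rates[1]
        assert round_half_up(wet.sensitivity) == 0.2131
        assert round_half_up(wet.specificity) == 0.9623

    def test_published_dryamd_noisy_precision_and_f1(self):
        dry = per_class_rates(example_ovr_counts("noisy"))[0]
        assert dry.precision == pytest.approx(42 / 250)
        assert round_half_up(dry.f1) == 0.2763  # 2*0.168*0.7778/(0.168+0.7778)

    def test_perfect_class_all_ones(self):
        counts = OneVsRestCounts(("pos",), (10,), (0,), (0,), (90,))
        r = per_class_rates(counts)[0]
        assert (r.sensitivity, r.specificity, r.precision, r.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominators_reported_as_nan(self):
        counts = OneVsRestCounts(("pos",), (0,), (0,), (0,), (100,))
        r = per_class_rates(counts)[0]
        assert math.isnan(r.sensitivity) and math.isnan(r.precision) and math.isnan(r.f1)
        assert r.specificity == 1.0


class TestMacroSummary:
    def test_published_noisy_condition(self):
        s = macro_summary(example_ovr_counts("noisy"))
        assert round_half_up(s.overall_accuracy) == 0.6908
        assert round_half_up(s.balanced_accuracy) == 0.5715
        assert round_half_up(s.macro_precision) == 0.4742
        assert round_half_up(s.macro_recall) == 0.5715
        assert round_half_up(s.macro_f1) == 0.4496
        assert round_half_up(s.weighted_f1) == 0.7472

    def test_published_denoised_condition(self):
        s = macro_summary(example_ovr_counts("denoised"))
        assert round_half_up(s.balanced_accuracy) == 0.9945
        assert round_half_up(s.macro_f1) == 0.9942
        assert round_half_up(s.overall_accuracy) == 0.9988

    def test_identity_case_every_class_perfect(self):
        counts = OneVsRestCounts(("a", "b"), (30, 70), (0, 0), (0, 0), (70, 30))
        s = macro_summary(counts)
        assert all(
            v == 1.0
            for v in (s.overall_accuracy, s.balanced_accuracy, s.macro_precision,
                      s.macro_recall, s.macro_f1, s.weighted_f1)
        )

    def test_undefined_class_metric_propagates(self):
        counts = OneVsRestCounts(("a", "b"), (0, 50), (0, 50), (50, 0), (50, 0))
        assert math.isnan(macro_summary(counts).macro_f1)


class TestMulticlassAgreement:
    def test_published_noisy_marginals(self):
        ag = multiclass_agreement(example_ovr_counts("noisy").marginals())
        assert round_half_up(ag.mcc) == 0.2912
        assert round_half_up(ag.kappa) == 0.2426

    def test_published_denoised_marginals(self):
        ag = multiclass_agreement(example_ovr_counts("denoised").marginals())
        assert round_half_up(ag.mcc) == 0.9952
        assert round_half_up(ag.kappa) == 0.9952

    def test_perfect_agreement(self):
        m = marginals_from_matrix(np.diag([5, 7, 9]))
        ag = multiclass_agreement(m)
        assert ag.mcc == 1.0 and ag.kappa == 1.0

    def test_constant_predictor_degenerate_zero(self):
        m = np.zeros((3, 3), dtype=int)
        m[:, 0] = [10, 5, 5]  # everything predicted as class 0
        ag = multiclass_agreement(marginals_from_matrix(m))
        assert ag.mcc == 0.0 and ag.kappa == 0.0 and ag.degenerate

    def test_marginal_form_equals_full_matrix_form(self, rng):
        """The marginal-only MCC/kappa must agree with scikit-learn computed
        from the full label vectors (independent implementation)."""
        from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

        for _ in range(20):
            m = random_confusion_matrix(rng)
            if np.any(m.sum(axis=0) == 0) or np.any(m.sum(axis=1) == 0):
                continue
            y_true, y_pred = labels_from_matrix(m)
            ag = multiclass_agreement(marginals_from_matrix(m))
            if ag.degenerate:
                continue
            assert ag.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
            assert ag.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(50):
            m = random_confusion_matrix(rng)
            if np.any(m.sum(axis=0) == 0) or np.any(m.sum(axis=1) == 0):
                continue
            ag = multiclass_agreement(marginals_from_matrix(m))
            assert -1.0 <= ag.mcc <= 1.0 and -1.0 <= ag.kappa <= 1.0

    def test_inconsistent_marginals_rejected(self):
        with pytest.raises(ValueError):
            MulticlassMarginals(("a", "b"), (1, 1), (2, 2), (1, 2), 4)

    def test_reconstruction_consistency_with_paired_table(self):
        # correct-under-noisy count from the paired table equals the diagonal sum
        counts = example_ovr_counts("noisy")
        paired = example_paired_table()
        assert sum(counts.tp) == paired.a + paired.c == 592
        assert counts.n == paired.n == 857


class TestMcNemar:
    def test_published_worked_example(self):
        r = mcnemar(McNemarInput(a=592, b=264, c=0, d=1))
        assert round_half_up(r.chi2_cc) == 262.0038
        assert r.chi2_unc == 264.0
        assert r.p_cc < 1e-6 and r.p_unc < 1e-6
        assert r.p_exact < 1e-12

    def test_symmetric_null(self):
        r = mcnemar(McNemarInput(0, 5, 5, 0))
        assert r.chi2_unc == 0.0 and r.p_unc == 1.0

    def test_exact_p_small_case(self):
        assert mcnemar(McNemarInput(0, 3, 1, 0)).p_exact == pytest.approx(0.625)

    @pytest.mark.parametrize("b,c", [(0, 0), (1, 0), (3, 1), (6, 6), (12, 0), (5, 7), (2, 9)])
    def test_exact_p_equals_enumeration(self, b, c):
        r = mcnemar(McNemarInput(0, b, c, 0))
        assert r.p_exact == pytest.approx(float(exact_binomial_two_sided(b, c)), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(264, 0), (10, 3), (7, 7), (1, 20)]:
            ours = mcnemar(McNemarInput(0, b, c, 0))
            table = [[0, b], [c, 0]]
            exact = sm_mcnemar(table, exact=True)
            chi = sm_mcnemar(table, exact=False, correction=True)
            assert ours.p_exact == pytest.approx(float(exact.pvalue), abs=1e-12)
            assert ours.chi2_cc == pytest.approx(float(chi.statistic), abs=1e-9)

    @given(st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=60, deadline=None)
    def test_swap_symmetry(self, b, c):
        r1 = mcnemar(McNemarInput(0, b, c, 0))
        r2 = mcnemar(McNemarInput(0, c, b, 0))
        if b + c == 0:
            assert r1.degenerate and r2.degenerate and r1.p_exact == r2.p_exact == 1.0
            return
        assert r1.chi2_cc == r2.chi2_cc and r1.chi2_unc == r2.chi2_unc
        assert r1.p_exact == pytest.approx(r2.p_exact, abs=1e-12)

    def test_continuity_correction_shrinks_statistic(self):
        r = mcnemar(McNemarInput(0, 10, 4, 0))
        assert r.chi2_cc <= r.chi2_unc

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            McNemarInput(1, -1, 0, 0)


class TestCountValidation:
    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError):
            OneVsRestCounts(("a", "b"), (5, 5), (5, 5), (5, 4), (85, 85))

    def test_rounding_half_up(self):
        assert round_half_up(0.26315, 4) == 0.2632
        assert round_half_up(0.00005, 4) == 0.0001
        assert round_half_up(-0.00005, 4) == -0.0001
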