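"""Agreement and diagnostic statistics against independent oracles."""

import numpy as np
import pytest

from apneaflow.metrics import (
    bland_altman,
    binary_diagnostics,
    build_confusion_4,
    cohen_kappa,
    diagnostic_report,
    icc,
    rmse,
)


def icc_anova_oracle(a, b):
    """Explicit two-way ANOVA mean-squares computation for ICC(A,1)."""
    table = np.column_stack([a, b]).astype(float)
    n, k = table.shape
    grand = table.mean()
    ms_rows = k * np.sum((table.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((table.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = table - table.mean(axis=1, keepdims=True) - table.mean(axis=0) + grand
    ms_err = np.sum(resid**2) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err + k / n * (ms_cols - ms_err))


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 4.0, 7.0, 2.0, 9.0])
        assert icc(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_is_negative(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert icc(x, -x) < 0

    def test_hand_table_matches_anova_oracle(self):
        a = np.array([4.0, 7.0, 10.0, 6.0, 3.0])
        b = np.array([5.0, 8.0, 9.0, 8.0, 2.0])
        assert icc(a, b) == pytest.approx(icc_anova_oracle(a, b), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        """Cross-check against the reference implementation of two-way
        single-measure absolute agreement (ICC2)."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(0)
        a = rng.uniform(0, 20, 40)
        b = a + rng.normal(0, 3, 40)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(40), 2),
                "rater": np.repeat(["psg", "model"], 40),
                "score": np.concatenate([a, b]),
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        ref_val = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc(a, b) == pytest.approx(ref_val, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])


class TestRMSE:
    def test_identical_zero(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_offset(self):
        assert rmse([1, 2, 3], [3.5, 4.5, 5.5]) == pytest.approx(2.5)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert rmse(a, b) == pytest.approx(np.sqrt(np.mean((a - b) ** 2)), abs=1e-12)


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (ba.mean_diff, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_plus_minus_one_differences(self):
        """diffs {-1, +1}: mean 0, SD (n-1 denominator) = sqrt(2)."""
        ba = bland_altman([0.0, 0.0], [-1.0, 1.0])
        assert ba.mean_diff == 0.0
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-12)
        assert ba.loa_low == pytest.approx(-1.96 * np.sqrt(2.0), abs=1e-12)

    def test_sign_convention_overestimation_positive(self):
        ba = bland_altman([1.0, 2.0, 3.0], [2.0, 3.0, 4.5])
        assert ba.mean_diff > 0

    def test_limits_order_invariant(self):
        rng = np.random.default_rng(2)
        ba = bland_altman(rng.uniform(0, 20, 30), rng.uniform(0, 20, 30))
        assert ba.loa_low <= ba.mean_diff <= ba.loa_high


class TestKappa:
    def test_diagonal_matrix_is_one(self):
        assert cohen_kappa(np.diag([5, 3, 2, 7])) == 1.0

    def test_chance_agreement_is_zero(self):
        # rows proportional to column marginals -> observed = expected
        m = np.array([[16, 24], [24, 36]])
        assert cohen_kappa(m) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # p_o = 4/6, p_e = 1/2 -> kappa = 1/3
        assert cohen_kappa(np.array([[2, 1], [1, 2]])) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 200)
        b = np.where(rng.uniform(size=200) < 0.6, a, rng.integers(0, 4, 200))
        m = np.zeros((4, 4), dtype=int)
        for i, j in zip(a, b):
            m[i, j] += 1
        assert cohen_kappa(m) == pytest.approx(
            sklearn_metrics.cohen_kappa_score(a, b), abs=1e-12
        )

    def test_symmetrization_changes_kappa_with_asymmetric_marginals(self):
        """Averaging a confusion matrix with its transpose alters kappa when
        the marginals are asymmetric — guards against accidental
        symmetrization inside the implementation."""
        m = np.array([[10, 8], [0, 2]])
        sym = (m + m.T) / 2
        assert cohen_kappa(m) == pytest.approx(0.2, abs=1e-12)
        assert cohen_kappa(sym) != pytest.approx(cohen_kappa(m), abs=1e-6)
        # with symmetric marginals the symmetrized matrix agrees
        m_sym_marg = np.array([[6, 2], [2, 6]])
        assert cohen_kappa((m_sym_marg + m_sym_marg.T) / 2) == pytest.approx(
            cohen_kappa(m_sym_marg), abs=1e-12
        )

    def test_degenerate_single_cell(self):
        # all mass on one diagonal cell: perfect agreement, defined as 1
        assert cohen_kappa(np.array([[7, 0], [0, 0]])) == 1.0
        # all mass on one off-diagonal cell: p_o = p_e = 0 -> kappa 0
        assert cohen_kappa(np.array([[0, 9], [0, 0]])) == 0.0


class TestBinaryDiagnostics:
    def test_perfect_prediction(self):
        a = [0.2, 3.0, 8.0, 12.0]
        d = binary_diagnostics(a, a, cutoff=5.0)
        assert (d.se, d.sp, d.acc, d.ppv, d.npv) == (100.0, 100.0, 100.0, 100.0, 100.0)
        assert d.lr_neg == 0.0

    def test_counts_example(self):
        """TP=8, FN=2, TN=9, FP=1 -> Se 80%, Sp 90%, LR+ = 0.8/0.1 = 8."""
        actual = [10.0] * 10 + [0.0] * 10
        est = [10.0] * 8 + [0.0] * 2 + [0.0] * 9 + [10.0]
        d = binary_diagnostics(actual, est, cutoff=5.0)
        assert (d.tp, d.fn, d.tn, d.fp) == (8, 2, 9, 1)
        assert d.se == pytest.approx(80.0)
        assert d.sp == pytest.approx(90.0)
        assert d.lr_pos == pytest.approx(8.0)

    def test_all_predicted_positive_flags_degenerate_ratio(self):
        d = binary_diagnostics([0.0, 10.0, 0.0, 10.0], [10.0] * 4, cutoff=5.0)
        assert d.sp == 0.0
        assert d.undefined  # the 0/0 likelihood ratio is flagged, not silent
        assert "lr_neg" in d.undefined

    def test_no_actual_positives_flags_sensitivity(self):
        d = binary_diagnostics([0.0, 0.0, 0.0], [0.0, 10.0, 0.0], cutoff=5.0)
        assert "se" in d.undefined and np.isnan(d.se)

    def test_monotone_relabeling_invariance(self):
        """Any AHI transform preserving the >=cutoff partition preserves the
        binary metrics."""
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 20, 50)
        e = rng.uniform(0, 20, 50)
        d1 = binary_diagnostics(a, e, 5.0)
        warp = lambda x: np.where(x >= 5.0, 5.0 + 3 * (x - 5.0) ** 2, x / 7.0)
        d2 = binary_diagnostics(warp(a), warp(e), 5.0)
        assert (d1.tp, d1.fn, d1.tn, d1.fp) == (d2.tp, d2.fn, d2.tn, d2.fp)


class TestConfusion4:
    def test_all_correct_diagonal(self):
        labels = ["no_osa", "mild", "moderate", "severe", "mild"]
        m = build_confusion_4(labels, labels)
        assert np.trace(m) == 5 and m.sum() == 5

    def test_single_misclassification_cell(self):
        m = build_confusion_4(["mild"], ["moderate"])
        assert m[1, 2] == 1 and m.sum() == 1

    def test_totals_preserved(self):
        rng = np.random.default_rng(6)
        classes = ["no_osa", "mild", "moderate", "severe"]
        a = [classes[i] for i in rng.integers(0, 4, 120)]
        p = [classes[i] for i in rng.integers(0, 4, 120)]
        assert build_confusion_4(a, p).sum() == 120


class TestReport:
    def test_acc4_is_trace_over_total(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 20, 60)
        e = np.clip(a + rng.normal(0, 2, 60), 0, None)
        rep = diagnostic_report(a, e)
        assert rep.acc4 == pytest.approx(100.0 * np.trace(rep.confusion) / 60)
        assert rep.confusion.sum() == 60
        assert rep.bland_altman.loa_low <= rep.bland_altman.mean_diff <= rep.bland_altman.loa_high
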