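"""Confusion metrics, aggregates, net benefit and Cohen's kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)

from polarcnn.metrics import (
    AgreementResult,
    ConfusionCounts,
    aggregate_runs,
    cohen_kappa,
    compute_metrics,
    confusion,
    decision_curve,
    metrics_from_labels,
    net_benefit,
)

label_vectors = st.lists(
    st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60
)


def vectors_from_counts(c: ConfusionCounts):
    ref = [1] * (c.TP + c.FN) + [0] * (c.TN + c.FP)
    pred = [1] * c.TP + [0] * c.FN + [0] * c.TN + [1] * c.FP
    return np.array(pred), np.array(ref)


class TestConfusion:
    def test_counts_from_clinical_style_vectors(self):
        pred, ref = vectors_from_counts(ConfusionCounts(15, 25, 1, 5))
        assert confusion(pred, ref) == ConfusionCounts(TP=15, TN=25, FP=1, FN=5)

    def test_perfect_agreement_has_no_errors(self):
        ref = np.array([1, 0, 1, 0])
        c = confusion(ref, ref)
        assert c.FP == c.FN == 0

    def test_six_case_toy_vector_by_enumeration(self):
        pred = [1, 1, 0, 0, 1, 0]
        ref = [1, 0, 1, 0, 1, 1]
        assert confusion(pred, ref) == ConfusionCounts(TP=2, TN=1, FP=1, FN=2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(pairs=label_vectors)
    def test_matches_sklearn_confusion_matrix(self, pairs):
        pred, ref = zip(*pairs)
        c = confusion(pred, ref)
        m = confusion_matrix(ref, pred, labels=[0, 1])
        assert (c.TN, c.FP, c.FN, c.TP) == tuple(m.ravel())


class TestMetricFormulas:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (
                ConfusionCounts(15, 25, 1, 5),
                dict(
                    ACC=0.8696, AUC=0.8558, F1S=0.8333,
                    SEN=0.7500, SPE=0.9615, PRE=0.9375,
                ),
            ),
            (
                ConfusionCounts(13, 25, 1, 7),
                dict(
                    ACC=0.8261, AUC=0.8058, F1S=0.7647,
                    SEN=0.6500, SPE=0.9615, PRE=0.9286,
                ),
            ),
        ],
    )
    def test_worked_confusion_examples(self, counts, expected):
        m = compute_metrics(counts).as_dict()
        for name, val in expected.items():
            assert m[name] == pytest.approx(val, abs=5e-5), name

    def test_perfect_classifier_scores_one_everywhere(self):
        m = compute_metrics(ConfusionCounts(5, 7, 0, 0))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_zero_denominator_yields_undefined_sentinel(self):
        m = compute_metrics(ConfusionCounts(0, 10, 0, 0))
        assert np.isnan(m.SEN) and np.isnan(m.PRE)
        assert m.SPE == 1.0 and m.ACC == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(pairs=label_vectors)
    def test_equivalence_with_direct_label_computation(self, pairs):
        pred, ref = np.array([p for p, _ in pairs]), np.array(
            [r for _, r in pairs]
        )
        m = metrics_from_labels(pred, ref)
        assert m.ACC == pytest.approx(accuracy_score(ref, pred))
        if (ref == 1).any():
            assert m.SEN == pytest.approx(recall_score(ref, pred, zero_division=0))
        if (pred == 1).any():
            assert m.PRE == pytest.approx(precision_score(ref, pred))
        if len(np.unique(ref)) == 2:
            # two-point ROC: AUC identically (SEN+SPE)/2
            assert m.AUC == pytest.approx(roc_auc_score(ref, pred))
            assert m.AUC == pytest.approx((m.SEN + m.SPE) / 2.0)


class TestAggregation:
    def test_identical_runs_have_zero_iqr(self):
        m = compute_metrics(ConfusionCounts(13, 25, 1, 7))
        agg = aggregate_runs([m] * 10)
        assert (agg["iqr"] == 0.0).all()
        assert agg.loc["SPE", "median"] == pytest.approx(0.9615, abs=5e-5)

    def test_hand_sorted_median_and_iqr(self):
        sets = [
            compute_metrics(ConfusionCounts(tp, 25, 1, 20 - tp))
            for tp in (10, 11, 13, 14, 15)
        ]
        agg = aggregate_runs(sets)
        accs = np.sort([m.ACC for m in sets])
        assert agg.loc["ACC", "median"] == pytest.approx(accs[2])
        # type-7 quartiles by direct interpolation
        q1 = accs[1]
        q3 = accs[3]
        assert agg.loc["ACC", "iqr"] == pytest.approx(q3 - q1)

    def test_aggregation_invariant_to_run_order(self):
        sets = [
            compute_metrics(ConfusionCounts(tp, 25, 1, 20 - tp))
            for tp in (10, 15, 12, 13)
        ]
        a = aggregate_runs(sets)
        b = aggregate_runs(sets[::-1])
        assert np.allclose(a["median"], b["median"])
        assert np.allclose(a["iqr"], b["iqr"])


class TestDecisionCurve:
    CLINICAL = ConfusionCounts(15, 25, 1, 5)

    def test_net_benefit_at_zero_threshold_is_tp_rate(self):
        assert net_benefit(self.CLINICAL, 0.0) == pytest.approx(15 / 46)

    def test_net_benefit_at_half_threshold(self):
        assert net_benefit(self.CLINICAL, 0.5) == pytest.approx(14 / 46)

    def test_no_false_positives_gives_flat_curve(self):
        curve = decision_curve(ConfusionCounts(10, 30, 0, 6))
        assert np.allclose(curve["net_benefit"], 10 / 46)

    def test_curve_strictly_decreasing_when_fp_positive(self):
        curve = decision_curve(self.CLINICAL)
        assert (np.diff(curve["net_benefit"]) < 0).all()

    def test_negative_values_retained_internally(self):
        curve = decision_curve(ConfusionCounts(1, 10, 9, 3), grid=[0.0, 0.9])
        assert curve["net_benefit"].iloc[1] < 0

    def test_unit_threshold_excluded(self):
        with pytest.raises(ValueError):
            decision_curve(self.CLINICAL, grid=[0.5, 1.0])


class TestKappa:
    def test_identical_mixed_vectors_reach_unity(self):
        a = [1, 0, 1, 0, 0]
        assert cohen_kappa(a, a).kappa == pytest.approx(1.0)

    def test_hand_computed_agreement_table(self):
        # table [[10, 2], [3, 31]]: p_o = 41/46, p_e from marginal products
        a = [1] * 12 + [0] * 34
        b = [1] * 10 + [0] * 2 + [1] * 3 + [0] * 31
        res = cohen_kappa(a, b)
        p_o = 41 / 46
        p_e = (12 * 13 + 34 * 33) / 46**2
        assert res.observed_agreement == pytest.approx(p_o)
        assert res.expected_agreement == pytest.approx(p_e)
        assert res.kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_both_raters_constant_is_undefined(self):
        res = cohen_kappa([1, 1, 1], [1, 1, 1])
        assert np.isnan(res.kappa)
        assert "undefined" in res.context

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(pairs=label_vectors)
    def test_symmetry_flip_invariance_and_sklearn_agreement(self, pairs):
        a = np.array([p for p, _ in pairs])
        b = np.array([r for _, r in pairs])
        res = cohen_kappa(a, b)
        assert isinstance(res, AgreementResult)
        sym = cohen_kappa(b, a)
        flip = cohen_kappa(1 - a, 1 - b)
        if np.isnan(res.kappa):
            assert np.isnan(sym.kappa) and np.isnan(flip.kappa)
        else:
            assert sym.kappa == pytest.approx(res.kappa)
            assert flip.kappa == pytest.approx(res.kappa)
            if len(np.unique(a)) == 2 and len(np.unique(b)) == 2:
                assert res.kappa == pytest.approx(cohen_kappa_score(a, b))
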