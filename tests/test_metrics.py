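"""Unit and property tests for the confusion-matrix indicators and their CIs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxeval import (
    AnalysisConfig,
    ConfusionMatrix,
    accuracy,
    build_confusion_matrix,
    evaluate_all,
    likelihood_ratios,
    predictive_values,
    sensitivity,
    specificity,
    wilson_interval,
    youden,
)
from conftest import random_confusion_matrix


class TestConfusionMatrix:
    def test_margins_and_total(self, example_cm):
        assert example_cm.n_diseased == 72
        assert example_cm.n_nondiseased == 41
        assert example_cm.total == 113

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=2)

    @pytest.mark.parametrize(
        "test,ref,expected",
        [
            ([1, 1, 0, 0], [1, 0, 1, 0], (1, 1, 1, 1)),
            ([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], [1, 1, 1, 1, 0, 0, 0, 0, 0, 0], (4, 0, 0, 6)),
        ],
    )
    def test_build_from_vectors(self, test, ref, expected):
        cm = build_confusion_matrix(test, ref)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == expected

    def test_build_counts_sum_to_length(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 2, 57)
        r = rng.integers(0, 2, 57)
        # guard: both classes not required for the raw cross-tabulation
        assert build_confusion_matrix(t, r).total == 57

    def test_build_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            build_confusion_matrix([1, 0], [1, 0, 1])


class TestWilsonInterval:
    def test_hand_computed_values(self):
        lo, hi = wilson_interval(58, 72)
        assert lo == pytest.approx(0.6996702472161007, abs=1e-12)
        assert hi == pytest.approx(0.8804862895658236, abs=1e-12)
        lo, hi = wilson_interval(26, 41)
        assert lo == pytest.approx(0.4812042325216125, abs=1e-12)
        assert hi == pytest.approx(0.7641036958306319, abs=1e-12)

    def test_boundary_collapse_is_exact(self):
        assert wilson_interval(0, 10)[0] == 0.0
        assert wilson_interval(10, 10)[1] == 1.0

    def test_zero_denominator_is_missing(self):
        assert wilson_interval(0, 0) == (None, None)

    @given(
        n=st.integers(min_value=1, max_value=10_000),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_contains_proportion_and_stays_in_unit_interval(self, n, frac):
        successes = int(round(frac * n))
        lo, hi = wilson_interval(successes, n)
        p = successes / n
        assert 0.0 <= lo <= p <= hi <= 1.0

    def test_agrees_with_statsmodels_wilson(self):
        # independent implementation; tiny slack for its qnorm-based z
        from statsmodels.stats.proportion import proportion_confint

        for successes, n in [(58, 72), (26, 41), (1, 5), (199, 200), (7, 1000)]:
            lo, hi = wilson_interval(successes, n)
            ref_lo, ref_hi = proportion_confint(successes, n, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-4)
            assert hi == pytest.approx(ref_hi, abs=1e-4)

    def test_approaches_wald_for_large_n(self):
        successes, n = 300_000, 1_000_000
        p = successes / n
        half = 1.96 * math.sqrt(p * (1 - p) / n)
        lo, hi = wilson_interval(successes, n)
        assert lo == pytest.approx(p - half, abs=1e-5)
        assert hi == pytest.approx(p + half, abs=1e-5)


class TestProportionMetrics:
    def test_worked_example_values(self, example_cm, cfg):
        assert sensitivity(example_cm, cfg).value == pytest.approx(58 / 72)
        assert specificity(example_cm, cfg).value == pytest.approx(26 / 41)
        assert accuracy(example_cm, cfg).value == pytest.approx(84 / 113)

    @pytest.mark.parametrize(
        "metric,cm,expected",
        [
            (sensitivity, ConfusionMatrix(10, 0, 0, 10), 1.0),
            (specificity, ConfusionMatrix(10, 0, 0, 10), 1.0),
            (accuracy, ConfusionMatrix(10, 0, 0, 10), 1.0),
            (accuracy, ConfusionMatrix(0, 10, 10, 0), 0.0),
            (sensitivity, ConfusionMatrix(0, 5, 0, 5), None),
            (specificity, ConfusionMatrix(5, 0, 5, 0), None),
        ],
    )
    def test_extreme_and_missing_cases(self, metric, cm, expected, cfg):
        est = metric(cm, cfg)
        if expected is None:
            assert est.value is None and est.lower is None and est.upper is None
        else:
            assert est.value == expected


class TestPredictiveValues:
    def test_worked_example_bayes_values(self, example_cm, cfg):
        se = sensitivity(example_cm, cfg)
        sp = specificity(example_cm, cfg)
        ppv, npv = predictive_values(se, sp, cfg)
        assert ppv.value == pytest.approx(0.19656141510993555, abs=1e-12)
        assert ppv.lower == pytest.approx(0.13032075264763937, abs=1e-12)
        assert ppv.upper == pytest.approx(0.29314824197355527, abs=1e-12)
        assert npv.value == pytest.approx(0.9670531511881528, abs=1e-12)
        assert npv.lower == pytest.approx(0.9351503200046781, abs=1e-12)
        assert npv.upper == pytest.approx(0.9829179423646129, abs=1e-12)

    def test_perfect_test(self, cfg):
        cm = ConfusionMatrix(10, 0, 0, 10)
        ppv, npv = predictive_values(sensitivity(cm, cfg), specificity(cm, cfg), cfg)
        assert ppv.value == 1.0
        assert npv.value == 1.0

    def test_missing_inputs_propagate(self, cfg):
        cm = ConfusionMatrix(0, 5, 0, 5)  # no diseased -> Se missing
        ppv, npv = predictive_values(sensitivity(cm, cfg), specificity(cm, cfg), cfg)
        assert ppv.value is None and ppv.lower is None
        assert npv.value is None and npv.upper is None

    def test_monotone_attainment_and_point_inside_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cm = random_confusion_matrix(rng)
            cfg = AnalysisConfig(prevalence=float(rng.uniform(0.01, 0.99)))
            se = sensitivity(cm, cfg)
            sp = specificity(cm, cfg)
            ppv, npv = predictive_values(se, sp, cfg)
            pr = cfg.prevalence

            def bayes_ppv(a, b):
                den = a * pr + (1 - b) * (1 - pr)
                return a * pr / den if den else None

            def bayes_npv(a, b):
                den = b * (1 - pr) + (1 - a) * pr
                return b * (1 - pr) / den if den else None

            # monotone in both arguments: extremes attained at (lo,lo)/(hi,hi)
            lo_val = bayes_ppv(se.lower, sp.lower)
            hi_val = bayes_ppv(se.upper, sp.upper)
            if ppv.value is not None and lo_val is not None and hi_val is not None:
                assert ppv.lower == pytest.approx(lo_val, abs=1e-12)
                assert ppv.upper == pytest.approx(hi_val, abs=1e-12)
                assert ppv.lower - 1e-12 <= ppv.value <= ppv.upper + 1e-12
            lo_val = bayes_npv(se.lower, sp.lower)
            hi_val = bayes_npv(se.upper, sp.upper)
            if npv.value is not None and lo_val is not None and hi_val is not None:
                assert npv.lower == pytest.approx(lo_val, abs=1e-12)
                assert npv.upper == pytest.approx(hi_val, abs=1e-12)
                assert npv.lower - 1e-12 <= npv.value <= npv.upper + 1e-12

    def test_sample_prevalence_identity(self):
        # at pr = n_d/N, Bayes PPV collapses to TP/(TP+FP) and NPV to TN/(TN+FN)
        rng = np.random.default_rng(11)
        for _ in range(200):
            cm = random_confusion_matrix(rng)
            if cm.tp + cm.fp == 0 or cm.tn + cm.fn == 0:
                continue
            pr = cm.n_diseased / cm.total
            if not 0 < pr < 1:
                continue
            cfg = AnalysisConfig(prevalence=pr)
            ppv, npv = predictive_values(
                sensitivity(cm, cfg), specificity(cm, cfg), cfg
            )
            assert ppv.value == pytest.approx(cm.tp / (cm.tp + cm.fp), abs=1e-12)
            assert npv.value == pytest.approx(cm.tn / (cm.tn + cm.fn), abs=1e-12)


class TestLikelihoodRatios:
    def test_worked_example_simel_intervals(self, example_cm, cfg):
        lr_pos, lr_neg = likelihood_ratios(example_cm, cfg)
        assert lr_pos.value == pytest.approx(2.201851851851852, abs=1e-12)
        assert lr_pos.lower == pytest.approx(1.4486391814965036, abs=1e-10)
        assert lr_pos.upper == pytest.approx(3.3466936690854183, abs=1e-10)
        assert lr_neg.value == pytest.approx(0.3066239316239316, abs=1e-12)
        assert lr_neg.lower == pytest.approx(0.18147566381399055, abs=1e-10)
        assert lr_neg.upper == pytest.approx(0.5180762724245195, abs=1e-10)

    def test_perfect_test_missing_rules(self, cfg):
        lr_pos, lr_neg = likelihood_ratios(ConfusionMatrix(10, 0, 0, 10), cfg)
        assert lr_pos.value is None  # 1 - Sp = 0
        assert lr_neg.value == 0.0  # point defined, but 1/FN undefined
        assert lr_neg.lower is None and lr_neg.upper is None

    def test_interval_contains_point_when_all_cells_positive(self):
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(300):
            cm = random_confusion_matrix(rng)
            if min(cm.tp, cm.fp, cm.fn, cm.tn) == 0:
                continue
            lr_pos, lr_neg = likelihood_ratios(cm, AnalysisConfig(prevalence=0.2))
            assert lr_pos.lower <= lr_pos.value <= lr_pos.upper
            assert lr_neg.lower <= lr_neg.value <= lr_neg.upper
            checked += 1
        assert checked > 100


class TestYouden:
    def test_worked_example(self, example_cm, cfg):
        j = youden(example_cm, cfg)
        assert j.value == pytest.approx(0.4397018970189701, abs=1e-12)
        assert j.lower == pytest.approx(0.2662208596678821, abs=1e-10)
        assert j.upper == pytest.approx(0.6131829343700581, abs=1e-10)

    def test_perfect_test_has_degenerate_interval(self, cfg):
        j = youden(ConfusionMatrix(10, 0, 0, 10), cfg)
        assert j.value == 1.0 and j.lower == 1.0 and j.upper == 1.0

    def test_random_classifier_is_zero(self, cfg):
        assert youden(ConfusionMatrix(5, 5, 5, 5), cfg).value == pytest.approx(0.0)

    def test_missing_on_empty_margin(self, cfg):
        assert youden(ConfusionMatrix(0, 5, 0, 5), cfg).value is None


class TestEvaluateAll:
    def test_composition_matches_worked_example(self, example_cm, cfg):
        report = evaluate_all(example_cm, cfg)
        assert [e.label for e in report] == [
            "Sensitivity",
            "Specificity",
            "Accuracy",
            "PPV",
            "NPV",
            "LR+",
            "LR-",
            "Youden index",
        ]
        assert report["Sensitivity"].value == pytest.approx(58 / 72)
        assert report["PPV"].value == pytest.approx(0.19656141510993555)
        assert report["LR+"].value == pytest.approx(2.201851851851852)

    def test_perfect_test(self, cfg):
        report = evaluate_all(ConfusionMatrix(10, 0, 0, 10), cfg)
        for label in ("Sensitivity", "Specificity", "Accuracy", "PPV", "NPV", "Youden index"):
            assert report[label].value == 1.0
        assert report["LR+"].value is None
        assert report["LR-"].value == 0.0

    def test_partial_missing_propagation(self, cfg):
        report = evaluate_all(ConfusionMatrix(0, 5, 0, 5), cfg)
        assert report["Specificity"].value == pytest.approx(0.5)
        for label in ("Sensitivity", "PPV", "NPV", "LR+", "LR-", "Youden index"):
            assert report[label].value is None

    def test_prevalence_bounds_enforced(self):
        with pytest.raises(ValueError):
            AnalysisConfig(prevalence=0.0)
        with pytest.raises(ValueError):
            AnalysisConfig(prevalence=1.0)
        with pytest.raises(ValueError):
            AnalysisConfig(prevalence=1.5)
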