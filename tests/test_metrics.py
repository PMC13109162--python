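"""Confusion counts, burden arithmetic, discrimination curves and the
resampling machinery, checked against brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest

from ewsval.metrics import (ConfusionCounts, ResamplingConfig,
                            alarms_per_additional_event, auroc,
                            burden_metrics, check_burden_identities,
                            clustered_bootstrap_ci, confusion_counts,
                            expected_event_count, paired_permutation_test,
                            pr_auc, pr_curve, roc_curve, threshold_metrics,
                            ward_rate)
from ewsval.scoring import TriggerRule
from helpers_oracles import brute_force_auroc

RULE5 = TriggerRule(">=5", "gews", 5, False)


class TestConfusionCounts:
    def test_small_enumeration(self):
        labels = np.array(["event", "event", "non_event", "non_event"])
        total = np.array([6, 3, 1, 5])
        mx = np.array([2, 1, 0, 2])
        c = confusion_counts(labels, total, mx, RULE5)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_all_non_event_no_alerts(self):
        labels = np.array(["non_event"] * 5)
        c = confusion_counts(labels, np.zeros(5), np.zeros(5), RULE5)
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 0, 0, 5)

    def test_threshold_one_degenerate(self):
        labels = np.array(["event", "non_event"])
        c = confusion_counts(labels, np.array([9, 9]), np.array([3, 3]),
                             TriggerRule(">=1", "gews", 1, False))
        assert (c.tn, c.fn) == (0, 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array([]), np.array([]), np.array([]), RULE5)

    def test_neutralized_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array(["neutralized"]), np.array([0]),
                             np.array([0]), RULE5)


class TestThresholdAndBurden:
    @pytest.mark.parametrize("alerts,tp,expected_nne", [
        (459, 228, 2.013),  # GEWS >= 5 column reconstruction
        (523, 191, 2.738),  # NEWS >= 5 column reconstruction
        (10, 10, 1.0),      # perfect precision
    ])
    def test_nne_from_alerts_and_true_positives(self, alerts, tp, expected_nne):
        c = ConfusionCounts(tp=tp, fp=alerts - tp, tn=0, fn=0)
        assert round(threshold_metrics(c)["nne"], 3) == expected_nne

    def test_nne_undefined_when_no_true_positives(self):
        c = ConfusionCounts(tp=0, fp=5, tn=5, fn=0)
        assert np.isnan(threshold_metrics(c)["nne"])

    def test_burden_rates_per_100_patient_days(self):
        c = ConfusionCounts(tp=228, fp=523 - 228, tn=0, fn=0)
        m = burden_metrics(c, 5154.0)
        assert round(m["roa"], 3) == 10.147
        assert round(m["aoer"], 3) == 4.424

    def test_zero_alerts_zero_rates(self):
        m = burden_metrics(ConfusionCounts(0, 0, 10, 0), 100.0)
        assert m["roa"] == 0 and m["aoer"] == 0

    def test_non_positive_patient_days_rejected(self):
        with pytest.raises(ValueError):
            burden_metrics(ConfusionCounts(1, 1, 1, 1), 0.0)

    def test_identities_hold_on_random_counts(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            m = threshold_metrics(c) | burden_metrics(c, 1000.0)
            check_burden_identities(m)

    def test_ward_rate_conversion(self):
        # 8.906 alerts/100 patient-days on a 24-bed ward over 24 h
        assert ward_rate(8.906, beds=24) == pytest.approx(2.137, abs=5e-4)

    def test_alarm_cost_of_threshold_change(self):
        alarms, fps = alarms_per_additional_event(1.463, 0.102)
        assert (alarms, fps) == (14, 13)


class TestDiscrimination:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3], ["non_event", "non_event", "event"]) == 1.0
        assert pr_auc([1, 2, 3], ["non_event", "non_event", "event"]) == 1.0

    def test_ties_only_gives_half(self):
        assert auroc([2, 2, 2, 2], ["event", "non_event", "event", "non_event"]) == 0.5

    def test_hand_computed_pairwise_case(self):
        scores = [3, 1, 2, 2]
        labels = ["event", "non_event", "non_event", "event"]
        assert auroc(scores, labels) == pytest.approx(0.875)
        assert pr_auc(scores, labels) == pytest.approx(5 / 6, abs=5e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 2], ["event", "event"])
        with pytest.raises(ValueError):
            pr_auc([1, 2], ["non_event", "non_event"])

    def test_all_equal_scores_pr_auc_equals_prevalence(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            y = rng.random(n) < rng.uniform(0.1, 0.9)
            if not y.any():
                continue
            assert pr_auc(np.full(n, 4.0), y) == pytest.approx(y.mean())

    def test_auroc_equals_brute_force_concordance(self, rng):
        """Oracle equivalence on 100 random datasets of <= 200 sets."""
        for _ in range(100):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 12, n).astype(float)
            y = rng.random(n) < 0.3
            if y.all() or not y.any():
                continue
            assert auroc(scores, y) == pytest.approx(
                brute_force_auroc(scores, y), abs=1e-12)

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        for _ in range(20):
            n = int(rng.integers(20, 300))
            scores = rng.integers(0, 15, n).astype(float)
            y = rng.random(n) < 0.25
            if y.all() or not y.any():
                continue
            assert auroc(scores, y) == pytest.approx(roc_auc_score(y, scores))
            assert pr_auc(scores, y) == pytest.approx(
                average_precision_score(y, scores))

    def test_roc_curve_trapezoid_equals_rank_auroc(self, rng):
        scores = rng.integers(0, 10, 150).astype(float)
        y = rng.random(150) < 0.3
        pts = roc_curve(scores, y)
        area = np.trapezoid(pts["tpr"], pts["fpr"])
        assert area == pytest.approx(auroc(scores, y))

    def test_raising_threshold_never_raises_sensitivity(self, rng):
        labels = np.where(rng.random(300) < 0.2, "event", "non_event")
        total = rng.integers(0, 15, 300)
        mx = rng.integers(0, 4, 300)
        prev_sens, prev_spec = 1.1, -0.1
        for thr in range(1, 15):
            c = confusion_counts(labels, total, mx,
                                 TriggerRule("t", "gews", thr, False))
            m = threshold_metrics(c)
            assert m["sensitivity"] <= prev_sens + 1e-12
            assert m["specificity"] >= prev_spec - 1e-12
            prev_sens, prev_spec = m["sensitivity"], m["specificity"]


class TestClusteredBootstrap:
    def test_constant_metric_zero_width_ci(self):
        clusters = np.repeat(np.arange(30), 4)
        lo, hi = clustered_bootstrap_ci(
            lambda idx: 0.7, clusters,
            ResamplingConfig(bootstrap_samples=200, permutations=1, seed=1))
        assert lo == hi == 0.7

    def test_fixed_seed_reproducible(self, rng):
        vals = rng.normal(size=120)
        clusters = np.repeat(np.arange(30), 4)
        cfg = ResamplingConfig(bootstrap_samples=300, permutations=1, seed=9)
        ci1 = clustered_bootstrap_ci(lambda i: vals[i].mean(), clusters, cfg)
        ci2 = clustered_bootstrap_ci(lambda i: vals[i].mean(), clusters, cfg)
        assert ci1 == ci2

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            clustered_bootstrap_ci(lambda i: 0.0, np.zeros(10))

    def test_mostly_undefined_statistic_reported_as_failure(self):
        clusters = np.repeat(np.arange(10), 2)
        with pytest.raises(ValueError, match="undefined"):
            clustered_bootstrap_ci(
                lambda i: float("nan"), clusters,
                ResamplingConfig(bootstrap_samples=50, permutations=1, seed=0))


class TestPairedPermutation:
    def test_identical_scores_give_p_one(self, rng):
        z = rng.normal(size=80)
        y = rng.random(80) < 0.4
        clusters = np.repeat(np.arange(20), 4)
        stat = lambda s: auroc(s, y)
        delta, p = paired_permutation_test(
            stat, stat, z, z.copy(), clusters,
            ResamplingConfig(bootstrap_samples=1, permutations=199, seed=3))
        assert delta == 0.0 and p == 1.0

    def test_fixed_seed_reproducible(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        y = rng.random(60) < 0.4
        clusters = np.repeat(np.arange(15), 4)
        stat = lambda s: auroc(s, y)
        cfg = ResamplingConfig(bootstrap_samples=1, permutations=199, seed=4)
        r1 = paired_permutation_test(stat, stat, a, b, clusters, cfg)
        r2 = paired_permutation_test(stat, stat, a, b, clusters, cfg)
        assert r1 == r2

    def test_p_value_never_zero(self, rng):
        a = rng.normal(size=40) + 3.0
        b = rng.normal(size=40)
        y = np.concatenate([np.ones(20, bool), np.zeros(20, bool)])
        clusters = np.arange(40)
        stat = lambda s: auroc(s, y)
        _, p = paired_permutation_test(
            stat, stat, a, b, clusters,
            ResamplingConfig(bootstrap_samples=1, permutations=99, seed=5))
        assert p >= 1 / 100

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_permutation_test(lambda s: 0.0, lambda s: 0.0,
                                    np.zeros(4), np.zeros(5), np.zeros(4))


class TestSampleSizeArithmetic:
    def test_planning_case(self):
        assert expected_event_count(500, 10, 0.005) == pytest.approx(25.0)

    def test_zero_patients(self):
        assert expected_event_count(0, 10, 0.005) == 0

    def test_mortality_rate_arithmetic(self):
        assert expected_event_count(541, 10, 0.0077) == pytest.approx(41.657)
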