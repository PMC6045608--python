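"""ROC/AUROC, Youden cut-offs, confusion metrics and confidence intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hepamir.diagnostics import (
    build_ratio_features,
    confusion_metrics,
    empirical_roc,
    evaluate_marker,
    metric_confidence_intervals,
    predictive_values,
    youden_optimal_cutoff,
)


class TestRatioFeatures:
    def test_self_ratio_is_one(self):
        lv = pd.DataFrame({"a": [0.5, 2.0, 3.0]}, index=list("xyz"))
        out = build_ratio_features(lv, ["a"], ["a"])
        assert np.allclose(out["a/a"], 1.0)

    def test_default_pair_count_and_names(self, nafld_levels):
        _, _, levels = nafld_levels
        out = build_ratio_features(levels)
        assert out.shape[1] == 18
        for name in ("miR-34a/197", "miR-192/197", "miR-192/30c",
                     "miR-27b/30c", "miR-27b/197"):
            assert name in out.columns

    def test_missing_assay_errors(self):
        lv = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="nope"):
            build_ratio_features(lv, ["a"], ["nope"])


class TestEmpiricalRoc:
    def test_perfect_separation(self):
        roc = empirical_roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auroc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        roc = empirical_roc([5.0] * 8, [0, 1] * 4)
        assert roc.auroc == pytest.approx(0.5)

    def test_small_worked_example(self):
        # positives {2, 3}, negatives {1, 2.5}: 3 of 4 pairs concordant
        roc = empirical_roc([2, 3, 1, 2.5], [1, 1, 0, 0])
        assert roc.auroc == pytest.approx(0.75)
        assert roc.direction == "higher_is_positive"

    def test_auto_direction_flip(self):
        roc = empirical_roc([10, 9, 1, 2], [0, 0, 1, 1])
        assert roc.direction == "lower_is_positive"
        assert roc.auroc == pytest.approx(1.0)

    def test_trapezoid_equals_mann_whitney(self, rng):
        """Trapezoidal area == U/(n1 n0) with ties half, on tied random data."""
        for _ in range(50):
            n = int(rng.integers(4, 12))
            scores = rng.integers(0, 4, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            roc = empirical_roc(scores, labels, direction="higher_is_positive")
            pos, neg = scores[labels], scores[~labels]
            u = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            assert roc.auroc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            empirical_roc([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_perfect_marker(self):
        roc = empirical_roc([1, 2, 8, 9], [0, 0, 1, 1])
        opt = youden_optimal_cutoff(roc)
        assert opt.j == pytest.approx(1.0)
        assert opt.sensitivity == 1.0 and opt.specificity == 1.0

    def test_tie_resolved_to_higher_sensitivity(self):
        roc = empirical_roc([2, 3, 1, 2.5], [1, 1, 0, 0])
        opt = youden_optimal_cutoff(roc)
        assert opt.j == pytest.approx(0.5)
        assert opt.cutoff == pytest.approx(2.0)     # sens 1.0 / spec 0.5 wins
        assert opt.sensitivity == pytest.approx(1.0)
        assert opt.specificity == pytest.approx(0.5)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 15))
            scores = np.round(rng.normal(0, 1, n), 1)
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            roc = empirical_roc(scores, labels, direction="higher_is_positive")
            opt = youden_optimal_cutoff(roc)
            best_j = max(
                ((scores >= t) & labels).sum() / labels.sum()
                + (~(scores >= t) & ~labels).sum() / (~labels).sum() - 1.0
                for t in np.unique(scores))
            assert opt.j == pytest.approx(best_j, abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = confusion_metrics(10, 0, 0, 10)
        assert rep.sensitivity == rep.specificity == rep.ppv == rep.npv == 1.0
        assert rep.accuracy == 1.0
        assert rep.nlr == 0.0
        assert np.isinf(rep.plr)

    @pytest.mark.parametrize(
        "tp, fn, tn, fp, nlr_2dp",
        [(73, 27, 83, 17, 0.33),    # sens 0.73 / spec 0.83
         (87, 13, 69, 31, 0.19)],   # sens 0.87 / spec 0.69
    )
    def test_nlr_rounding(self, tp, fn, tn, fp, nlr_2dp):
        rep = confusion_metrics(tp, fp, fn, tn)
        assert round(rep.nlr, 2) == nlr_2dp

    def test_degenerate_cells_flagged_not_raised(self):
        rep = confusion_metrics(0, 0, 5, 5)
        assert np.isnan(rep.ppv)
        assert "ppv_undefined" in rep.flags

    def test_bayes_consistency(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 40, 4)
            rep = confusion_metrics(tp, fp, fn, tn)
            n = tp + fp + fn + tn
            p = (tp + fn) / n
            assert rep.accuracy == pytest.approx(
                rep.sensitivity * p + rep.specificity * (1 - p), abs=1e-12)
            denom = rep.sensitivity * p + (1 - rep.specificity) * (1 - p)
            assert rep.ppv == pytest.approx(rep.sensitivity * p / denom, abs=1e-12)


class TestPredictiveValues:
    def test_matches_count_based_metrics(self):
        rep = confusion_metrics(30, 10, 20, 40)
        rates = predictive_values(rep.sensitivity, rep.specificity, prevalence=0.5)
        assert rates["ppv"] == pytest.approx(rep.ppv)
        assert rates["npv"] == pytest.approx(rep.npv)
        assert rates["nlr"] == pytest.approx(rep.nlr)
        assert rates["plr"] == pytest.approx(rep.plr)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            predictive_values(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            predictive_values(0.5, 0.5, 0.0)


class TestConfidenceIntervals:
    def test_boundary_sensitivity_interval(self):
        rep = metric_confidence_intervals(confusion_metrics(10, 5, 0, 5))
        lo, hi = rep.ci["sensitivity"]
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-10)  # exact Beta quantile

    def test_interval_width_shrinks_with_n(self):
        narrow = metric_confidence_intervals(confusion_metrics(200, 0, 200, 400))
        wide = metric_confidence_intervals(confusion_metrics(50, 0, 50, 100))
        w_n = np.diff(narrow.ci["sensitivity"])[0]
        w_w = np.diff(wide.ci["sensitivity"])[0]
        assert w_w / w_n == pytest.approx(2.0, abs=0.3)

    def test_sensitivity_ci_coverage(self):
        """Clopper-Pearson coverage at n=50, true sensitivity 0.8."""
        rng = np.random.default_rng(0)
        n, true = 50, 0.8
        k = rng.binomial(n, true, size=2000)
        alpha = 0.05
        lo = np.where(k == 0, 0.0, sps.beta.ppf(alpha / 2, k, n - k + 1))
        hi = np.where(k == n, 1.0, sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
        coverage = np.mean((lo <= true) & (true <= hi))
        assert coverage >= 0.93

    def test_lr_intervals_contain_estimate(self):
        rep = metric_confidence_intervals(confusion_metrics(40, 12, 10, 30))
        assert rep.ci["plr"][0] < rep.plr < rep.ci["plr"][1]
        assert rep.ci["nlr"][0] < rep.nlr < rep.ci["nlr"][1]


class TestEvaluateMarker:
    def test_perfect_marker(self):
        roc, rep = evaluate_marker([1, 2, 8, 9, 10], [0, 0, 1, 1, 1])
        assert roc.auroc == 1.0
        assert rep.accuracy == 1.0

    def test_worked_report(self):
        roc, rep = evaluate_marker([2, 3, 1, 2.5], [1, 1, 0, 0])
        assert roc.auroc == pytest.approx(0.75)
        assert rep.cutoff == pytest.approx(2.0)
        assert rep.counts == (2, 1, 0, 1)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.5

    def test_direction_invariance(self):
        scores = [0.3, 1.2, 0.8, 2.5, 1.9, 0.1, 3.0, 2.2]
        labels = [0, 0, 0, 1, 1, 0, 1, 1]
        roc_a, rep_a = evaluate_marker(scores, labels)
        roc_b, rep_b = evaluate_marker([-s for s in scores], labels)
        assert roc_b.auroc == pytest.approx(roc_a.auroc, abs=1e-12)
        assert rep_b.counts == rep_a.counts
        assert rep_b.cutoff == pytest.approx(-rep_a.cutoff)
        assert roc_b.direction == "lower_is_positive"

    def test_binormal_closed_form(self):
        """Mean empirical AUROC tracks Phi(delta/sqrt(2)) for a normal marker."""
        rng = np.random.default_rng(1)
        delta = 1.0
        aurocs = []
        for _ in range(200):
            neg = rng.normal(0, 1, 40)
            pos = rng.normal(delta, 1, 40)
            roc, _ = evaluate_marker(np.r_[neg, pos], np.r_[np.zeros(40), np.ones(40)])
            aurocs.append(roc.auroc)
        expected = sps.norm.cdf(delta / np.sqrt(2))
        assert np.mean(aurocs) == pytest.approx(expected, abs=0.02)
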