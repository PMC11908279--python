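"""Discrimination metrics against brute-force and permutation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

import ecgkit as ek
from ecgkit.metrics import _balanced_accuracy_curve


def auroc_bruteforce(labels, scores):
    """Pair-counting AUROC: ties get half credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def random_predset(rng, n, informative=True):
    y = (rng.random(n) < 0.5).astype(int)
    if not y.min() == 0 or not y.max() == 1:
        y[0], y[1] = 0, 1
    s = np.clip(rng.random(n) * 0.6 + y * 0.3 * informative, 0, 1)
    return y, s


class TestAuroc:
    def test_perfect_separation(self):
        assert ek.auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_known_small_example(self):
        # positives 0.9, 0.7 vs negatives 0.8, 0.1: 3 of 4 pairs won
        assert ek.auroc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = (rng.random(20000) < 0.5).astype(int)
        s = rng.random(20000)
        assert ek.auroc(y, s) == pytest.approx(0.5, abs=0.02)

    def test_ties_get_half_credit(self):
        assert ek.auroc([1, 0], [0.5, 0.5]) == 0.5

    def test_single_class_rejected_with_class_named(self):
        with pytest.raises(ValueError, match="class 1"):
            ek.auroc([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_bruteforce_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 500))
        y, s = random_predset(rng, n)
        s = np.round(s, 2)  # force ties
        assert ek.auroc(y, s) == pytest.approx(auroc_bruteforce(y, s), abs=1e-12)


class TestAuprc:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_average_precision(self, seed):
        rng = np.random.default_rng(seed)
        y, s = random_predset(rng, 300)
        s = np.round(s, 2)
        assert ek.auprc(y, s) == pytest.approx(
            average_precision_score(y, s), abs=1e-10
        )

    def test_perfect_separation(self):
        assert ek.auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0


class TestOverallAuroc:
    def test_single_label_reduces_to_plain_auroc(self):
        rng = np.random.default_rng(1)
        y, s = random_predset(rng, 200)
        ps = ek.PredictionSet(scores=s[:, None], labels=y[:, None])
        assert ek.overall_auroc(ps) == ek.auroc(y, s)

    def test_mixture_lies_between_per_label_values(self):
        rng = np.random.default_rng(2)
        n = 2000
        y1, s1 = random_predset(rng, n)               # informative
        y2, s2 = random_predset(rng, n, informative=False)  # random
        ps = ek.PredictionSet(
            scores=np.column_stack([s1, s2]), labels=np.column_stack([y1, y2])
        )
        a1, a2 = ek.auroc(y1, s1), ek.auroc(y2, s2)
        assert min(a1, a2) < ek.overall_auroc(ps) < max(a1, a2)

    def test_invariant_to_label_column_order(self):
        rng = np.random.default_rng(3)
        y1, s1 = random_predset(rng, 100)
        y2, s2 = random_predset(rng, 100)
        ps = ek.PredictionSet(
            scores=np.column_stack([s1, s2]), labels=np.column_stack([y1, y2])
        )
        ps_rev = ek.PredictionSet(
            scores=np.column_stack([s2, s1]), labels=np.column_stack([y2, y1])
        )
        assert ek.overall_auroc(ps) == ek.overall_auroc(ps_rev)

    def test_all_degenerate_rejected(self):
        ps = ek.PredictionSet(
            scores=np.array([[0.2], [0.4]]), labels=np.array([[0], [0]])
        )
        with pytest.raises(ValueError):
            ek.overall_auroc(ps)


class TestBootstrapMetric:
    def test_constant_metric_zero_width_ci(self):
        rng = np.random.default_rng(4)
        y, s = random_predset(rng, 100)
        ps = ek.PredictionSet(scores=s[:, None], labels=y[:, None])
        est = ek.bootstrap_metric(ps, lambda p: 0.7, iterations=50, seed=0)
        assert est.ci_low == est.ci_high == est.point == 0.7

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        y, s = random_predset(rng, 300)
        ps = ek.PredictionSet(scores=s[:, None], labels=y[:, None])
        metric = lambda p: ek.auroc(p.labels[:, 0], p.scores[:, 0])
        a = ek.bootstrap_metric(ps, metric, iterations=100, seed=3)
        b = ek.bootstrap_metric(ps, metric, iterations=100, seed=3)
        assert (a.point, a.ci_low, a.ci_high) == (b.point, b.ci_low, b.ci_high)

    def test_point_inside_ci(self):
        rng = np.random.default_rng(6)
        y, s = random_predset(rng, 500)
        ps = ek.PredictionSet(scores=s[:, None], labels=y[:, None])
        metric = lambda p: ek.auroc(p.labels[:, 0], p.scores[:, 0])
        est = ek.bootstrap_metric(ps, metric, iterations=200, seed=1)
        assert est.ci_low <= est.point <= est.ci_high

    @pytest.mark.parametrize("seed", range(3))
    def test_ci_narrows_with_sample_size(self, seed):
        metric = lambda p: ek.auroc(p.labels[:, 0], p.scores[:, 0])
        widths = {}
        for n in (500, 5000):
            rng = np.random.default_rng(seed)
            y, s = random_predset(rng, n)
            ps = ek.PredictionSet(scores=s[:, None], labels=y[:, None])
            est = ek.bootstrap_metric(ps, metric, iterations=200, seed=seed)
            widths[n] = est.ci_high - est.ci_low
        assert widths[5000] < widths[500]

    def test_bad_fraction_rejected(self):
        ps = ek.PredictionSet(scores=np.array([[0.5]]), labels=np.array([[1]]))
        with pytest.raises(ValueError):
            ek.bootstrap_metric(ps, lambda p: 0.0, fraction=1.5)


class TestDelong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(7)
        y, s = random_predset(rng, 100)
        a_auc, b_auc, p = ek.delong_test(y, s, s)
        assert a_auc == b_auc
        assert p == 1.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        y, s1 = random_predset(rng, 200)
        s2 = np.clip(s1 + rng.normal(0, 0.2, 200), 0, 1)
        a1, b1, p1 = ek.delong_test(y, s1, s2)
        a2, b2, p2 = ek.delong_test(y, s2, s1)
        assert (a1, b1) == (b2, a2)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_agrees_with_sklearn_aurocs(self):
        rng = np.random.default_rng(9)
        y, s1 = random_predset(rng, 300)
        _, s2 = random_predset(rng, 300)
        a, b, _ = ek.delong_test(y, s1, s2)
        assert a == pytest.approx(roc_auc_score(y, s1), abs=1e-12)
        assert b == pytest.approx(roc_auc_score(y, s2), abs=1e-12)

    def test_detects_clear_difference(self):
        rng = np.random.default_rng(10)
        n = 500
        y = (rng.random(n) < 0.5).astype(int)
        good = np.clip(0.5 + 0.4 * (2 * y - 1) + rng.normal(0, 0.1, n), 0, 1)
        rand = rng.random(n)
        _, _, p = ek.delong_test(y, good, rand)
        assert p < 1e-6


class TestSelectThresholds:
    def test_perfectly_separated_midpoint(self):
        ps = ek.PredictionSet(
            scores=np.array([[0.9], [0.8], [0.2], [0.1]]),
            labels=np.array([[1], [1], [0], [0]]),
        )
        thr = ek.select_thresholds(ps)["label0"]
        assert 0.2 < thr <= 0.8
        preds = ek.apply_thresholds(ps, {"label0": thr})
        rates = ek.confusion_rates(ps.labels[:, 0], preds[:, 0])
        assert rates.tpr == 1.0 and rates.fpr == 0.0

    def test_documented_example(self):
        ps = ek.PredictionSet(
            scores=np.array([[0.9], [0.6], [0.4], [0.1]]),
            labels=np.array([[1], [1], [0], [0]]),
        )
        thr = ek.select_thresholds(ps)["label0"]
        assert 0.4 < thr <= 0.6

    @pytest.mark.parametrize("seed", range(20))
    def test_achieves_bruteforce_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 1000))
        y, s = random_predset(rng, n)
        s = np.round(s, 2)
        ps = ek.PredictionSet(scores=s[:, None], labels=y[:, None])
        thr = ek.select_thresholds(ps)["label0"]
        # brute force over all unique candidate thresholds
        best = max(
            ((s >= t)[y == 1].mean() + (1 - (s >= t)[y == 0].mean())) / 2
            for t in np.unique(s)
        )
        preds = (s >= thr).astype(int)
        achieved = (preds[y == 1].mean() + (1 - preds[y == 0].mean())) / 2
        assert achieved == pytest.approx(best, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(21)
        y, s = random_predset(rng, 400)
        ps = ek.PredictionSet(scores=s[:, None], labels=y[:, None])
        ps_cubed = ek.PredictionSet(scores=s[:, None] ** 3, labels=y[:, None])
        thr = ek.select_thresholds(ps)["label0"]
        thr3 = ek.select_thresholds(ps_cubed)["label0"]
        assert np.array_equal(s >= thr, s**3 >= thr3)

    def test_degenerate_label_reported_missing(self):
        ps = ek.PredictionSet(
            scores=np.array([[0.2], [0.4]]), labels=np.array([[1], [1]])
        )
        assert np.isnan(ek.select_thresholds(ps)["label0"])

    def test_curve_candidates_are_unique_scores(self):
        y = np.array([1.0, 1, 0, 0])
        s = np.array([0.9, 0.6, 0.4, 0.1])
        uniq, bacc = _balanced_accuracy_curve(y, s)
        assert np.array_equal(uniq, [0.1, 0.4, 0.6, 0.9])
        assert bacc[np.searchsorted(uniq, 0.6)] == 1.0


class TestConfusionRates:
    def test_perfect_predictions(self):
        r = ek.confusion_rates([1, 0, 1], [1, 0, 1])
        assert (r.tpr, r.fpr, r.specificity) == (1.0, 0.0, 1.0)

    def test_inverted_predictions(self):
        r = ek.confusion_rates([1, 0, 1], [0, 1, 0])
        assert (r.tpr, r.fpr) == (0.0, 1.0)

    def test_constructed_counts(self):
        # TP=8, FN=2, FP=1, TN=9
        y = [1] * 10 + [0] * 10
        p = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9
        r = ek.confusion_rates(y, p)
        assert r.tpr == 0.8 and r.fpr == 0.1 and r.specificity == 0.9

    def test_zero_denominator_is_nan_not_error(self):
        r = ek.confusion_rates([1, 1], [1, 0])
        assert np.isnan(r.fpr) and r.tpr == 0.5
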