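"""Diagnostic statistics, ROC/AUC oracles and the split protocol."""

import numpy as np
import pytest

from wkelm.data import Dataset, SimConfig, simulate_dataset
from wkelm.elm import TrainConfig, fit
from wkelm.evaluation import (
    ConfusionCounts,
    SplitPlan,
    UndefinedStatisticError,
    auc,
    confusion,
    evaluate_scores,
    overall,
    roc_curve,
    run_protocol,
    sensitivity,
    specificity,
)
from wkelm.kernels import KernelSpec


def pair_counting_auc(true_labels, scores, positive):
    """Independent rank-statistic oracle: P(s_pos > s_neg) + 0.5 P(equal)."""
    t = np.asarray(true_labels)
    s = np.asarray(scores, dtype=float)
    pos = s[t == positive]
    neg = s[t != positive]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_direct_tally(self):
        c = confusion(["P", "P", "N", "N"], ["P", "N", "N", "P"], "P")
        assert (c.TP, c.FN, c.TN, c.FP) == (1, 1, 1, 1)
        assert c.total == 4

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1], 1)
        assert c.FP == c.FN == 0

    def test_swapping_positive_class_swaps_counts(self, rng):
        t = rng.integers(0, 2, 40)
        p = rng.integers(0, 2, 40)
        c1 = confusion(t, p, 1)
        c0 = confusion(t, p, 0)
        assert (c1.TP, c1.TN, c1.FP, c1.FN) == (c0.TN, c0.TP, c0.FN, c0.FP)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="unseen"):
            confusion([0, 1], [0, 2], 1)


class TestRates:
    def test_arithmetic(self):
        assert sensitivity(ConfusionCounts(TP=9, FN=1, TN=0, FP=5)) == pytest.approx(0.9)
        assert specificity(ConfusionCounts(TP=0, FN=3, TN=8, FP=2)) == pytest.approx(0.8)
        c = ConfusionCounts(TP=5, TN=5, FP=0, FN=0)
        assert sensitivity(c) == specificity(c) == overall(c) == 1.0

    def test_zero_denominator_raises(self):
        no_pos = ConfusionCounts(TP=0, FN=0, TN=3, FP=1)
        with pytest.raises(UndefinedStatisticError):
            sensitivity(no_pos)
        no_neg = ConfusionCounts(TP=3, FN=1, TN=0, FP=0)
        with pytest.raises(UndefinedStatisticError):
            specificity(no_neg)

    def test_balanced_average_of_class_rates(self):
        # averaging sensitivity and specificity gives the balanced summary rate
        assert round((95.45 + 98.17) / 2, 2) == 96.81


class TestROC:
    def test_perfect_separation_passes_through_corner(self):
        pts = roc_curve([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 1)
        assert any(np.allclose(p, (0.0, 1.0)) for p in pts)
        assert auc(pts) == 1.0

    def test_constant_scores_collapse_to_diagonal(self):
        pts = roc_curve([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], 1)
        assert np.allclose(pts, [(0, 0), (1, 1)])
        assert auc(pts) == 0.5

    def test_six_point_toy_matches_threshold_enumeration(self):
        truth = np.array([1, 1, 0, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.5])
        pts = roc_curve(truth, scores, 1)
        # brute-force oracle: enumerate every threshold, predict pos iff >= thr
        expected = [(0.0, 0.0)]
        for thr in sorted(set(scores), reverse=True):
            pred = scores >= thr
            tpr = np.sum(pred & (truth == 1)) / 3
            fpr = np.sum(pred & (truth == 0)) / 3
            expected.append((fpr, tpr))
        if expected[-1] != (1.0, 1.0):
            expected.append((1.0, 1.0))
        assert np.allclose(pts, expected)
        assert auc(pts) == pytest.approx(pair_counting_auc(truth, scores, 1), abs=1e-12)

    def test_endpoints_and_monotonicity_random_inputs(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            t = rng.integers(0, 2, n)
            t[:2] = [0, 1]
            s = np.round(rng.normal(size=n), 1)  # induce ties
            pts = roc_curve(t, s, 1)
            assert np.allclose(pts[0], (0, 0)) and np.allclose(pts[-1], (1, 1))
            assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
            assert np.all((pts >= 0) & (pts <= 1))

    def test_trapezoid_auc_equals_pair_counting_on_random_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            t = rng.integers(0, 2, n)
            t[:2] = [0, 1]
            s = np.round(rng.normal(size=n), 1)
            got = auc(roc_curve(t, s, 1))
            assert got == pytest.approx(pair_counting_auc(t, s, 1), abs=1e-12)

    def test_auc_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            t = rng.integers(0, 2, 50)
            t[:2] = [0, 1]
            s = rng.normal(size=50)
            assert auc(roc_curve(t, s, 1)) == pytest.approx(roc_auc_score(t, s), abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 1, 1], [0.1, 0.2, 0.3], 1)

    def test_threshold_predictions_invariant_to_monotone_score_transform(self, rng):
        t = rng.integers(0, 2, 60)
        t[:2] = [0, 1]
        s = rng.normal(size=60)
        r1 = evaluate_scores(t, s, 1)
        r2 = evaluate_scores(t, np.expm1(s), 1)  # strictly monotone, sign-preserving
        assert r1.sensitivity == r2.sensitivity
        assert r1.specificity == r2.specificity
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)


def _fixed_pipeline(X, y):
    return fit(X, y, KernelSpec(), TrainConfig())


class TestProtocol:
    def test_repeated_holdout_sizes_and_disjointness(self):
        ds = simulate_dataset(SimConfig(n_samples=192, seed=2))
        plan = SplitPlan(scheme="repeated_holdout", train_fraction=2 / 3, repeats=3, seed=1)
        from wkelm.evaluation import _splits

        for train_idx, test_idx in _splits(plan, ds.features, ds.labels, None):
            assert len(test_idx) == 64 and len(train_idx) == 128
            assert len(np.intersect1d(train_idx, test_idx)) == 0

    def test_k_fold_partitions_every_case_once(self):
        ds = simulate_dataset(SimConfig(n_samples=192, seed=2))
        plan = SplitPlan(scheme="k_fold", k=3, repeats=1, seed=1)
        from wkelm.evaluation import _splits

        tested = np.concatenate([te for _, te in _splits(plan, ds.features, ds.labels, None)])
        assert sorted(tested) == list(range(192))

    def test_aggregate_is_mean_of_per_repeat_reports(self):
        ds = simulate_dataset(SimConfig(n_samples=90, seed=5))
        reports, agg = run_protocol(ds, SplitPlan(repeats=3, seed=0), _fixed_pipeline)
        assert len(reports) == 3
        assert agg["overall"] == pytest.approx(np.mean([r.overall for r in reports]))
        assert agg["auc"] == pytest.approx(np.mean([r.auc for r in reports]))

    def test_no_test_set_leakage(self):
        """Perturbing held-out rows must not change the fitted model's scores
        on a fixed probe: the pipeline sees only training rows."""
        ds = simulate_dataset(SimConfig(n_samples=60, seed=8))
        plan = SplitPlan(repeats=1, seed=4)
        from wkelm.evaluation import _splits

        train_idx, test_idx = next(_splits(plan, ds.features, ds.labels, None))
        probe = ds.features[:5]

        model_a = _fixed_pipeline(ds.features[train_idx], ds.labels[train_idx])
        perturbed = ds.features.copy()
        perturbed[test_idx] *= 10.0
        model_b = _fixed_pipeline(perturbed[train_idx], ds.labels[train_idx])
        assert np.array_equal(model_a.decision_scores(probe), model_b.decision_scores(probe))

    def test_group_aware_split_keeps_subjects_together(self):
        ds = simulate_dataset(SimConfig(n_samples=60, seed=9))
        subjects = np.repeat(np.arange(10), 6)  # 6 recordings per subject
        plan = SplitPlan(repeats=2, seed=0, group_aware=True)
        from wkelm.evaluation import _splits

        for train_idx, test_idx in _splits(plan, ds.features, ds.labels, subjects):
            assert not set(subjects[train_idx]) & set(subjects[test_idx])

    def test_single_class_training_split_is_named_error(self):
        features = np.random.default_rng(0).normal(size=(12, 3))
        labels = np.array([0] * 11 + [1])
        ds = Dataset(features, ["a", "b", "c"], labels, positive_class=1)
        plan = SplitPlan(repeats=1, stratified=False, seed=5, train_fraction=0.5)
        with pytest.raises(ValueError, match="repeat|single class|least populated"):
            run_protocol(ds, plan, _fixed_pipeline)
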