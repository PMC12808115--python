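"""OOD scoring: ROC/AUC, F1 sweep, isotonic calibration, reliability."""

import numpy as np
import pytest

from mrxform.ood_detect import (
    CalibrationMap,
    OODScoreSet,
    calibrate_isotonic,
    f1_from_counts,
    f1_sweep,
    reliability_metrics,
    roc_auc,
)

rng = np.random.default_rng(0)


def _scoreset(scores, labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(scores))]
    return OODScoreSet(subject_ids=ids, scores=np.asarray(scores, float),
                       labels=np.asarray(labels, int))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        ss = _scoreset([0.1, 0.2, 0.3, 0.8, 0.9, 1.0], [0, 0, 0, 1, 1, 1])
        _, auc = roc_auc(ss)
        assert auc == pytest.approx(1.0)

    def test_random_scores_give_auc_near_half(self):
        local = np.random.default_rng(7)
        ss = _scoreset(local.random(2000), local.integers(0, 2, 2000))
        _, auc = roc_auc(ss)
        assert abs(auc - 0.5) < 0.05

    def test_rank_invariance_under_strictly_increasing_transform(self):
        local = np.random.default_rng(3)
        scores = local.random(50)
        labels = local.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1  # both classes present
        _, a1 = roc_auc(_scoreset(scores, labels))
        _, a2 = roc_auc(_scoreset(np.exp(5 * scores), labels))
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(_scoreset([0.1, 0.5], [0, 0]))


class TestF1:
    def test_contingency_arithmetic(self):
        # TP=8, FP=2, FN=2 -> precision 0.8, recall 0.8, F1 0.8
        assert f1_from_counts(8, 2, 2) == pytest.approx(0.8)

    def test_flag_everything_gives_recall_one_precision_prevalence(self):
        labels = np.array([1] * 4 + [0] * 12)
        scores = rng.random(16)
        f1s, _, _ = f1_sweep(_scoreset(scores, labels),
                             thresholds=np.array([scores.min() - 1.0]))
        prev = labels.mean()
        assert f1s[0] == pytest.approx(2 * prev / (prev + 1))

    def test_max_matches_bruteforce_over_midpoints(self):
        local = np.random.default_rng(5)
        scores = local.random(40)
        labels = (scores + 0.3 * local.standard_normal(40) > 0.5).astype(int)
        labels[:2] = [0, 1]
        ss = _scoreset(scores, labels)
        _, fmax, _ = f1_sweep(ss)
        # brute force over every midpoint threshold
        su = np.sort(np.unique(scores))
        cand = np.concatenate([[su[0] - 1], (su[1:] + su[:-1]) / 2, [su[-1] + 1]])
        brute = 0.0
        for th in cand:
            pred = (scores >= th).astype(int)
            tp = int(((pred == 1) & (labels == 1)).sum())
            fp = int(((pred == 1) & (labels == 0)).sum())
            fn = int(((pred == 0) & (labels == 1)).sum())
            brute = max(brute, f1_from_counts(tp, fp, fn))
        assert fmax == pytest.approx(brute)


class TestReliability:
    def test_perfect_probabilities(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        m = reliability_metrics(y.astype(float), y)
        assert m["brier"] == pytest.approx(0.0)
        assert m["ece"] == pytest.approx(0.0)
        assert m["nll"] < 1e-5

    def test_half_probabilities_on_balanced_set(self):
        y = np.array([0, 1] * 10)
        m = reliability_metrics(np.full(20, 0.5), y)
        assert m["brier"] == pytest.approx(0.25)
        assert m["nll"] == pytest.approx(np.log(2))

    def test_ece_matches_manual_binning_on_hand_built_set(self):
        probs = np.array([0.05, 0.15, 0.15, 0.35, 0.45, 0.55, 0.65, 0.85, 0.95, 0.95])
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 1])
        m = reliability_metrics(probs, y, n_bins=10)
        # manual equal-width binning
        manual = 0.0
        for lo in np.arange(0, 1, 0.1):
            hi = lo + 0.1
            sel = (probs >= lo) & (probs < hi) if hi < 1 else (probs >= lo)
            if sel.sum() == 0:
                continue
            manual += sel.sum() / 10 * abs(y[sel].mean() - probs[sel].mean())
        assert m["ece"] == pytest.approx(manual)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reliability_metrics(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            reliability_metrics(np.array([1.2]), np.array([1]))


class TestIsotonic:
    def _simulated(self, n, seed, transform=lambda p: p):
        local = np.random.default_rng(seed)
        p = local.random(n)
        y = (local.random(n) < p).astype(int)
        return transform(p), y

    def test_calibrated_scores_stay_calibrated(self):
        s_val, y_val = self._simulated(3000, 1)
        s_test, y_test = self._simulated(3000, 2)
        val = _scoreset(s_val, y_val, ids=[f"v{i}" for i in range(3000)])
        test = _scoreset(s_test, y_test, ids=[f"t{i}" for i in range(3000)])
        raw = reliability_metrics(s_test, y_test)
        cmap, test = calibrate_isotonic(val, test, n_folds=5, ood_subset_seed=0)
        cal = reliability_metrics(test.calibrated, y_test)
        assert cal["ece"] <= raw["ece"] + 0.01
        # the map should be close to the identity on the bulk of the range
        grid = np.linspace(0.1, 0.9, 9)
        assert np.abs(cmap(grid) - grid).mean() < 0.1

    def test_reduces_ece_of_miscalibrated_scores(self):
        # compressed scores: right ranking, wrong scale
        s_val, y_val = self._simulated(400, 3, transform=lambda p: 0.4 + 0.2 * p)
        s_test, y_test = self._simulated(400, 4, transform=lambda p: 0.4 + 0.2 * p)
        val = _scoreset(s_val, y_val, ids=[f"v{i}" for i in range(400)])
        test = _scoreset(s_test, y_test, ids=[f"t{i}" for i in range(400)])
        raw = reliability_metrics(s_test, y_test)
        _, test = calibrate_isotonic(val, test, n_folds=5, ood_subset_seed=0)
        cal = reliability_metrics(test.calibrated, y_test)
        assert cal["ece"] < raw["ece"]

    def test_monotone_map_preserves_ranking_auc(self):
        s_val, y_val = self._simulated(300, 5)
        s_test, y_test = self._simulated(300, 6)
        val = _scoreset(s_val, y_val, ids=[f"v{i}" for i in range(300)])
        test = _scoreset(s_test, y_test, ids=[f"t{i}" for i in range(300)])
        _, auc_raw = roc_auc(test)
        _, test = calibrate_isotonic(val, test, n_folds=5, ood_subset_seed=1)
        _, auc_cal = roc_auc(test, use="calibrated")
        assert abs(auc_cal - auc_raw) < 0.05  # plateaus introduce ties only

    def test_probabilities_always_in_unit_interval(self):
        s_val, y_val = self._simulated(100, 7)
        val = _scoreset(10 * s_val - 3, y_val, ids=[f"v{i}" for i in range(100)])
        s_test, y_test = self._simulated(100, 8)
        test = _scoreset(10 * s_test - 3, y_test, ids=[f"t{i}" for i in range(100)])
        _, test = calibrate_isotonic(val, test, n_folds=4, ood_subset_seed=2)
        assert test.calibrated.min() >= 0.0 and test.calibrated.max() <= 1.0

    def test_structural_errors(self):
        val = _scoreset([0.1, 0.9, 0.2, 0.8], [0, 1, 0, 1], ids=["a", "b", "c", "d"])
        overlap = _scoreset([0.5], [0], ids=["a"])
        with pytest.raises(ValueError, match="disjoint"):
            calibrate_isotonic(val, overlap)
        test = _scoreset([0.5], [0], ids=["z"])
        with pytest.raises(ValueError, match="folds"):
            calibrate_isotonic(val, test, n_folds=50)
        with pytest.raises(ValueError, match="monotone"):
            CalibrationMap(grid=np.array([0.0, 1.0]), values=np.array([0.8, 0.2]))


def test_scoreset_validation_and_normalization():
    with pytest.raises(ValueError):
        _scoreset([0.1, 0.2], [0, 2])
    ss = _scoreset([1.0, 3.0, 5.0], [0, 0, 1])
    np.testing.assert_allclose(ss.normalize(), [0.0, 0.5, 1.0])
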