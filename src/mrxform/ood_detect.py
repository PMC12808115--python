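"""OOD classification from scalar uncertainty scores.

The subject-level sigma_hat score (mean ensemble std over brain voxels)
is treated as a classifier score for in-distribution (label 0) versus
out-of-distribution (label 1) inputs: ROC/AUC, threshold-swept F1,
isotonic-regression calibration with cross-validation on held-out
validation data, and reliability metrics (ECE, Brier, NLL) on test data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "OODScoreSet",
    "CalibrationMap",
    "roc_auc",
    "f1_sweep",
    "calibrate_isotonic",
    "reliability_metrics",
]


@dataclass
class OODScoreSet:
    """Per-subject scores with binary labels (0 = ID, 1 = OOD)."""

    subject_ids: list
    scores: np.ndarray  # raw sigma_hat
    labels: np.ndarray
    model_tag: str = ""
    normalized: np.ndarray | None = None
    calibrated: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        self.labels = np.asarray(self.labels, int)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(self.scores) != len(self.labels):
            raise ValueError("scores/labels length mismatch")

    @classmethod
    def from_uncertainty_scores(cls, uscores, model_tag=""):
        return cls(
            subject_ids=[u.subject_id for u in uscores],
            scores=np.array([u.sigma_hat for u in uscores]),
            labels=np.array([0 if u.label == "ID" else 1 for u in uscores]),
            model_tag=model_tag,
        )

    def normalize(self, ref_min=None, ref_max=None):
        """Min-max scale scores (over this set, or a supplied reference range)."""
        lo = self.scores.min() if ref_min is None else ref_min
        hi = self.scores.max() if ref_max is None else ref_max
        rng = hi - lo if hi > lo else 1.0
        self.normalized = np.clip((self.scores - lo) / rng, 0.0, 1.0)
        return self.normalized

    def to_frame(self):
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "score": self.scores,
                "normalized": self.normalized if self.normalized is not None else np.nan,
                "calibrated": self.calibrated if self.calibrated is not None else np.nan,
                "label": self.labels,
                "model": self.model_tag,
            }
        )


@dataclass
class CalibrationMap:
    """Monotone nondecreasing score -> probability map on a fixed grid."""

    grid: np.ndarray
    values: np.ndarray
    n_folds: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("calibration map must be monotone nondecreasing")

    def __call__(self, scores):
        return np.clip(np.interp(np.asarray(scores, float), self.grid, self.values), 0.0, 1.0)


def _check_both_classes(labels):
    if labels.min() == labels.max():
        raise ValueError("both classes (ID and OOD) must be present")


def roc_auc(scores: OODScoreSet, use="scores"):
    """ROC curve and trapezoidal AUC for the score-as-OOD-probability rule."""
    s = getattr(scores, use) if use != "scores" else scores.scores
    _check_both_classes(scores.labels)
    fpr, tpr, thr = roc_curve(scores.labels, s)
    auc = float(roc_auc_score(scores.labels, s))
    return (fpr, tpr, thr), auc


def f1_sweep(scores: OODScoreSet, thresholds=None, use="scores"):
    """F1 (harmonic precision/recall mean) at each binarization threshold."""
    s = np.asarray(getattr(scores, use) if use != "scores" else scores.scores, float)
    y = scores.labels
    _check_both_classes(y)
    if thresholds is None:
        su = np.unique(s)
        mids = (su[1:] + su[:-1]) / 2.0
        thresholds = np.concatenate([[su[0] - 1.0], mids, [su[-1] + 1.0]])
    thresholds = np.asarray(thresholds, float)
    f1s = np.empty_like(thresholds)
    for i, th in enumerate(thresholds):
        pred = (s >= th).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        if tp == 0:
            f1s[i] = 0.0
        else:
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            f1s[i] = 2 * prec * rec / (prec + rec)
    best = int(np.argmax(f1s))
    return f1s, float(f1s[best]), float(thresholds[best])


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    prec = tp / (tp + fp)
    rec = tp / (tp + fn)
    return 2 * prec * rec / (prec + rec)


def calibrate_isotonic(
    val_scores: OODScoreSet,
    test_scores: OODScoreSet,
    n_folds: int = 5,
    ood_subset_seed: int = 0,
    grid_size: int = 201,
):
    """Cross-validated isotonic calibration fit on validation, applied to test.

    Folds are formed over the ID validation subjects, each combined with a
    randomly selected OOD subset of matching size for balanced coverage;
    per-fold isotonic fits are averaged on a fixed score grid into one
    monotone map, which rescales the held-out test scores.
    """
    if set(val_scores.subject_ids) & set(test_scores.subject_ids):
        raise ValueError("validation and test score sets must be subject-disjoint")
    y = val_scores.labels
    s = val_scores.scores
    id_idx = np.where(y == 0)[0]
    ood_idx = np.where(y == 1)[0]
    _check_both_classes(y)
    if n_folds > len(id_idx):
        raise ValueError(f"n_folds={n_folds} exceeds ID count {len(id_idx)}")
    rng = np.random.default_rng(ood_subset_seed)
    id_perm = rng.permutation(id_idx)
    folds = np.array_split(id_perm, n_folds)
    lo, hi = s.min(), s.max()
    grid = np.linspace(lo - 0.05 * (hi - lo + 1e-12), hi + 0.05 * (hi - lo + 1e-12), grid_size)
    fold_maps = []
    for fold in folds:
        train_id = np.setdiff1d(id_perm, fold)
        k = min(len(train_id), len(ood_idx))
        train_ood = rng.choice(ood_idx, size=k, replace=False)
        tr = np.concatenate([train_id, train_ood])
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(s[tr], y[tr])
        fold_maps.append(iso.predict(grid))
    values = np.mean(fold_maps, axis=0)
    cmap = CalibrationMap(grid=grid, values=values, n_folds=n_folds)
    test_scores.calibrated = cmap(test_scores.scores)
    val_scores.calibrated = cmap(val_scores.scores)
    return cmap, test_scores


def reliability_metrics(probs, labels, n_bins: int = 10, clip: float = 1e-6):
    """ECE (equal-width bins), Brier score, and NLL of binary probabilities."""
    p = np.asarray(probs, float)
    y = np.asarray(labels, int)
    if p.size == 0:
        raise ValueError("empty score set")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    n = len(p)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    ece = 0.0
    for m in range(n_bins):
        lo, hi = edges[m], edges[m + 1]
        sel = (p >= lo) & (p < hi) if m < n_bins - 1 else (p >= lo) & (p <= hi)
        nm = int(sel.sum())
        if nm == 0:
            continue
        acc = y[sel].mean()
        conf = p[sel].mean()
        ece += (nm / n) * abs(acc - conf)
    brier = float(((p - y) ** 2).mean())
    pc = np.clip(p, clip, 1.0 - clip)
    nll = float(-(y * np.log(pc) + (1 - y) * np.log(1 - pc)).mean())
    return {"ece": float(ece), "brier": brier, "nll": nll}
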