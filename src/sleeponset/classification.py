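"""RBF-SVM drowsiness classifier: level merging, training, pruning, evaluation.

The six annotated vigilance levels (6 = awake ... 1 = deep sleep) collapse to
four modeled classes — the three drowsiest levels carry no separable profile
and are merged.  Classes keep the numeric coding 6, 5, 4, 3 where 3 stands
for the merged {3, 2, 1} group.

Features are z-standardised (they mix µV, Hz, Hz² and counts), the RBF kernel
``K(x, x') = exp(-||x - x'||² / (2 σ²))`` is used, and (σ, C) are picked by
stratified n-fold cross-validated accuracy over a log grid.  Multiclass is
one-vs-one with voting; each binary sub-problem keeps its own support set so
the model can be compressed by retaining only the support vectors with the
largest absolute dual coefficients — the ones that dominate the decision
function.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ValidationError

#: level -> merged class (classes coded 6, 5, 4, 3; 3 = merged {3,2,1})
LEVEL_MAP = {6: 6, 5: 5, 4: 4, 3: 3, 2: 3, 1: 3}

CLASS_NAMES = {6: "awake", 5: "slightly drowsy", 4: "moderately drowsy", 3: "drowsy/sleep"}

DEFAULT_SIGMA_GRID = (0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_C_GRID = (1.0, 10.0, 100.0)


def merge_levels(labels) -> np.ndarray:
    """Map six-level annotations onto the four modeled classes."""
    arr = np.atleast_1d(np.asarray(labels, dtype=int))
    if not np.all(np.isin(arr, list(LEVEL_MAP))):
        bad = sorted(set(arr.tolist()) - set(LEVEL_MAP))
        raise ValidationError(f"labels outside 1..6: {bad}")
    return np.vectorize(LEVEL_MAP.get)(arr)


def rbf_kernel(x: np.ndarray, xi: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel ``exp(-||x - xi||² / (2 σ²))``; rows of 2-D inputs pair up."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    if x.shape[1] != xi.shape[1]:
        raise ValidationError("dimension mismatch")
    d2 = np.sum(x**2, axis=1)[:, None] + np.sum(xi**2, axis=1)[None, :] - 2.0 * x @ xi.T
    k = np.exp(-np.maximum(d2, 0.0) / (2.0 * sigma**2))
    return k if k.size > 1 else float(k[0, 0])


@dataclass
class _BinarySVM:
    """One one-vs-one sub-problem: decision > 0 votes for ``class_pos``."""

    class_neg: int
    class_pos: int
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i, signed
    intercept: float

    def decision(self, xs: np.ndarray, sigma: float) -> np.ndarray:
        k = np.atleast_2d(rbf_kernel(xs, self.support_vectors, sigma))
        return k @ self.dual_coef + self.intercept


@dataclass
class VigilanceModel:
    """Trained, optionally pruned, one-vs-one RBF-SVM over the mapped classes."""

    sigma: float
    C: float
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    classes: list[int]
    pairs: list[_BinarySVM]
    level_map: dict[int, int] = field(default_factory=lambda: dict(LEVEL_MAP))
    cv_accuracy: float = float("nan")

    @property
    def n_support_vectors(self) -> int:
        return sum(len(p.dual_coef) for p in self.pairs)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "VigilanceModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, VigilanceModel):
            raise ValidationError("file does not contain a VigilanceModel")
        return model


def _as_matrix(features, feature_names: list[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [f for f in feature_names if f not in features.columns]
        if missing:
            raise ValidationError(f"missing features: {missing}")
        x = features[feature_names].to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(feature_names):
            raise ValidationError(
                f"expected {len(feature_names)} features, got {x.shape[1]}"
            )
    if np.any(np.isnan(x)):
        raise ValidationError("NaN feature values; mask or impute before classification")
    return x


def train(
    features,
    labels,
    feature_names: list[str] | None = None,
    sigma_grid=DEFAULT_SIGMA_GRID,
    c_grid=DEFAULT_C_GRID,
    folds: int = 5,
    seed: int = 0,
    merge: bool = True,
) -> VigilanceModel:
    """Fit the one-vs-one RBF-SVM with (σ, C) chosen by cross-validated accuracy.

    ``features`` may be a DataFrame (columns selected by ``feature_names``)
    or a plain matrix.  Labels are six-level annotations; they are merged to
    the four modeled classes unless ``merge=False``.
    """
    if feature_names is None:
        if isinstance(features, pd.DataFrame):
            feature_names = [c for c in features.columns if c != "label"]
        else:
            feature_names = [f"f{i}" for i in range(np.atleast_2d(features).shape[1])]
    x = _as_matrix(features, feature_names)
    y = merge_levels(labels) if merge else np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes to train")
    if np.any(counts < folds):
        raise ValidationError(
            f"every class needs >= {folds} samples for {folds}-fold CV (counts: {dict(zip(classes, counts))})"
        )

    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0.0] = 1.0
    xs = (x - mean) / scale

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(xs, y))
    best = (-1.0, None, None)
    for sigma in sigma_grid:
        gamma = 1.0 / (2.0 * sigma**2)
        for c in c_grid:
            accs = []
            for tr, te in splits:
                clf = SVC(C=c, kernel="rbf", gamma=gamma)
                clf.fit(xs[tr], y[tr])
                accs.append(float(np.mean(clf.predict(xs[te]) == y[te])))
            score = float(np.mean(accs))
            if score > best[0]:
                best = (score, sigma, c)
    cv_acc, sigma, c = best
    gamma = 1.0 / (2.0 * sigma**2)

    pairs = []
    for a, b in combinations(sorted(classes), 2):
        mask = np.isin(y, (a, b))
        clf = SVC(C=c, kernel="rbf", gamma=gamma)
        clf.fit(xs[mask], y[mask])
        # sklearn orders binary classes ascending; decision > 0 => classes_[1]
        pairs.append(
            _BinarySVM(
                class_neg=int(clf.classes_[0]),
                class_pos=int(clf.classes_[1]),
                support_vectors=clf.support_vectors_.copy(),
                dual_coef=clf.dual_coef_[0].copy(),
                intercept=float(clf.intercept_[0]),
            )
        )
    return VigilanceModel(
        sigma=sigma,
        C=c,
        feature_names=list(feature_names),
        scaler_mean=mean,
        scaler_scale=scale,
        classes=[int(v) for v in sorted(classes)],
        pairs=pairs,
        cv_accuracy=cv_acc,
    )


def predict(model: VigilanceModel, features, return_scores: bool = False):
    """Mapped class per row by one-vs-one voting; ties break toward the drowsier class."""
    x = _as_matrix(features, model.feature_names)
    xs = (x - model.scaler_mean) / model.scaler_scale
    n = xs.shape[0]
    votes = {c: np.zeros(n) for c in model.classes}
    margin = {c: np.zeros(n) for c in model.classes}
    for pair in model.pairs:
        d = pair.decision(xs, model.sigma)
        pos = d > 0
        votes[pair.class_pos] += pos
        votes[pair.class_neg] += ~pos
        margin[pair.class_pos] += d
        margin[pair.class_neg] -= d
    vote_mat = np.stack([votes[c] for c in model.classes])
    margin_mat = np.stack([margin[c] for c in model.classes])
    # lexicographic: votes first, summed margins break ties deterministically
    best = np.argmax(vote_mat + 1e-6 * np.tanh(margin_mat), axis=0)
    preds = np.array([model.classes[i] for i in best])
    if return_scores:
        return preds, {c: margin[c] for c in model.classes}
    return preds


def prune_support_vectors(model: VigilanceModel, fraction: float = 0.30) -> VigilanceModel:
    """Compress the model: keep the ``ceil(fraction * n_sv)`` largest-|dual|
    support vectors of every binary sub-problem.

    The retained dual coefficients are rescaled per sign group so that the
    dual balance ``sum(alpha_i y_i) = 0`` of the full solution is preserved;
    dropping it would shift every decision value by a class-dependent bias.
    Intercepts are kept, so pruning is exact at ``fraction=1``.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must lie in (0, 1]")
    pruned = []
    for pair in model.pairs:
        keep = math.ceil(fraction * len(pair.dual_coef))
        idx = np.argsort(-np.abs(pair.dual_coef), kind="stable")[:keep]
        idx = np.sort(idx)
        dual = pair.dual_coef[idx].copy()
        pos = dual[dual > 0].sum()
        neg = -dual[dual < 0].sum()
        if pos > 0 and neg > 0:
            target = 0.5 * (pos + neg)
            dual = np.where(dual > 0, dual * target / pos, dual * target / neg)
        pruned.append(
            _BinarySVM(
                class_neg=pair.class_neg,
                class_pos=pair.class_pos,
                support_vectors=pair.support_vectors[idx],
                dual_coef=dual,
                intercept=pair.intercept,
            )
        )
    return VigilanceModel(
        sigma=model.sigma,
        C=model.C,
        feature_names=list(model.feature_names),
        scaler_mean=model.scaler_mean,
        scaler_scale=model.scaler_scale,
        classes=list(model.classes),
        pairs=pruned,
        level_map=dict(model.level_map),
        cv_accuracy=model.cv_accuracy,
    )


@dataclass
class EvaluationReport:
    """Accuracy / macro sensitivity / macro specificity (%) with the confusion matrix."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: pd.DataFrame  # rows = truth, columns = predicted
    n_test: int

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "n_test": self.n_test,
            "confusion": self.confusion.to_dict(),
        }


def evaluate(predictions, truth) -> EvaluationReport:
    """Overall accuracy plus macro one-vs-rest sensitivity and specificity (percent)."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape or pred.size == 0:
        raise ValidationError("predictions and truth must be equal-length and non-empty")
    classes = sorted(set(y.tolist()) | set(pred.tolist()))
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y, pred):
        cm[index[t], index[p]] += 1
    total = cm.sum()
    acc = 100.0 * np.trace(cm) / total
    sens, spec = [], []
    for i in range(len(classes)):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            sens.append(tp / (tp + fn))
        if tn + fp > 0:
            spec.append(tn / (tn + fp))
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    return EvaluationReport(
        accuracy=float(acc),
        sensitivity=100.0 * float(np.mean(sens)),
        specificity=100.0 * float(np.mean(spec)),
        confusion=confusion,
        n_test=int(total),
    )


def alarm(mapped_class: int, threshold_class: int = 4) -> bool:
    """True when the predicted class is at or beyond the alarm threshold severity.

    Classes are coded 6 (awake) down to 3 (merged drowsy/sleep); the default
    threshold fires from 'moderately drowsy' (4) downward.
    """
    if mapped_class not in CLASS_NAMES or threshold_class not in CLASS_NAMES:
        raise ValidationError("classes must be one of 6, 5, 4, 3")
    return mapped_class <= threshold_class
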