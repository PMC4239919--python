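"""Mutual-information ranking of features against the six-level drowsiness label.

Features are discretised into equal-frequency bins (default 8) and scored by
the plug-in mutual information ``I(X;Y) = H(X) + H(Y) - H(X,Y)`` in bits
against the six-level class.  Equal-frequency binning makes the score
invariant to any strictly monotone rescaling of a feature, which suits a
feature set that mixes µV, Hz, Hz² and counts.  The top-``k`` features
(default k = 12) feed the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class MIRanking:
    """Per-feature MI scores (bits) and the descending-score feature order."""

    scores: dict[str, float]
    order: list[str]
    n_bins: int
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": self.order,
                "mi_bits": [self.scores[f] for f in self.order],
            }
        )


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of a discrete distribution; ``0 log 0 = 0``."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete columns."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if x.size == 0:
        raise ValidationError("empty input")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    hx = entropy(joint.sum(axis=1))
    hy = entropy(joint.sum(axis=0))
    hxy = entropy(joint.ravel())
    return max(0.0, hx + hy - hxy)


def discretize(column: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Equal-frequency binning by stable rank; ties keep their input order.

    Sample ``i`` with rank ``r`` (stable sort) gets bin ``floor(r * b / n)``
    where ``b = min(n_bins, #distinct values)``.  Monotone transforms of the
    column produce the identical binning.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValidationError("empty column")
    if np.any(np.isnan(x)):
        raise ValidationError("NaN values must be dropped before discretisation")
    b = min(n_bins, len(np.unique(x)))
    if b < 1:
        raise ValidationError("n_bins must be >= 1")
    ranks = np.empty(x.size, dtype=int)
    ranks[np.argsort(x, kind="stable")] = np.arange(x.size)
    return (ranks * b) // x.size


def rank_features(features: pd.DataFrame, labels: np.ndarray, n_bins: int = 8) -> MIRanking:
    """Score every feature column by MI with the labels, descending.

    NaN feature values are dropped pairwise (per feature) together with their
    labels; ties in MI break by canonical column order.
    """
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValidationError("labels and feature rows differ in length")
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least 2 distinct labels")
    cols = [c for c in features.columns if c != "label"]
    scores: dict[str, float] = {}
    for c in cols:
        x = features[c].to_numpy(dtype=float)
        mask = ~np.isnan(x)
        if mask.sum() < 2 or len(np.unique(labels[mask])) < 2:
            scores[c] = 0.0
            continue
        scores[c] = mutual_information(discretize(x[mask], n_bins), labels[mask])
    # stable sort on -score keeps canonical column order among ties
    order = sorted(cols, key=lambda c: (-scores[c], cols.index(c)))
    return MIRanking(scores=scores, order=order, n_bins=n_bins, n_samples=len(features))


def select_top_k(ranking: MIRanking, k: int = 12) -> list[str]:
    """First ``k`` feature names of the descending-MI order."""
    if not (1 <= k <= len(ranking.order)):
        raise ValidationError(f"k={k} outside 1..{len(ranking.order)}")
    return ranking.order[:k]
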