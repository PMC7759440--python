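"""Dice coefficient and the composite segmentation training loss.

The validation metric is the hard Dice coefficient

    D(X, Y) = 2 |X ∩ Y| / (|X| + |Y|) = 2 TP / (2 TP + FP + FN),

1 for a perfect match and 0 for disjoint non-empty regions.  The training
loss combines a differentiable soft Dice with categorical cross-entropy:

    loss = (1 - soft Dice) + 0.1 * CCE,

where soft Dice uses predicted class probabilities with a smoothing term
eps = 1 in numerator and denominator (avoids 0/0 on empty classes) and CCE
is averaged over voxels so the 0.1 weight is resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Feature classes scored by default; background (0) is excluded so it
#: cannot mask feature errors.
FEATURE_CLASSES = (1, 2, 3)

#: Smoothing constant of the soft Dice.
DICE_EPS = 1.0

#: Weight of the cross-entropy term in the composite loss.
CCE_WEIGHT = 0.1


@dataclass
class ConfusionCounts:
    """Voxel-level true/false positive and false negative counts for a class."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def dice(self) -> float:
        return dice_from_counts(self.tp, self.fp, self.fn)


def dice(pred_region: np.ndarray, true_region: np.ndarray) -> float:
    """Hard Dice overlap of two boolean masks on the same lattice.

    Two empty masks score 1 (perfect agreement on absence).
    """
    x = np.asarray(pred_region, dtype=bool)
    y = np.asarray(true_region, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask lattices differ: {x.shape} vs {y.shape}")
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / total


def dice_from_counts(tp: int, fp: int, fn: int) -> float:
    """Dice as 2TP / (2TP + FP + FN); 1 when all three counts are zero."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def dice_multiclass(
    pred, truth, classes: tuple[int, ...] = FEATURE_CLASSES
) -> tuple[dict[int, float], float]:
    """Per-class hard Dice plus the unweighted mean over present classes.

    ``pred`` and ``truth`` may be LabelMaps or integer arrays.  A class absent
    from both prediction and truth is scored 1 but excluded from the mean, so
    feature-free crops do not dilute the average.
    """
    p = np.asarray(getattr(pred, "data", pred))
    t = np.asarray(getattr(truth, "data", truth))
    if p.shape != t.shape:
        raise ValueError(f"label lattices differ: {p.shape} vs {t.shape}")
    scores: dict[int, float] = {}
    present: list[float] = []
    for c in classes:
        pc, tc = p == c, t == c
        scores[c] = dice(pc, tc)
        if pc.any() or tc.any():
            present.append(scores[c])
    mean = float(np.mean(present)) if present else 1.0
    return scores, mean


def one_hot(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Label grid -> (..., n_classes) one-hot float array."""
    lab = np.asarray(getattr(labels, "data", labels))
    out = np.zeros(lab.shape + (n_classes,), dtype=np.float64)
    for c in range(n_classes):
        out[..., c] = lab == c
    return out


def soft_dice(pred_probs: np.ndarray, truth_onehot: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Differentiable Dice over probabilities, averaged over classes."""
    axes = tuple(range(pred_probs.ndim - 1))
    num = 2.0 * (pred_probs * truth_onehot).sum(axis=axes) + eps
    den = pred_probs.sum(axis=axes) + truth_onehot.sum(axis=axes) + eps
    return float(np.mean(num / den))


def categorical_cross_entropy(pred_probs: np.ndarray,
                              truth_onehot: np.ndarray) -> float:
    """Per-voxel multiclass log loss, averaged over voxels."""
    p = np.clip(pred_probs, 1e-12, 1.0)
    per_voxel = -(truth_onehot * np.log(p)).sum(axis=-1)
    return float(per_voxel.mean())


def composite_loss(pred_probs: np.ndarray, truth,
                   cce_weight: float = CCE_WEIGHT,
                   eps: float = DICE_EPS) -> float:
    """(1 - soft Dice) + 0.1 x categorical cross-entropy.

    ``truth`` may be a one-hot array or an integer label grid/LabelMap.
    Zero exactly when the prediction is a one-hot match of the truth.
    """
    pred_probs = np.asarray(pred_probs, dtype=np.float64)
    sums = pred_probs.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("pred_probs must sum to 1 across classes at every voxel")
    truth_arr = np.asarray(getattr(truth, "data", truth))
    if truth_arr.shape == pred_probs.shape:
        onehot = truth_arr.astype(np.float64)
    else:
        onehot = one_hot(truth_arr, pred_probs.shape[-1])
    return (1.0 - soft_dice(pred_probs, onehot, eps)
            + cce_weight * categorical_cross_entropy(pred_probs, onehot))
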