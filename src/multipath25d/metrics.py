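"""Segmentation loss and evaluation statistics.

The training objective is a two-channel soft-Dice loss.  For a soft
prediction p over voxels i and a binary target r,

    D(p) = 2 * sum_i p_i r_i / (sum_i p_i^2 + sum_i r_i^2 + eps)

and with a softmax-paired output (p, q), where channel p predicts the lesion
and channel q its complement, the loss is

    L = 2 - ( D(p; r) + D(q; 1 - r) ).

Evaluation uses the plain Dice coefficient DICE = 2TP / (2TP + FP + FN),
lesion-size stratification by bounding-box extent, and the two-sided
Wilcoxon rank-sum (Mann-Whitney U) test for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

#: denominator guard so empty-target channels do not divide by zero
SOFT_DICE_EPS = 1e-7


class MetricValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# soft Dice loss
# ---------------------------------------------------------------------------

def soft_dice(p: np.ndarray, r: np.ndarray, eps: float = SOFT_DICE_EPS) -> float:
    """Soft Dice overlap D(p) between a soft prediction and a binary target."""
    p = np.asarray(p)
    r = np.asarray(r)
    if p.shape != r.shape:
        raise MetricValidationError(f"shape mismatch: {p.shape} vs {r.shape}")
    pr = float(np.sum(p.astype(np.float64) * r))
    den = float(np.sum(p.astype(np.float64) ** 2) + np.sum(r.astype(np.float64) ** 2))
    return 2.0 * pr / (den + eps)


def _soft_dice_grad(p: np.ndarray, r: np.ndarray,
                    eps: float = SOFT_DICE_EPS) -> np.ndarray:
    """dD/dp for D(p) = 2*sum(p r) / (sum p^2 + sum r^2 + eps)."""
    p64 = p.astype(np.float64)
    r64 = r.astype(np.float64)
    num = 2.0 * np.sum(p64 * r64)
    den = np.sum(p64 ** 2) + np.sum(r64 ** 2) + eps
    return (2.0 * r64 * den - num * 2.0 * p64) / den ** 2


def two_channel_loss(p: np.ndarray, q: np.ndarray, r: np.ndarray,
                     eps: float = SOFT_DICE_EPS) -> float:
    """Loss 2 - (D(p; r) + D(q; 1-r)); zero iff the prediction is exact."""
    r = np.asarray(r)
    return 2.0 - (soft_dice(p, r, eps) + soft_dice(q, 1 - r, eps))


def two_channel_loss_from_logits(logits: np.ndarray, r: np.ndarray,
                                 eps: float = SOFT_DICE_EPS
                                 ) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. the raw 2-channel logits.

    *logits* has the channel axis at position 1 (shape ``(n, 2, ...)``); the
    softmax pairing p + q = 1 is applied internally, and the returned
    gradient has the same shape as *logits*.  The loss is computed jointly
    over the whole batch, so slices without lesion still contribute through
    the complement channel.
    """
    if logits.shape[1] != 2:
        raise MetricValidationError("logits must have 2 channels on axis 1")
    r = np.asarray(r)
    if r.shape != logits.shape[:1] + logits.shape[2:]:
        raise MetricValidationError(
            f"target shape {r.shape} incompatible with logits {logits.shape}")
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    sm = e / e.sum(axis=1, keepdims=True)
    p, q = sm[:, 0], sm[:, 1]
    loss = 2.0 - (soft_dice(p, r, eps) + soft_dice(q, 1 - r, eps))
    # dL/dp_total, folding in q = 1 - p
    dLdp = -_soft_dice_grad(p, r, eps) + _soft_dice_grad(q, 1 - r, eps)
    # softmax pair: dp/dz0 = p*q, dp/dz1 = -p*q
    pq = (p * q).astype(np.float64)
    dz = np.empty_like(logits, dtype=np.float64)
    dz[:, 0] = dLdp * pq
    dz[:, 1] = -dLdp * pq
    return float(loss), dz.astype(np.float32)


# ---------------------------------------------------------------------------
# hard Dice coefficient
# ---------------------------------------------------------------------------

@dataclass
class DiceResult:
    """Voxel counts and the Dice coefficient for one prediction/truth pair."""

    tp: int
    fp: int
    fn: int
    dice: float


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> DiceResult:
    """DICE = 2TP / (2TP + FP + FN); empty-vs-empty is defined as 1."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise MetricValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if not np.all(np.isin(np.unique(arr), (0, 1))):
            raise MetricValidationError(f"{name} mask is not binary")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    den = 2 * tp + fp + fn
    dice = 1.0 if den == 0 else 2.0 * tp / den
    return DiceResult(tp=tp, fp=fp, fn=fn, dice=dice)


# ---------------------------------------------------------------------------
# lesion size stratification
# ---------------------------------------------------------------------------

class SizeClass(str, Enum):
    SMALL = "small"
    LARGE = "large"


#: bounding-box extent thresholds in mm, in canonical array-axis order
#: (inferior-superior, posterior-anterior, left-right).  The anatomical rule
#: is 20 x 20 x 25 mm in (x=LR, y=PA, z=IS), hence (25, 20, 20) here.
SIZE_THRESHOLDS_MM = (25.0, 20.0, 20.0)


def classify_lesion_size(mask: np.ndarray,
                         spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                         thresholds_mm: tuple[float, float, float] = SIZE_THRESHOLDS_MM
                         ) -> SizeClass:
    """Classify a lesion as small or large by its bounding-box extents.

    A lesion is *small* iff every bounding-box extent (in mm) is strictly
    below its threshold; a lesion meeting or exceeding any threshold is
    *large*.  The box is measured over the whole foreground.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise MetricValidationError("cannot classify an empty mask")
    extents = []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        extents.append((idx[-1] - idx[0] + 1) * spacing[axis])
    small = all(e < t for e, t in zip(extents, thresholds_mm))
    return SizeClass.SMALL if small else SizeClass.LARGE


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Uses exact null enumeration when the combined sample size is at most 12
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise MetricValidationError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        # fully tied: the tie-corrected normal approximation degenerates
        return 1.0
    no_ties = np.unique(combined).size == combined.size
    if no_ties and combined.size <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)
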