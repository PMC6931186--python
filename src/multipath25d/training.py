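"""Optimization loop and evaluation harnesses.

Training follows the published recipe: stochastic gradient descent with
Nesterov momentum 0.9 and weight decay 1e-4, batch size 32, initial learning
rate 0.01 decayed by 3% after each epoch, 50 epochs at full scale.  The nine
path networks are trained independently on 2D slices and then frozen; the 3D
post-processor is trained on stacked path outputs.  Harnesses cover balanced
k-fold cross-validation and cross-study (train on one dataset, test on a
disjoint one) evaluation with size-stratified summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    classify_lesion_size,
    dice_coefficient,
    two_channel_loss_from_logits,
)
from .nn import SGD
from .unet import DualUNet
from .views import PathInput
from .fusion import Fusion3DNet, StackedPathTensor


class ValidationError(ValueError):
    pass


class LeakageError(ValueError):
    """A case appears in both the training and the test role."""


@dataclass
class TrainConfig:
    """Hyperparameters of the SGD recipe.

    ``lr_decay_per_epoch`` is a multiplicative learning-rate decay (3% per
    epoch); ``weight_decay`` is the separate L2 penalty.  ``steps_per_epoch``
    limits minibatches per epoch (None = one full pass over all slices).
    """

    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 32
    lr0: float = 0.01
    lr_decay_per_epoch: float = 0.03
    epochs: int = 50
    seed: int = 0
    steps_per_epoch: int | None = None

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValidationError("lr0 must be positive")
        if not 0.0 <= self.lr_decay_per_epoch < 1.0:
            raise ValidationError("lr decay must be in [0, 1)")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate at *epoch*: lr0 * (1 - decay)^epoch."""
    if not 0 <= epoch < cfg.epochs:
        raise ValidationError(f"epoch {epoch} outside [0, {cfg.epochs})")
    return cfg.lr0 * (1.0 - cfg.lr_decay_per_epoch) ** epoch


def train_path(data: list[tuple[PathInput, np.ndarray]], cfg: TrainConfig,
               net: DualUNet) -> list[float]:
    """Train one path network on slice pairs; returns the per-epoch mean loss.

    *data* pairs each :class:`PathInput` with the matching ``(n, h, w)``
    binary mask stack.  Half of every batch is drawn from lesion-bearing
    slices and half from all slices: without this class balancing the
    soft-Dice/softmax pairing can saturate into an all-background prediction
    whose gradient vanishes with p.  Slices without lesion are retained (the
    complement channel keeps the loss informative on them).
    """
    if not data:
        raise ValidationError("no training data")
    index: list[tuple[int, int]] = []
    lesion_index: list[tuple[int, int]] = []
    for ci, (view, mask_stack) in enumerate(data):
        if mask_stack.shape != view.primary_stack.shape:
            raise ValidationError("mask stack shape differs from view stack")
        for si in range(mask_stack.shape[0]):
            index.append((ci, si))
            if mask_stack[si].any():
                lesion_index.append((ci, si))
    index_arr = np.array(index)
    lesion_arr = np.array(lesion_index) if lesion_index else index_arr
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(net, lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay, nesterov=True)
    n_steps = cfg.steps_per_epoch or int(np.ceil(len(index_arr) / cfg.batch_size))
    n_lesion = cfg.batch_size // 2

    trace: list[float] = []
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        losses = []
        for _ in range(n_steps):
            pick = np.concatenate([
                lesion_arr[rng.integers(0, len(lesion_arr), size=n_lesion)],
                index_arr[rng.integers(0, len(index_arr),
                                       size=cfg.batch_size - n_lesion)],
            ])
            xp = np.stack([data[ci][0].primary_stack[si] for ci, si in pick])
            xa = np.stack([data[ci][0].auxiliary_stack[si] for ci, si in pick])
            tgt = np.stack([data[ci][1][si] for ci, si in pick]).astype(np.float32)
            logits = net.forward(xp, xa)
            loss, dz = two_channel_loss_from_logits(logits, tgt)
            net.zero_grad()
            net.backward(dz)
            opt.step(lr=lr)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


def train_fuser(stacks: list[StackedPathTensor], masks: list[np.ndarray],
                cfg: TrainConfig, fuser: Fusion3DNet,
                patch_size: int = 16, patch_batch: int = 4) -> list[float]:
    """Train the 3D post-processor on stacked path outputs (paths frozen).

    Optimizes the two-channel soft-Dice loss on random 3D patches, half of
    them centered on lesion voxels so the minority class is always seen.
    Returns the per-epoch mean loss trace.
    """
    if not stacks:
        raise ValidationError("no training data")
    if len(stacks) != len(masks):
        raise ValidationError("stacks and masks differ in length")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(fuser, lr=cfg.lr0, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay, nesterov=True)
    lesion_coords = [np.argwhere(np.asarray(m) > 0) for m in masks]
    n_steps = cfg.steps_per_epoch or max(1, 4 * len(stacks) // patch_batch)

    def sample_patch(case_idx: int) -> tuple[np.ndarray, np.ndarray]:
        stack = stacks[case_idx].data
        mask = np.asarray(masks[case_idx])
        shape = mask.shape
        coords = lesion_coords[case_idx]
        if len(coords) and rng.random() < 0.5:
            center = coords[rng.integers(0, len(coords))]
            lo = [int(np.clip(c - patch_size // 2, 0, s - patch_size))
                  for c, s in zip(center, shape)]
        else:
            lo = [int(rng.integers(0, s - patch_size + 1)) for s in shape]
        sl = tuple(slice(l, l + patch_size) for l in lo)
        return stack[(slice(None),) + sl], mask[sl]

    trace: list[float] = []
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        losses = []
        for _ in range(n_steps):
            picks = rng.integers(0, len(stacks), size=patch_batch)
            xs, ts = zip(*(sample_patch(int(ci)) for ci in picks))
            x = np.stack(xs).astype(np.float32)
            t = np.stack(ts).astype(np.float32)
            logits = fuser.forward(x)
            loss, dz = two_channel_loss_from_logits(logits, t)
            fuser.zero_grad()
            fuser.backward(dz)
            opt.step(lr=lr)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace


# ---------------------------------------------------------------------------
# evaluation harnesses
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Balanced assignment of cases to k cross-validation folds."""

    n_cases: int
    k: int
    assignments: dict[str, int]
    seed: int

    def fold_sizes(self) -> list[int]:
        counts = [0] * self.k
        for f in self.assignments.values():
            counts[f] += 1
        return counts

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train_ids, test_ids) for one fold."""
        test = [c for c, f in self.assignments.items() if f == fold]
        train = [c for c, f in self.assignments.items() if f != fold]
        return train, test


def kfold_split(case_ids: list[str], k: int = 5, seed: int = 0) -> FoldPlan:
    """Deterministic, size-balanced k-fold partition of *case_ids*."""
    if k > len(case_ids):
        raise ValidationError(f"k={k} exceeds {len(case_ids)} cases")
    if len(set(case_ids)) != len(case_ids):
        raise ValidationError("duplicate case ids")
    rng = np.random.default_rng(seed)
    order = list(case_ids)
    rng.shuffle(order)
    assignments = {cid: i % k for i, cid in enumerate(order)}
    return FoldPlan(n_cases=len(case_ids), k=k, assignments=assignments, seed=seed)


def evaluate_cases(cases, predict_fn) -> pd.DataFrame:
    """Per-case Dice table: predict_fn(case) -> binary mask array."""
    rows = []
    for case in cases:
        pred = np.asarray(predict_fn(case))
        truth = case.mask.data
        res = dice_coefficient(pred, truth)
        size = classify_lesion_size(truth, case.mask.spacing).value
        rows.append({"case_id": case.case_id, "tp": res.tp, "fp": res.fp,
                     "fn": res.fn, "dice": res.dice, "size_class": size})
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> dict:
    """Mean/median Dice overall and stratified by lesion size."""
    out = {
        "n": int(len(table)),
        "mean_dice": float(table["dice"].mean()),
        "median_dice": float(table["dice"].median()),
    }
    for size in ("small", "large"):
        sub = table[table["size_class"] == size]
        if len(sub):
            out[f"mean_dice_{size}"] = float(sub["dice"].mean())
            out[f"n_{size}"] = int(len(sub))
    return out


def cross_study_eval(train_cases, test_cases, pipeline) -> pd.DataFrame:
    """Train on one dataset, evaluate per-case Dice on a disjoint one.

    *pipeline* must provide ``fit(cases)`` and ``predict(case)``.  Overlapping
    case ids raise :class:`LeakageError` before any training happens.
    """
    train_ids = {c.case_id for c in train_cases}
    test_ids = {c.case_id for c in test_cases}
    overlap = train_ids & test_ids
    if overlap:
        raise LeakageError(f"cases in both roles: {sorted(overlap)}")
    pipeline.fit(train_cases)
    return evaluate_cases(test_cases, pipeline.predict)
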