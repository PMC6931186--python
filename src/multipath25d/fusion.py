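"""Combining the nine path predictions into one 3D lesion mask.

Three strategies are provided: voxelwise union, majority vote (at least
ceil(n/2) of an odd number of paths), and a learned 3D convolutional
post-processor.  For the learned fuser, each path's binarized prediction is
stacked with the original input volume, giving an 18-channel 3D tensor at
the canonical grid; the post-processor is a chain of 3x3x3 convolutions with
channel plan 18 -> 36 -> 9 -> 9 -> 2 (padding 1 throughout, ReLU between
layers) ending in a per-voxel softmax whose first channel is the lesion
probability.  Hard masks use the >= 0.5 rule, ties going to lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .volume_io import BrainVolume, LesionMask, VolumeValidationError

#: binarization threshold for soft predictions (ties round up to lesion)
BINARIZE_THRESHOLD = 0.5

N_PATHS = 9


class FusionConfigurationError(ValueError):
    pass


@dataclass
class StackedPathTensor:
    """(2 * n_paths, D, H, W) tensor: 9 binary predictions + 9 image copies.

    Channel layout is ``[pred_0, img, pred_1, img, ...]`` — each path's
    binarized prediction followed by the (unnormalized) primary volume.
    """

    data: np.ndarray
    n_paths: int = N_PATHS

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[0] != 2 * self.n_paths:
            raise VolumeValidationError(
                f"expected ({2 * self.n_paths}, D, H, W) stack, got {self.data.shape}")


@dataclass
class FuserConfig:
    strategy: str = "cnn3d"          # union | majority | cnn3d
    n_paths: int = N_PATHS
    channel_plan: tuple[int, ...] = (36, 9, 9, 2)

    def __post_init__(self) -> None:
        if self.strategy not in ("union", "majority", "cnn3d"):
            raise FusionConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.channel_plan[-1] != 2:
            raise FusionConfigurationError("final fuser output must have 2 channels")


def binarize(soft: np.ndarray, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
    """Round a soft prediction to {0,1}; values >= threshold become lesion."""
    return (np.asarray(soft) >= threshold).astype(np.uint8)


def assemble_stack(preds: list[np.ndarray], vol: BrainVolume) -> StackedPathTensor:
    """Binarize nine soft path volumes and interleave them with the image."""
    if len(preds) != N_PATHS:
        raise VolumeValidationError(f"expected {N_PATHS} predictions, got {len(preds)}")
    img = np.asarray(vol.data, dtype=np.float32)
    channels = []
    for p in preds:
        p = np.asarray(p)
        if p.shape != img.shape:
            raise VolumeValidationError(
                f"prediction shape {p.shape} != volume shape {img.shape}")
        channels.append(binarize(p).astype(np.float32))
        channels.append(img)
    return StackedPathTensor(data=np.stack(channels, axis=0))


def fuse_union(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise OR: lesion wherever at least one path predicts lesion."""
    _check_masks(masks)
    out = np.zeros_like(np.asarray(masks[0]), dtype=np.uint8)
    for m in masks:
        out |= np.asarray(m).astype(np.uint8)
    return out


def fuse_majority(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise majority vote; requires an odd path count (no tie rule)."""
    _check_masks(masks)
    if len(masks) % 2 == 0:
        raise FusionConfigurationError(
            "majority vote needs an odd number of paths (tie rule undefined)")
    votes = np.zeros(np.asarray(masks[0]).shape, dtype=np.int16)
    for m in masks:
        votes += np.asarray(m).astype(np.int16)
    need = len(masks) // 2 + 1
    return (votes >= need).astype(np.uint8)


def _check_masks(masks: list[np.ndarray]) -> None:
    if not masks:
        raise VolumeValidationError("no masks to fuse")
    shape = np.asarray(masks[0]).shape
    for m in masks:
        if np.asarray(m).shape != shape:
            raise VolumeValidationError("mask shapes differ")


class Fusion3DNet(nn.Module):
    """The 3D convolutional post-processor (channel plan 18->36->9->9->2)."""

    def __init__(self, cfg: FuserConfig | None = None, seed: int = 0) -> None:
        super().__init__()
        self.cfg = cfg or FuserConfig()
        rng = np.random.default_rng(seed)
        in_ch = 2 * self.cfg.n_paths
        plan = (in_ch,) + tuple(self.cfg.channel_plan)
        self.convs = [nn.Conv3d(plan[i], plan[i + 1], rng)
                      for i in range(len(plan) - 1)]
        self.relus = [nn.ReLU() for _ in range(len(self.convs) - 1)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 18, D, H, W) -> 2-channel logits of identical spatial shape."""
        if x.shape[1] != 2 * self.cfg.n_paths:
            raise VolumeValidationError(
                f"stack has {x.shape[1]} channels, fuser expects "
                f"{2 * self.cfg.n_paths}")
        for i, conv in enumerate(self.convs):
            x = conv.forward(x)
            if i < len(self.relus):
                x = self.relus[i].forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for i in reversed(range(len(self.convs))):
            if i < len(self.relus):
                g = self.relus[i].backward(g)
            g = self.convs[i].backward(g)
        return g

    def predict_proba(self, stack: StackedPathTensor) -> np.ndarray:
        """Per-voxel lesion probability (D, H, W) for one stacked case."""
        logits = self.forward(stack.data[None].astype(np.float32))
        return nn.softmax_pair(logits, axis=1)[0, 0]


def fuse_cnn3d(stack: StackedPathTensor, net: Fusion3DNet) -> np.ndarray:
    """Run the 3D post-processor and return the soft lesion volume."""
    return net.predict_proba(stack)


def fuse(preds: list[np.ndarray], vol: BrainVolume, strategy: str,
         net: Fusion3DNet | None = None) -> np.ndarray:
    """Dispatch on strategy; returns a hard binary mask array."""
    if strategy == "union":
        return fuse_union([binarize(p) for p in preds])
    if strategy == "majority":
        return fuse_majority([binarize(p) for p in preds])
    if strategy == "cnn3d":
        if net is None:
            raise FusionConfigurationError("cnn3d fusion needs a trained fuser")
        soft = fuse_cnn3d(assemble_stack(preds, vol), net)
        return binarize(soft)
    raise FusionConfigurationError(f"unknown strategy {strategy!r}")


def save_fuser(net: Fusion3DNet, path) -> None:
    import json

    meta = {"n_paths": net.cfg.n_paths, "channel_plan": list(net.cfg.channel_plan)}
    np.savez(path, __meta__=json.dumps(meta), **net.state_dict())


def load_fuser(path) -> Fusion3DNet:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    net = Fusion3DNet(FuserConfig(strategy="cnn3d", n_paths=int(meta["n_paths"]),
                                  channel_plan=tuple(meta["channel_plan"])))
    net.load_state_dict(state)
    return net
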