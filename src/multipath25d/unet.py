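"""The per-path 2D network: dual encoders, multi-scale fusion, one decoder.

Each of the nine paths runs this network on 2D slices.  Two weight-separate
encoders process the primary view and the auxiliary view (the mirrored scan
or a second modality).  At every encoder scale the two 32-channel feature
maps are merged by a 2x1x1 3D fusion kernel, and the decoder upsamples with
2x2-stride-2 transposed convolutions, *adding* the fused skip feature at the
matching scale before a ReLU (addition rather than multiplication keeps
gradients alive when feature values are small).  A 1x1 projection produces a
two-channel output whose softmax pairs a lesion map with its complement.

The encoder has five convolutional blocks but only four pooling steps
(after blocks 1-4): four 2x2 poolings are exactly undone by the decoder's
four doubling deconvolutions, so in-plane dims must divide 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .views import PathInput, PlaneId, restack_slices


class ConfigurationError(ValueError):
    pass


@dataclass
class PathNetConfig:
    """Architecture of one path network.

    ``base_filters`` is the constant channel width at every scale (32 at
    full scale; smaller widths train in minutes on a CPU for phantom work).
    """

    base_filters: int = 32
    encoder_blocks: int = 5
    decoder_blocks: int = 4
    in_plane_shape: tuple[int, int] = (224, 192)

    def __post_init__(self) -> None:
        if self.encoder_blocks != self.decoder_blocks + 1:
            raise ConfigurationError("encoder_blocks must equal decoder_blocks + 1")
        div = 2 ** self.decoder_blocks
        if any(s % div for s in self.in_plane_shape):
            raise ConfigurationError(
                f"in_plane_shape {self.in_plane_shape} must be divisible by {div}")

    def to_dict(self) -> dict:
        return {
            "base_filters": self.base_filters,
            "encoder_blocks": self.encoder_blocks,
            "decoder_blocks": self.decoder_blocks,
            "in_plane_shape": list(self.in_plane_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathNetConfig":
        return cls(base_filters=int(d["base_filters"]),
                   encoder_blocks=int(d["encoder_blocks"]),
                   decoder_blocks=int(d["decoder_blocks"]),
                   in_plane_shape=tuple(d["in_plane_shape"]))


class ConvBlock(nn.Module):
    """3x3 conv (stride 1, pad 1) -> ReLU -> 3x3 conv -> ReLU; dims preserved."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, rng)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, rng)
        self.relu2 = nn.ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu2.forward(self.conv2.forward(
            self.relu1.forward(self.conv1.forward(x))))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.relu2.backward(g))))


class Encoder(nn.Module):
    """Five conv blocks with 2x2 average pooling between them.

    Returns the feature pyramid: block outputs at scales 1, 1/2, 1/4, 1/8,
    1/16, each with ``base_filters`` channels.
    """

    def __init__(self, cfg: PathNetConfig, rng: np.random.Generator,
                 in_ch: int = 1) -> None:
        super().__init__()
        f = cfg.base_filters
        self.blocks = [ConvBlock(in_ch if i == 0 else f, f, rng)
                       for i in range(cfg.encoder_blocks)]
        self.pools = [nn.AvgPool2d() for _ in range(cfg.encoder_blocks - 1)]

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        levels = []
        for i, block in enumerate(self.blocks):
            if i > 0:
                x = self.pools[i - 1].forward(x)
            x = block.forward(x)
            levels.append(x)
        return levels

    def backward(self, dlevels: list[np.ndarray]) -> np.ndarray:
        g = None
        for i in reversed(range(len(self.blocks))):
            g = dlevels[i] if g is None else dlevels[i] + g
            g = self.blocks[i].backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)
        return g


class Decoder(nn.Module):
    """Four deconv-add-ReLU-conv blocks plus the 2-channel 1x1 head."""

    def __init__(self, cfg: PathNetConfig, rng: np.random.Generator) -> None:
        super().__init__()
        f = cfg.base_filters
        nb = cfg.decoder_blocks
        self.deconvs = [nn.ConvTranspose2d(f, f, rng) for _ in range(nb)]
        self.relus = [nn.ReLU() for _ in range(nb)]
        self.blocks = [ConvBlock(f, f, rng) for _ in range(nb)]
        self.head = nn.Conv1x1(f, 2, rng)

    def forward(self, fused: list[np.ndarray]) -> np.ndarray:
        n_levels = len(fused)
        x = fused[-1]
        for i in range(len(self.deconvs)):
            level = n_levels - 2 - i
            x = self.deconvs[i].forward(x)
            if x.shape != fused[level].shape:
                raise ConfigurationError(
                    f"decoder scale mismatch at level {level}: "
                    f"{x.shape} vs skip {fused[level].shape}")
            x = self.relus[i].forward(x + fused[level])
            x = self.blocks[i].forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        n_levels = len(self.deconvs) + 1
        dfused: list[np.ndarray | None] = [None] * n_levels
        g = self.head.backward(dlogits)
        for i in reversed(range(len(self.deconvs))):
            level = n_levels - 2 - i
            g = self.blocks[i].backward(g)
            g = self.relus[i].backward(g)
            dfused[level] = g
            g = self.deconvs[i].backward(g)
        dfused[-1] = g
        return dfused  # type: ignore[return-value]


class DualUNet(nn.Module):
    """The full per-path network, mapping a slice pair to 2-channel logits."""

    def __init__(self, cfg: PathNetConfig, seed: int = 0) -> None:
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.enc_primary = Encoder(cfg, rng)
        self.enc_auxiliary = Encoder(cfg, rng)
        self.fusers = [nn.FuseTwo(cfg.base_filters, rng)
                       for _ in range(cfg.encoder_blocks)]
        self.decoder = Decoder(cfg, rng)

    def forward(self, primary: np.ndarray, auxiliary: np.ndarray) -> np.ndarray:
        """Slice batches ``(n, h, w)`` (or ``(n, 1, h, w)``) -> logits ``(n, 2, h, w)``."""
        primary = self._with_channel(primary)
        auxiliary = self._with_channel(auxiliary)
        if primary.shape[2:] != tuple(self.cfg.in_plane_shape):
            raise ConfigurationError(
                f"slice shape {primary.shape[2:]} != configured "
                f"{tuple(self.cfg.in_plane_shape)}")
        pyr_p = self.enc_primary.forward(primary)
        pyr_a = self.enc_auxiliary.forward(auxiliary)
        fused = [fz.forward(a, b) for fz, a, b in zip(self.fusers, pyr_p, pyr_a)]
        return self.decoder.forward(fused)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.decoder.backward(dlogits)
        dpyr_p, dpyr_a = [], []
        for fz, g in zip(self.fusers, dfused):
            da, db = fz.backward(g)
            dpyr_p.append(da)
            dpyr_a.append(db)
        self.enc_primary.backward(dpyr_p)
        self.enc_auxiliary.backward(dpyr_a)

    def predict_proba(self, primary: np.ndarray, auxiliary: np.ndarray) -> np.ndarray:
        """Softmax lesion probability per pixel, shape ``(n, h, w)``."""
        logits = self.forward(primary, auxiliary)
        return nn.softmax_pair(logits, axis=1)[:, 0]

    @staticmethod
    def _with_channel(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        return x


def path_forward(path_input: PathInput, net: DualUNet,
                 batch_size: int = 16) -> np.ndarray:
    """Run a path network over a whole view and reassemble the soft 3D volume.

    Slices are processed in minibatches; per-slice lesion probabilities are
    restacked along the source axis via ``slice_index_map`` so the output is
    a soft volume in the source volume's geometry, values in [0, 1].
    """
    stack_p = path_input.primary_stack
    stack_a = path_input.auxiliary_stack
    n = stack_p.shape[0]
    probs = np.empty_like(stack_p, dtype=np.float32)
    for lo in range(0, n, batch_size):
        hi = min(lo + batch_size, n)
        probs[lo:hi] = net.predict_proba(stack_p[lo:hi], stack_a[lo:hi])
    ordered = np.empty_like(probs)
    ordered[path_input.slice_index_map] = probs
    return restack_slices(ordered, path_input.plane)


def save_checkpoint(net: DualUNet, path, extra: dict | None = None) -> None:
    """Serialize weights plus a config echo to a single ``.npz`` file."""
    import json

    meta = {"config": net.cfg.to_dict(), **(extra or {})}
    np.savez(path, __meta__=json.dumps(meta), **net.state_dict())


def load_checkpoint(path) -> DualUNet:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    net = DualUNet(PathNetConfig.from_dict(meta["config"]))
    net.load_state_dict(state)
    return net
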