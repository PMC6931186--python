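"""A compact numpy conv-net core with hand-written backpropagation.

Only the operations the segmentation system needs are provided: 3x3 2D
convolution (stride 1, padding 1), 2x2 average pooling, 2x2-stride-2
transposed convolution, the 2x1x1 dual-encoder fusion kernel, 1x1 projection,
3x3x3 3D convolution (padding 1), and ReLU.  Every layer caches what its
backward pass needs during ``forward`` and accumulates parameter gradients in
``grads`` during ``backward``; all math is float32 with float64 reductions
where it matters.

Weight initialization is uniform fan-in scaling, U(-1/sqrt(fan_in),
1/sqrt(fan_in)), drawn from a caller-supplied ``numpy.random.Generator`` so
runs are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np


class Module:
    """Base class: parameter bookkeeping and (de)serialization."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    # -- recursion over child modules -------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for key, val in vars(self).items():
            if key in ("params", "grads"):
                continue
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{prefix}{key}.{i}.")

    def named_parameters(self):
        for mpath, mod in self.named_modules():
            for pname in mod.params:
                yield f"{mpath}{pname}", mod, pname

    def zero_grad(self) -> None:
        for _, mod, pname in self.named_parameters():
            mod.grads[pname] = np.zeros_like(mod.params[pname])

    def n_parameters(self) -> int:
        return sum(p.size for _, m, n in self.named_parameters()
                   for p in (m.params[n],))

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {path: mod.params[name].copy()
                for path, mod, name in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {path: (mod, name) for path, mod, name in self.named_parameters()}
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} "
                             f"unexpected={sorted(extra)}")
        for path, arr in state.items():
            mod, name = own[path]
            if mod.params[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {path}: "
                                 f"{mod.params[name].shape} vs {arr.shape}")
            mod.params[name] = np.asarray(arr, dtype=np.float32).copy()


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    # Kaiming-style uniform fan-in scaling: variance 2/fan_in, which keeps
    # activation magnitudes stable through ReLU stacks (there are no
    # normalization layers anywhere in this system).
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """3x3 convolution, stride 1, padding 1: output spatial dims equal input."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.params["weight"] = _fan_in_uniform(rng, (out_ch, in_ch, kernel, kernel),
                                                fan_in)
        self.params["bias"] = _fan_in_uniform(rng, (out_ch,), fan_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k)
        wmat = self.params["weight"].reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.params["bias"]
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.pad
        gmat = np.ascontiguousarray(gout.transpose(0, 2, 3, 1)).reshape(n * h * w,
                                                                        self.out_ch)
        wmat = self.params["weight"].reshape(self.out_ch, -1)
        self.grads["weight"] = self.grads.get("weight", 0) + (
            gmat.T @ cols).reshape(self.params["weight"].shape)
        self.grads["bias"] = self.grads.get("bias", 0) + gmat.sum(axis=0)
        dcols = (gmat @ wmat).reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, :, :, di, dj]
        return dxp[:, :, p:p + h, p:p + w]


class Conv1x1(Module):
    """Pointwise projection, used as the 2-channel output head."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["weight"] = _fan_in_uniform(rng, (out_ch, in_ch), in_ch)
        self.params["bias"] = _fan_in_uniform(rng, (out_ch,), in_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = np.einsum("oc,nchw->nohw", self.params["weight"], x, optimize=True)
        return out + self.params["bias"][None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.grads["weight"] = self.grads.get("weight", 0) + np.einsum(
            "nohw,nchw->oc", gout, self._x, optimize=True)
        self.grads["bias"] = self.grads.get("bias", 0) + gout.sum(axis=(0, 2, 3))
        return np.einsum("oc,nohw->nchw", self.params["weight"], gout, optimize=True)


class AvgPool2d(Module):
    """2x2 average pooling with stride 2: halves both spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even to pool, got {(h, w)}")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = np.broadcast_to(gout[:, :, :, None, :, None] / 4.0,
                            (n, c, h // 2, 2, w // 2, 2))
        return g.reshape(n, c, h, w).astype(np.float32)


class ConvTranspose2d(Module):
    """2x2 transposed convolution with stride 2: doubles both spatial dims."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["weight"] = _fan_in_uniform(rng, (in_ch, out_ch, 2, 2), in_ch)
        self.params["bias"] = _fan_in_uniform(rng, (out_ch,), in_ch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, c, h, w = x.shape
        out6 = np.einsum("ncij,coab->noiajb", x, self.params["weight"], optimize=True)
        out = out6.reshape(n, self.out_ch, 2 * h, 2 * w)
        return out + self.params["bias"][None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        g6 = gout.reshape(n, self.out_ch, h, 2, w, 2)
        self.grads["weight"] = self.grads.get("weight", 0) + np.einsum(
            "ncij,noiajb->coab", x, g6, optimize=True)
        self.grads["bias"] = self.grads.get("bias", 0) + gout.sum(axis=(0, 2, 3))
        return np.einsum("noiajb,coab->ncij", g6, self.params["weight"],
                         optimize=True)


class FuseTwo(Module):
    """The 2x1x1 3D fusion kernel merging two same-shape feature maps.

    The pair (a, b) is stacked along a depth-2 axis and convolved with a
    (2, 1, 1) kernel over ``channels`` input channels, producing a depth-1 map
    that is squeezed back to 2D feature-map shape.  Equivalently::

        out[o] = sum_c  W[o, c, 0] * a[c] + W[o, c, 1] * b[c]  + bias[o]
    """

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.channels = channels
        fan_in = channels * 2
        self.params["weight"] = _fan_in_uniform(rng, (channels, channels, 2), fan_in)
        self.params["bias"] = _fan_in_uniform(rng, (channels,), fan_in)

    def set_mean_weights(self) -> None:
        """Identity-routed averaging: out = (a + b) / 2 (useful for tests)."""
        w = np.zeros_like(self.params["weight"])
        idx = np.arange(self.channels)
        w[idx, idx, 0] = 0.5
        w[idx, idx, 1] = 0.5
        self.params["weight"] = w
        self.params["bias"] = np.zeros_like(self.params["bias"])

    def forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if a.shape != b.shape:
            raise ValueError(f"fusion inputs differ in shape: {a.shape} vs {b.shape}")
        self._ab = (a, b)
        w = self.params["weight"]
        out = np.einsum("oc,nchw->nohw", w[:, :, 0], a, optimize=True)
        out += np.einsum("oc,nchw->nohw", w[:, :, 1], b, optimize=True)
        return out + self.params["bias"][None, :, None, None]

    def backward(self, gout: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, b = self._ab
        w = self.params["weight"]
        gw = np.stack([
            np.einsum("nohw,nchw->oc", gout, a, optimize=True),
            np.einsum("nohw,nchw->oc", gout, b, optimize=True),
        ], axis=2)
        self.grads["weight"] = self.grads.get("weight", 0) + gw
        self.grads["bias"] = self.grads.get("bias", 0) + gout.sum(axis=(0, 2, 3))
        da = np.einsum("oc,nohw->nchw", w[:, :, 0], gout, optimize=True)
        db = np.einsum("oc,nohw->nchw", w[:, :, 1], gout, optimize=True)
        return da, db


class Conv3d(Module):
    """3x3x3 3D convolution, stride 1, padding 1 (spatial dims preserved).

    Implemented by shift-and-accumulate over the 27 kernel offsets so no
    27-fold im2col copy of a full 3D volume is ever materialized.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * 27
        self.params["weight"] = _fan_in_uniform(rng, (out_ch, in_ch, 3, 3, 3), fan_in)
        self.params["bias"] = _fan_in_uniform(rng, (out_ch,), fan_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp = xp
        self._xshape = x.shape
        wgt = self.params["weight"]
        out = np.zeros((n, self.out_ch, d, h, w), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = xp[:, :, i:i + d, j:j + h, k:k + w]
                    out += np.einsum("oc,ncdhw->nodhw", wgt[:, :, i, j, k], xs,
                                     optimize=True)
        return out + self.params["bias"][None, :, None, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, c, d, h, w = self._xshape
        wgt = self.params["weight"]
        gw = np.zeros_like(wgt)
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    xs = xp[:, :, i:i + d, j:j + h, k:k + w]
                    gw[:, :, i, j, k] = np.einsum("nodhw,ncdhw->oc", gout, xs,
                                                  optimize=True)
                    dxp[:, :, i:i + d, j:j + h, k:k + w] += np.einsum(
                        "oc,nodhw->ncdhw", wgt[:, :, i, j, k], gout, optimize=True)
        self.grads["weight"] = self.grads.get("weight", 0) + gw
        self.grads["bias"] = self.grads.get("bias", 0) + gout.sum(
            axis=(0, 2, 3, 4))
        return dxp[:, :, 1:1 + d, 1:1 + h, 1:1 + w]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0).astype(np.float32)


def softmax_pair(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax over a 2-entry channel axis."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
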