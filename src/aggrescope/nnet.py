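"""A small encoder-decoder segmentation network in pure numpy.

The architecture follows the tile-segmentation recipe: 3x3 convolutions
alternated with 2x2 max-pool layers, doubling the channel depth while
halving the resolution; leaky rectified linear units after each
convolution; convolutional up-sampling (nearest-neighbor x2 followed by
convolution, with skip concatenation) back to the original resolution; a
final tanh squashing.  Outputs are mapped to probabilities via
``(tanh + 1)/2`` and trained with mean squared error against binary
(mask, outline) targets.  Optimization is Adam with a geometrically
decaying learning rate.

Implemented directly on numpy arrays (NCHW layout) with explicit
backpropagation; batch sizes and tile sizes here are small enough that
im2col matmuls on a single CPU are adequate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelConfig", "TrainSchedule", "UNet"]

LEAKY_SLOPE = 0.1


@dataclass
class ModelConfig:
    depth: int = 3
    base_channels: int = 8
    in_channels: int = 1
    out_channels: int = 2  # (mask, outline)

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
        }


@dataclass
class TrainSchedule:
    """Training contract: fixed iteration budget with periodic validation.

    Validation runs exactly at iterations divisible by ``validate_every``
    (the default budget of 2200 with validation every 100th iteration gives
    22 validation entries).
    """

    max_iterations: int = 2200
    validate_every: int = 100
    learning_rate: float = 3e-4
    lr_decay: float = 0.999  # multiplicative decay per iteration
    warmup_iterations: int = 50  # linear ramp from 0; avoids early tanh saturation
    batch_size: int = 4
    # Init selection: the tanh output saturates irrecoverably for some weight
    # initializations (an absorbing all-background state), so up to
    # init_candidates seeds are probed for probe_iterations each and the
    # first whose loss beats the constant-predictor baseline is trained for
    # the full budget.  Deterministic given the training seed.
    init_candidates: int = 6
    probe_iterations: int = 150

    def lr_at(self, iteration: int) -> float:
        """Learning rate at a 1-based iteration: warmup ramp then decay."""
        ramp = min(1.0, iteration / max(self.warmup_iterations, 1))
        return self.learning_rate * ramp * self.lr_decay**iteration


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Same-padding stride-1 correlation, NCHW x (out, in, k, k)."""
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
    out = np.einsum("nchwij,ocij->nohw", cols, w, optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    return out


class _Conv:
    """3x3 (or 1x1) convolution with bias; leaky-ReLU handled by the net."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        # He-style init scaled for the leaky unit
        scale = np.sqrt(2.0 / (cin * k * k * (1 + LEAKY_SLOPE**2)))
        self.w = rng.normal(0.0, scale, size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return _conv2d(x, self.w, self.b)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self.x
        k = self.w.shape[2]
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))
        self.dw = np.einsum("nohw,nchwij->ocij", dout, cols, optimize=True)
        self.db = dout.sum(axis=(0, 2, 3))
        # dx = full correlation of dout with the spatially flipped, transposed kernel
        w_rot = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _conv2d(dout, w_rot, None)

    @property
    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class _LeakyReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return np.where(self.mask, x, LEAKY_SLOPE * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self.mask, dout, LEAKY_SLOPE * dout)


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self.argmax = xr.argmax(axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(xr, self.argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self.in_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self.argmax[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class _Upsample2:
    """Nearest-neighbor x2; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Encoder-decoder with skip concatenation; see module docstring."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d, b = cfg.depth, cfg.base_channels
        self.enc_convs: list[_Conv] = []
        cin = cfg.in_channels
        for i in range(d):
            cout = b * 2**i
            self.enc_convs.append(_Conv(cin, cout, 3, rng))
            cin = cout
        self.bottleneck = _Conv(cin, b * 2**d, 3, rng)
        self.dec_up_convs: list[_Conv] = []
        self.dec_merge_convs: list[_Conv] = []
        ch = b * 2**d
        for i in reversed(range(d)):
            ci = b * 2**i
            self.dec_up_convs.append(_Conv(ch, ci, 3, rng))
            self.dec_merge_convs.append(_Conv(2 * ci, ci, 3, rng))
            ch = ci
        self.head = _Conv(b, cfg.out_channels, 1, rng)
        self._adam_state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability maps in [0, 1], shape (n, out_channels, h, w)."""
        d = self.cfg.depth
        if x.shape[2] % 2**d or x.shape[3] % 2**d:
            raise ValueError(
                f"tile size {x.shape[2:]} must be divisible by 2**depth = {2**d}"
            )
        self._acts = []
        skips = []
        self._enc_relus, self._pools = [], []
        h = x
        for conv in self.enc_convs:
            relu = _LeakyReLU()
            h = relu.forward(conv.forward(h))
            self._enc_relus.append(relu)
            skips.append(h)
            pool = _MaxPool2()
            h = pool.forward(h)
            self._pools.append(pool)
        self._bottleneck_relu = _LeakyReLU()
        h = self._bottleneck_relu.forward(self.bottleneck.forward(h))
        self._ups, self._dec_relus, self._split_sizes = [], [], []
        for up_conv, merge_conv, skip in zip(
            self.dec_up_convs, self.dec_merge_convs, reversed(skips)
        ):
            up = _Upsample2()
            h = up.forward(h)
            self._ups.append(up)
            r1 = _LeakyReLU()
            h = r1.forward(up_conv.forward(h))
            self._split_sizes.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            r2 = _LeakyReLU()
            h = r2.forward(merge_conv.forward(h))
            self._dec_relus.append((r1, r2))
        z = self.head.forward(h)
        self._tanh = np.tanh(z)
        return (self._tanh + 1.0) / 2.0

    # Binary targets are softened into the open interval so the MSE optimum
    # sits at finite z: exact {0, 1} targets put the optimum at tanh = +/-1
    # (z infinite), and early optimizer steps then saturate the unit and kill
    # its gradient for good.
    TARGET_EPS = 0.05

    def loss_and_backward(self, prob: np.ndarray, target: np.ndarray) -> float:
        """MSE between probabilities and (softened) binary targets."""
        target = target * (1 - 2 * self.TARGET_EPS) + self.TARGET_EPS
        diff = prob - target
        loss = float(np.mean(diff**2))
        # d loss / d z through (tanh(z)+1)/2
        dz = (2.0 * diff / diff.size) * 0.5 * (1.0 - self._tanh**2)
        dh = self.head.backward(dz)
        dskips = [None] * self.cfg.depth
        for level in reversed(range(self.cfg.depth)):
            r1, r2 = self._dec_relus[level]
            dh = self.dec_merge_convs[level].backward(r2.backward(dh))
            c = self._split_sizes[level]
            dh, dskip = dh[:, :c], dh[:, c:]
            dskips[self.cfg.depth - 1 - level] = dskip
            dh = self.dec_up_convs[level].backward(r1.backward(dh))
            dh = self._ups[level].backward(dh)
        dh = self.bottleneck.backward(self._bottleneck_relu.backward(dh))
        for level in reversed(range(self.cfg.depth)):
            dh = self._pools[level].backward(dh)
            dh = dh + dskips[level]
            dh = self.enc_convs[level].backward(self._enc_relus[level].backward(dh))
        return loss

    def loss(self, prob: np.ndarray, target: np.ndarray) -> float:
        return float(np.mean((prob - target) ** 2))

    # -- optimization ------------------------------------------------------

    def _layers(self):
        return (
            self.enc_convs
            + [self.bottleneck]
            + self.dec_up_convs
            + self.dec_merge_convs
            + [self.head]
        )

    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.99,
                  eps: float = 1e-8) -> None:
        # beta2 = 0.99 lets the second moment forget the large warm-up
        # gradients within ~100 iterations; with the default 0.999 the early
        # transient suppresses steps for most of a short training budget.
        self._adam_t += 1
        t = self._adam_t
        for layer in self._layers():
            for name, p, g in layer.params:
                key = id(p)
                if key not in self._adam_state:
                    self._adam_state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._adam_state[key]
                m[...] = beta1 * m + (1 - beta1) * g
                v[...] = beta2 * v + (1 - beta2) * g**2
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            out[f"w{i}"] = layer.w
            out[f"b{i}"] = layer.b
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._layers()):
            layer.w[...] = arrays[f"w{i}"]
            layer.b[...] = arrays[f"b{i}"]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump({"model_cfg": self.cfg.to_dict()}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "UNet":
        path = Path(path)
        with open(path.with_suffix(".json"), encoding="utf-8") as fh:
            doc = json.load(fh)
        net = cls(ModelConfig(**doc["model_cfg"]))
        with np.load(path.with_suffix(".npz")) as data:
            net.load_state_arrays(dict(data))
        return net
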