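"""Three-layer convolutional super-resolution engine with momentum SGD.

The network maps a bicubic-interpolated LR image Y straight to the HR image:

    F1(Y) = relu(W1 * Y + B1)      n1 filters, f1 x f1   (patch extraction)
    F2(Y) = relu(W2 * F1 + B2)     n2 filters, f2 x f2   (non-linear mapping)
    F3(Y) = W3 * F2 + B3           1 filter,  f3 x f3    (reconstruction)

'*' is cross-correlation with 'same'-size replicate padding, so one output
pixel depends on an (f1 + f2 + f3 - 2)^2 input neighborhood — 49 pixels at
the default (5, 1, 3) geometry.  Training minimizes the mean squared error
between F3(Y_i) and the HR target X_i over the library (full-batch), with the
momentum update

    v <- momentum * v - eta * dL/dtheta,      theta <- theta + v.

A border of width (f1 + f2 + f3 - 3) / 2 (3 px by default) is excluded from
the loss so replicate-padding artifacts do not bias the fit.  Filters are
initialized from N(0, init_sigma^2) with zero biases.  The default scale
(0.05) is matched to the data so full-batch training escapes the near-zero
saddle within a few hundred iterations; initialization scales of ~1e-3, as
used with very long stochastic schedules, leave plain momentum SGD pinned to
a constant-output plateau for thousands of iterations (see docs/methods.md).
Everything is plain float64 numpy, backpropagation included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .imgcore import as_gray
from .resample import ResampleConfig, TrainingPair, upsample_bicubic

__all__ = [
    "CnnConfig",
    "CnnModel",
    "conv_forward",
    "train_cnn",
    "apply_cnnsr",
    "save_cnn",
    "load_cnn",
]


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training configuration of the convolutional engine."""

    n1: int = 64
    n2: int = 32
    f1: int = 5
    f2: int = 1
    f3: int = 3
    eta: float = 0.1
    momentum: float = 0.9
    iters: int = 2000
    seed: int = 0
    t: int = 4
    init_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.f1 % 2 == 0 or self.f3 % 2 == 0:
            raise ValueError("f1 and f3 must be odd for centered filters")
        if min(self.n1, self.n2) < 1:
            raise ValueError("filter counts must be >= 1")
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def receptive_field(self) -> int:
        """Side of the input neighborhood one output pixel depends on."""
        return self.f1 + self.f2 + self.f3 - 2

    @property
    def loss_border(self) -> int:
        """Pixels excluded from each image edge when evaluating the loss."""
        return (self.f1 + self.f2 + self.f3 - 3) // 2


@dataclass
class CnnModel:
    W1: np.ndarray  # (n1, 1, f1, f1)
    B1: np.ndarray  # (n1,)
    W2: np.ndarray  # (n2, n1, f2, f2)
    B2: np.ndarray  # (n2,)
    W3: np.ndarray  # (1, n2, f3, f3)
    B3: np.ndarray  # (1,)
    config: CnnConfig
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def conv_forward(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, *, relu: bool = False
) -> np.ndarray:
    """'Same'-size multi-channel cross-correlation with replicate padding.

    ``x`` is (C, H, W); ``W`` is (O, C, f, f); returns (O, H, W).
    """
    x = np.asarray(x, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if x.ndim != 3 or W.ndim != 4:
        raise ValueError(f"expected x (C,H,W) and W (O,C,f,f); got {x.shape}, {W.shape}")
    if x.shape[0] != W.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[0]} channels, filters expect {W.shape[1]}"
        )
    f = W.shape[2]
    pad = f // 2
    if pad:
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), mode="edge")
    else:
        xp = x
    if f == 1:
        out = np.einsum("oc,chw->ohw", W[:, :, 0, 0], x)
    else:
        patches = np.lib.stride_tricks.sliding_window_view(xp, (f, f), axis=(1, 2))
        out = np.tensordot(W, patches, axes=([1, 2, 3], [0, 3, 4]))
    out += np.asarray(b, dtype=np.float64)[:, None, None]
    if relu:
        np.maximum(out, 0.0, out=out)
    return out


def _conv_backward(
    dout: np.ndarray, x: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-size replicate-padded cross-correlation.

    Returns (dW, db, dx).  The replicate padding is folded back: gradient
    that landed on padded rows/columns is accumulated onto the edge pixels
    they replicate.
    """
    O, C, f, _ = W.shape
    _, H, Wd = x.shape
    pad = f // 2
    db = dout.sum(axis=(1, 2))
    if f == 1:
        dW = np.einsum("ohw,chw->oc", dout, x)[:, :, None, None]
        dx = np.einsum("oc,ohw->chw", W[:, :, 0, 0], dout)
        return dW, db, dx
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), mode="edge")
    patches = np.lib.stride_tricks.sliding_window_view(xp, (f, f), axis=(1, 2))
    dW = np.tensordot(dout, patches, axes=([1, 2], [1, 2]))  # (O, C, f, f)
    dxp = np.zeros_like(xp)
    for i in range(f):
        for j in range(f):
            dxp[:, i : i + H, j : j + Wd] += np.einsum(
                "oc,ohw->chw", W[:, :, i, j], dout
            )
    # fold padding gradient back onto the replicated edge pixels
    dxp[:, pad, :] += dxp[:, :pad, :].sum(axis=1)
    dxp[:, H + pad - 1, :] += dxp[:, H + pad :, :].sum(axis=1)
    dxp[:, :, pad] += dxp[:, :, :pad].sum(axis=2)
    dxp[:, :, Wd + pad - 1] += dxp[:, :, Wd + pad :].sum(axis=2)
    return dW, db, dxp[:, pad : H + pad, pad : Wd + pad]


def _forward(y: np.ndarray, m: CnnModel) -> tuple[np.ndarray, dict]:
    x0 = y[None]
    a1 = conv_forward(x0, m.W1, m.B1)
    f1 = np.maximum(a1, 0.0)
    a2 = conv_forward(f1, m.W2, m.B2)
    f2 = np.maximum(a2, 0.0)
    a3 = conv_forward(f2, m.W3, m.B3)
    return a3[0], {"x0": x0, "a1": a1, "f1": f1, "a2": a2, "f2": f2}


def _backward(dout: np.ndarray, m: CnnModel, cache: dict) -> dict:
    dW3, dB3, df2 = _conv_backward(dout[None], cache["f2"], m.W3)
    da2 = df2 * (cache["a2"] > 0)
    dW2, dB2, df1 = _conv_backward(da2, cache["f1"], m.W2)
    da1 = df1 * (cache["a1"] > 0)
    dW1, dB1, _ = _conv_backward(da1, cache["x0"], m.W1)
    return {"W1": dW1, "B1": dB1, "W2": dW2, "B2": dB2, "W3": dW3, "B3": dB3}


def _init_model(cfg: CnnConfig) -> CnnModel:
    rng = np.random.default_rng(cfg.seed)
    s = cfg.init_sigma
    return CnnModel(
        W1=rng.normal(0.0, s, (cfg.n1, 1, cfg.f1, cfg.f1)),
        B1=np.zeros(cfg.n1),
        W2=rng.normal(0.0, s, (cfg.n2, cfg.n1, cfg.f2, cfg.f2)),
        B2=np.zeros(cfg.n2),
        W3=rng.normal(0.0, s, (1, cfg.n2, cfg.f3, cfg.f3)),
        B3=np.zeros(1),
        config=cfg,
    )


def _loss_and_grads(
    m: CnnModel, inputs: list[np.ndarray], targets: list[np.ndarray], border: int
) -> tuple[float, dict]:
    """Mean squared error over the border-masked region, plus its gradients."""
    n = len(inputs)
    grads = {k: 0.0 for k in ("W1", "B1", "W2", "B2", "W3", "B3")}
    loss = 0.0
    for y, x in zip(inputs, targets):
        out, cache = _forward(y, m)
        diff = np.zeros_like(out)
        sl = (slice(border, out.shape[0] - border), slice(border, out.shape[1] - border))
        diff[sl] = out[sl] - x[sl]
        npix = (out.shape[0] - 2 * border) * (out.shape[1] - 2 * border)
        loss += np.sum(diff[sl] ** 2) / npix
        g = _backward(2.0 * diff / (npix * n), m, cache)
        for k in grads:
            grads[k] = grads[k] + g[k]
    return loss / n, grads


def train_cnn(pairs: Sequence[TrainingPair], cfg: CnnConfig = CnnConfig()) -> CnnModel:
    """Train the three-layer network on (lr_int, hr) pairs with momentum SGD.

    The whole library forms one deterministic batch per iteration (the images
    are small), and the per-iteration masked MSE is recorded in
    ``loss_history``.  Training aborts with a diagnostic if the loss stays
    above 10x its initial value for 100 consecutive iterations.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    inputs = [as_gray(p.lr_int, allow_signed=True) for p in pairs]
    targets = [as_gray(p.hr) for p in pairs]
    for y, x in zip(inputs, targets):
        if y.shape != x.shape:
            raise ValueError(f"lr_int/hr shape mismatch: {y.shape} vs {x.shape}")
    m = _init_model(cfg)
    border = cfg.loss_border
    vel = {
        "W1": np.zeros_like(m.W1),
        "B1": np.zeros_like(m.B1),
        "W2": np.zeros_like(m.W2),
        "B2": np.zeros_like(m.B2),
        "W3": np.zeros_like(m.W3),
        "B3": np.zeros_like(m.B3),
    }
    history = np.empty(cfg.iters)
    initial = None
    bad_streak = 0
    for it in range(cfg.iters):
        loss, grads = _loss_and_grads(m, inputs, targets, border)
        history[it] = loss
        if initial is None:
            initial = loss
        if loss > 10.0 * initial:
            bad_streak += 1
            if bad_streak >= 100:
                raise RuntimeError(
                    f"training diverged (loss {loss:.3g} > 10x initial "
                    f"{initial:.3g} for 100 iterations); try a smaller eta"
                )
        else:
            bad_streak = 0
        for k in vel:
            vel[k] = cfg.momentum * vel[k] - cfg.eta * grads[k]
            cur = getattr(m, k)
            setattr(m, k, cur + vel[k])
    m.loss_history = history
    return m


def apply_cnnsr(lr: np.ndarray, model: CnnModel) -> np.ndarray:
    """Super-resolve one LR image: bicubic upsample, forward pass, clamp."""
    lr = as_gray(lr)
    y = upsample_bicubic(lr, ResampleConfig(t=model.config.t))
    out, _ = _forward(y, model)
    return np.clip(out, 0.0, 1.0)


def save_cnn(model: CnnModel, path: str | Path) -> None:
    """Persist filters, biases and the loss history as an HDF5 container."""
    c = model.config
    with h5py.File(path, "w") as f:
        for name in ("W1", "B1", "W2", "B2", "W3", "B3"):
            f.create_dataset(name, data=getattr(model, name))
        f.create_dataset("loss_history", data=model.loss_history)
        f.attrs.update(
            {
                "engine": "cnn",
                "n1": c.n1, "n2": c.n2, "f1": c.f1, "f2": c.f2, "f3": c.f3,
                "t": c.t, "eta": c.eta, "momentum": c.momentum,
                "iters": c.iters, "seed": c.seed, "init_sigma": c.init_sigma,
                "version": 1,
            }
        )


def load_cnn(path: str | Path) -> CnnModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("engine") != "cnn":
            raise ValueError(f"{path} is not a CNN model file")
        cfg = CnnConfig(
            n1=int(f.attrs["n1"]), n2=int(f.attrs["n2"]),
            f1=int(f.attrs["f1"]), f2=int(f.attrs["f2"]), f3=int(f.attrs["f3"]),
            eta=float(f.attrs["eta"]), momentum=float(f.attrs["momentum"]),
            iters=int(f.attrs["iters"]), seed=int(f.attrs["seed"]),
            t=int(f.attrs["t"]), init_sigma=float(f.attrs["init_sigma"]),
        )
        return CnnModel(
            W1=f["W1"][...], B1=f["B1"][...],
            W2=f["W2"][...], B2=f["B2"][...],
            W3=f["W3"][...], B3=f["B3"][...],
            config=cfg,
            loss_history=f["loss_history"][...],
        )
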