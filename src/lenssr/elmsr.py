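"""Random-feature (extreme learning machine) super-resolution engine.

A single-hidden-layer network maps a 14-dimensional local feature vector of
the bicubic-interpolated LR image to the high-frequency residual at the patch
center.  The input weights ``A`` and biases ``B`` are random and fixed; only
the output weights ``beta`` are learned, in closed form, by ridge regression:

    beta = T H(X)^T (I / C + H(X) H(X)^T)^{-1},      H(X) = sigmoid(A X + B)

where ``X`` stacks one feature column per interior pixel of every training
image's ``lr_int`` and ``T`` holds the residual ``hf`` at the same pixels.
``C`` trades training error against ``||beta||``.

Feature vector per 3x3 patch (centers span the interior, so an M x N image
contributes (M-2)(N-2) columns — 46 x 46 = 2116 for M = N = 48):

    rows 0-8   the nine patch intensities in raster order
    row  9     dP/dx   central difference (E - W) / 2
    row 10     dP/dy   central difference (S - N) / 2
    row 11     d2P/dx2 second difference  E - 2P + W
    row 12     d2P/dy2 second difference  S - 2P + N
    row 13     d2P/dxdy four-corner mixed difference (SE - SW - NE + NW) / 4

At test time the recovered residual is added back onto the interpolation,
``hr' = clip(lr_int' + beta H(X'), 0, 1)``; border pixels, which have no
centered patch, fall back to plain bicubic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .imgcore import as_gray
from .resample import ResampleConfig, TrainingPair, upsample_bicubic

__all__ = [
    "ElmConfig",
    "ElmModel",
    "FeatureMatrix",
    "extract_features",
    "train_elm",
    "apply_elmsr",
    "save_elm",
    "load_elm",
]

#: patch intensities + 5 derivative features
FEATURE_DIM = 14


@dataclass(frozen=True)
class ElmConfig:
    """Hyperparameters of the ELM engine.

    L : hidden-node count.
    C : ridge tuning parameter (larger C -> less regularization).
    t : magnification factor.
    seed : seed for the random input weights/biases.
    normalize_features : optionally standardize feature rows before the
        hidden layer (off by default; intensities and derivatives are fed
        at their natural scales).
    """

    L: int = 20
    C: float = 512.0
    t: int = 4
    seed: int = 0
    normalize_features: bool = False
    d: int = FEATURE_DIM

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"hidden node count L must be >= 1, got {self.L}")
        if self.C <= 0:
            raise ValueError(f"ridge parameter C must be > 0, got {self.C}")
        if self.d != FEATURE_DIM:
            raise ValueError(f"feature dimensionality is fixed at {FEATURE_DIM}")


@dataclass
class ElmModel:
    """Trained ELM: random hidden layer (A, B) plus ridge output weights."""

    A: np.ndarray  # (L, d) input weights
    B: np.ndarray  # (L,) hidden biases
    beta: np.ndarray  # (L,) output weights
    config: ElmConfig
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    training_mse: float = float("nan")


@dataclass
class FeatureMatrix:
    """Per-patch feature columns plus the (row, col) center of each column."""

    X: np.ndarray  # (14, n_patches)
    centers: np.ndarray  # (n_patches, 2) int, raster order
    image_shape: tuple[int, int]


def extract_features(img: np.ndarray) -> FeatureMatrix:
    """Extract the 14-feature column for every interior 3x3 patch center.

    Columns follow a raster scan of the centers; raises for images smaller
    than 3x3.
    """
    a = as_gray(img, allow_signed=True)
    h, w = a.shape
    if h < 3 or w < 3:
        raise ValueError(f"image {a.shape} too small for 3x3 patch extraction")
    win = np.lib.stride_tricks.sliding_window_view(a, (3, 3))  # (h-2, w-2, 3, 3)
    nh, nw = h - 2, w - 2
    n = nh * nw
    X = np.empty((FEATURE_DIM, n))
    X[:9] = win.reshape(n, 9).T
    nw_, n_, ne = win[..., 0, 0], win[..., 0, 1], win[..., 0, 2]
    w_, p, e = win[..., 1, 0], win[..., 1, 1], win[..., 1, 2]
    sw, s, se = win[..., 2, 0], win[..., 2, 1], win[..., 2, 2]
    X[9] = ((e - w_) / 2.0).ravel()
    X[10] = ((s - n_) / 2.0).ravel()
    X[11] = (e - 2.0 * p + w_).ravel()
    X[12] = (s - 2.0 * p + n_).ravel()
    X[13] = ((se - sw - ne + nw_) / 4.0).ravel()
    rows, cols = np.mgrid[1 : h - 1, 1 : w - 1]
    centers = np.column_stack([rows.ravel(), cols.ravel()])
    return FeatureMatrix(X=X, centers=centers, image_shape=(h, w))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _hidden(model_A: np.ndarray, model_B: np.ndarray, X: np.ndarray) -> np.ndarray:
    return _sigmoid(model_A @ X + model_B[:, None])


def train_elm(pairs: Sequence[TrainingPair], cfg: ElmConfig = ElmConfig()) -> ElmModel:
    """Fit the ridge output weights on the interior pixels of all pairs.

    ``X`` collects feature columns from every pair's ``lr_int``; ``T`` holds
    the matching ``hf`` values.  ``A ~ U(-1, 1)`` and ``B ~ U(0, 1)`` are
    drawn once from ``cfg.seed``.  A degenerate (constant-image) library
    still yields a defined ``beta`` thanks to the ridge term.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    hr_shape = pairs[0].hr.shape
    for p in pairs:
        if p.hr.shape != hr_shape:
            raise ValueError(
                f"all training pairs must share the HR size; got {p.hr.shape} "
                f"and {hr_shape}"
            )
        if p.hr.shape[0] != p.lr.shape[0] * cfg.t:
            raise ValueError(
                f"pair HR/LR sizes {p.hr.shape}/{p.lr.shape} inconsistent with t={cfg.t}"
            )
    X = np.concatenate([extract_features(p.lr_int).X for p in pairs], axis=1)
    T = np.concatenate([p.hf[1:-1, 1:-1].ravel() for p in pairs])

    mean = scale = None
    if cfg.normalize_features:
        mean = X.mean(axis=1)
        scale = X.std(axis=1)
        scale[scale < 1e-12] = 1.0
        X = (X - mean[:, None]) / scale[:, None]

    rng = np.random.default_rng(cfg.seed)
    A = rng.uniform(-1.0, 1.0, size=(cfg.L, cfg.d))
    B = rng.uniform(0.0, 1.0, size=cfg.L)
    H = _hidden(A, B, X)
    gram = H @ H.T
    gram[np.diag_indices_from(gram)] += 1.0 / cfg.C
    beta = np.linalg.solve(gram, H @ T)  # symmetric system: beta = T H^T (I/C + H H^T)^-1
    mse = float(np.mean((beta @ H - T) ** 2))
    return ElmModel(
        A=A, B=B, beta=beta, config=cfg,
        feature_mean=mean, feature_scale=scale, training_mse=mse,
    )


def apply_elmsr(lr: np.ndarray, model: ElmModel) -> np.ndarray:
    """Recover an HR image from one LR cell image with a trained ELM.

    The LR input is bicubic-upsampled by ``t``, the learned residual is added
    at every interior pixel, and the result is clamped to ``[0, 1]``.
    """
    lr = as_gray(lr)
    if lr.shape[0] < 3 or lr.shape[1] < 3:
        raise ValueError(f"LR input {lr.shape} too small (need >= 3x3)")
    cfg = model.config
    lr_int = upsample_bicubic(lr, ResampleConfig(t=cfg.t))
    feats = extract_features(lr_int)
    X = feats.X
    if model.feature_mean is not None:
        X = (X - model.feature_mean[:, None]) / model.feature_scale[:, None]
    hf = np.zeros(lr_int.shape)
    interior = (model.beta @ _hidden(model.A, model.B, X)).reshape(
        lr_int.shape[0] - 2, lr_int.shape[1] - 2
    )
    hf[1:-1, 1:-1] = interior
    return np.clip(lr_int + hf, 0.0, 1.0)


def save_elm(model: ElmModel, path: str | Path) -> None:
    """Persist a model as an HDF5 container (datasets A, B, beta + attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=model.A)
        f.create_dataset("B", data=model.B)
        f.create_dataset("beta", data=model.beta)
        if model.feature_mean is not None:
            f.create_dataset("feature_mean", data=model.feature_mean)
            f.create_dataset("feature_scale", data=model.feature_scale)
        f.attrs.update(
            {
                "engine": "elm",
                "d": model.config.d,
                "L": model.config.L,
                "C": model.config.C,
                "t": model.config.t,
                "seed": model.config.seed,
                "normalize_features": model.config.normalize_features,
                "training_mse": model.training_mse,
                "version": 1,
            }
        )


def load_elm(path: str | Path) -> ElmModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("engine") != "elm":
            raise ValueError(f"{path} is not an ELM model file")
        cfg = ElmConfig(
            L=int(f.attrs["L"]),
            C=float(f.attrs["C"]),
            t=int(f.attrs["t"]),
            seed=int(f.attrs["seed"]),
            normalize_features=bool(f.attrs["normalize_features"]),
        )
        mean = f["feature_mean"][...] if "feature_mean" in f else None
        scale = f["feature_scale"][...] if "feature_scale" in f else None
        return ElmModel(
            A=f["A"][...],
            B=f["B"][...],
            beta=f["beta"][...],
            config=cfg,
            feature_mean=mean,
            feature_scale=scale,
            training_mse=float(f.attrs.get("training_mse", float("nan"))),
        )
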