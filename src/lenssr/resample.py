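"""Bicubic resampling and the HR = LR_int + HF training decomposition.

Both super-resolution engines are trained on pairs produced here: a
high-resolution (HR) cell image is bicubic-downsampled by the magnification
factor ``t`` to a low-resolution (LR) image emulating the lensless capture,
the LR image is bicubic-upsampled back to HR size (``lr_int``), and the
signed high-frequency residual ``hf = hr - lr_int`` is the detail that plain
interpolation cannot recover — the learning target.

The resampler is the separable Keys cubic convolution kernel with
``a = -0.5`` (Catmull–Rom), pixel-center aligned (output center ``u`` maps to
input coordinate ``(u + 0.5) / s - 0.5`` for scale ``s``), with
clamp-to-edge handling of kernel overhang.  Downsampling widens the kernel by
``t`` (anti-aliasing) by default, mimicking the pixel-aperture averaging of a
real sensor; per-row weight normalization makes both directions preserve
constant images exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .imgcore import as_gray

__all__ = [
    "ResampleConfig",
    "TrainingPair",
    "downsample_bicubic",
    "upsample_bicubic",
    "hf_decompose",
    "bicubic_kernel",
]


@dataclass(frozen=True)
class ResampleConfig:
    """Resampling parameters shared across the pipeline.

    t : integer magnification/decimation factor (>= 2).
    kernel_a : Keys kernel free parameter; -0.5 is Catmull–Rom.
    antialias : widen the kernel by ``t`` when downsampling.
    """

    t: int = 4
    kernel_a: float = -0.5
    antialias: bool = True

    def __post_init__(self) -> None:
        if self.t < 2:
            raise ValueError(f"magnification factor t must be >= 2, got {self.t}")


@dataclass
class TrainingPair:
    """One HR image together with its derived LR / interpolated / HF images."""

    hr: np.ndarray
    lr: np.ndarray
    lr_int: np.ndarray
    hf: np.ndarray
    cell_type: Optional[str] = None


def bicubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel k(x)."""
    ax = np.abs(np.asarray(x, dtype=np.float64))
    out = np.zeros_like(ax)
    near = ax <= 1.0
    far = (ax > 1.0) & (ax < 2.0)
    out[near] = (a + 2.0) * ax[near] ** 3 - (a + 3.0) * ax[near] ** 2 + 1.0
    out[far] = a * ax[far] ** 3 - 5.0 * a * ax[far] ** 2 + 8.0 * a * ax[far] - 4.0 * a
    return out


def _resample_matrix(
    n_in: int, n_out: int, a: float, antialias: bool
) -> np.ndarray:
    """Dense (n_out, n_in) one-dimensional resampling operator.

    Pixel-center grid alignment; replicate (clamp-to-edge) boundary handling;
    rows normalized to unit sum so constants are preserved exactly.
    """
    scale = n_out / n_in
    # kernel stretched over the source grid when minifying (anti-alias)
    kscale = min(scale, 1.0) if antialias else 1.0
    radius = 2.0 / kscale
    centers = (np.arange(n_out) + 0.5) / scale - 0.5
    first = np.floor(centers - radius).astype(int) + 1
    ntaps = int(np.ceil(2.0 * radius)) + 2
    taps = first[:, None] + np.arange(ntaps)[None, :]
    w = bicubic_kernel((centers[:, None] - taps) * kscale, a)
    w /= w.sum(axis=1, keepdims=True)
    m = np.zeros((n_out, n_in))
    src = np.clip(taps, 0, n_in - 1)
    np.add.at(m, (np.repeat(np.arange(n_out), ntaps), src.ravel()), w.ravel())
    return m


def downsample_bicubic(img: np.ndarray, cfg: ResampleConfig = ResampleConfig()) -> np.ndarray:
    """Bicubic-downsample by ``cfg.t``; both sides must be divisible by ``t``."""
    a = as_gray(img, allow_signed=True)
    h, w = a.shape
    if h % cfg.t or w % cfg.t:
        raise ValueError(
            f"image shape {a.shape} not divisible by t={cfg.t}; "
            f"crop or pad to a multiple of {cfg.t} first"
        )
    mr = _resample_matrix(h, h // cfg.t, cfg.kernel_a, cfg.antialias)
    mc = _resample_matrix(w, w // cfg.t, cfg.kernel_a, cfg.antialias)
    return mr @ a @ mc.T


def upsample_bicubic(img: np.ndarray, cfg: ResampleConfig = ResampleConfig()) -> np.ndarray:
    """Bicubic-upsample by ``cfg.t`` (never anti-aliased: it is magnification)."""
    a = as_gray(img, allow_signed=True)
    h, w = a.shape
    mr = _resample_matrix(h, h * cfg.t, cfg.kernel_a, antialias=False)
    mc = _resample_matrix(w, w * cfg.t, cfg.kernel_a, antialias=False)
    return mr @ a @ mc.T


def hf_decompose(
    hr: np.ndarray,
    cfg: ResampleConfig = ResampleConfig(),
    cell_type: Optional[str] = None,
) -> TrainingPair:
    """Decompose an HR image into its LR / interpolated / high-frequency parts.

    The identity ``lr_int + hf == hr`` holds to machine precision by
    construction; ``hf`` is signed.
    """
    hr = as_gray(hr)
    lr = downsample_bicubic(hr, cfg)
    lr_int = upsample_bicubic(lr, cfg)
    hf = hr - lr_int
    return TrainingPair(hr=hr, lr=lr, lr_int=lr_int, hf=hf, cell_type=cell_type)
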