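"""Synthetic cell phantoms, the lensless degradation chain, and flow scenes.

No image data accompanies the system being modelled, so all testing and
benchmarking runs on phantoms that reproduce its qualitative structure:

* **rbc** — small disc whose rim is dimmer than its center (the biconcave
  profile of a red blood cell seen in transmission);
* **wbc** — medium disc with an offset, darker, granular nucleus;
* **hepg2** — larger blob with a sinusoidally perturbed, irregular boundary
  (a hepatoma tumor cell).

Cells sit dark on a bright background (~0.9) as in shadow imaging.  The
degradation chain emulates a lensless capture: the image contrast falls with
the cell-to-sensor distance ``d_obj`` following

    contrast(d_obj) = alpha / (1 + (d_obj / D)**phi),

then diffraction spread is approximated by a Gaussian blur whose sigma grows
linearly with ``d_obj``, the frame is decimated by the pixel-pitch factor
``t``, and additive Gaussian sensor noise is applied.  The numeric defaults
(alpha = 1, D = 100 um, phi = 1.5, d_obj in the 5–30 um range allowed by a
30 um channel, blur sigma = 0.05 px/um, noise sigma = 0.01) are synthetic
choices spanning a visible contrast range; only the functional form of the
contrast law is physical.

``make_flow_sequence`` renders ground-truthed scenes of cells transiting a
channel for the detection/counting pipeline, returning both the LR frames
and a per-cell event log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .imgcore import ImageLibrary, LibraryEntry, as_gray
from .resample import ResampleConfig, downsample_bicubic

__all__ = [
    "PhantomSpec",
    "ContrastModel",
    "CellEvent",
    "make_phantom",
    "make_library",
    "degrade_lensless",
    "make_flow_sequence",
]

CELL_TYPES = ("hepg2", "rbc", "wbc")

#: bright background level of a shadow image on the [0, 1] scale
BACKGROUND = 0.9


@dataclass(frozen=True)
class PhantomSpec:
    """Morphology of one synthetic cell.

    ``diameter`` is in pixels at HR scale.  Type-specific knobs: ``ring_depth``
    (rbc rim-vs-center contrast), ``nucleus_radius``/``nucleus_contrast``
    (wbc), ``irregularity`` (hepg2 boundary perturbation amplitude).
    """

    cell_type: str
    diameter: float
    ring_depth: float = 0.2
    nucleus_radius: float = 0.45
    nucleus_contrast: float = 0.2
    irregularity: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(
                f"unknown cell type {self.cell_type!r}; expected one of {CELL_TYPES}"
            )
        if self.diameter <= 2:
            raise ValueError(f"diameter must exceed 2 px, got {self.diameter}")


#: default HR diameter as a fraction of the image side, per type
_DIAMETER_FRACTION = {"rbc": 0.32, "wbc": 0.42, "hepg2": 0.60}


@dataclass(frozen=True)
class ContrastModel:
    """Contrast-versus-distance law of the lensless capture.

    ``contrast(d) = alpha / (1 + (d / D)**phi)`` — equal to ``alpha`` at the
    sensor surface and strictly decreasing with distance for ``phi > 0``.
    Distances are in micrometres.
    """

    alpha: float = 1.0
    D: float = 100.0
    phi: float = 1.5

    def contrast(self, d_obj: float) -> float:
        if d_obj < 0:
            raise ValueError(f"object distance must be >= 0, got {d_obj}")
        return self.alpha / (1.0 + (d_obj / self.D) ** self.phi)


def _soft_disc(rr: np.ndarray, radius: float, softness: float = 0.6) -> np.ndarray:
    """Smooth indicator of a disc: 1 inside, 0 outside, ~1-px soft edge."""
    return 1.0 / (1.0 + np.exp((rr - radius) / softness))


def make_phantom(
    spec: PhantomSpec, size: int, center: Optional[tuple[float, float]] = None
) -> tuple[np.ndarray, dict]:
    """Render one HR cell phantom on a textured bright background.

    Returns the image and a metadata dict (type, center, radius) used as
    ground truth by the detection tests.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    rr = np.hypot(yy - center[0], xx - center[1])
    img = BACKGROUND + rng.normal(0.0, 0.005, (size, size))
    radius = spec.diameter / 2.0

    if spec.cell_type == "rbc":
        body = _soft_disc(rr, radius)
        rim_level, center_level = 0.35, 0.35 + spec.ring_depth
        inner = _soft_disc(rr, 0.55 * radius)
        cell = rim_level * (body - inner) + center_level * inner
        img = img * (1.0 - body) + cell
    elif spec.cell_type == "wbc":
        body = _soft_disc(rr, radius)
        img = img * (1.0 - body) + 0.45 * body
        off = 0.3 * radius
        ang = rng.uniform(0.0, 2.0 * np.pi)
        ncy = center[0] + off * np.sin(ang)
        ncx = center[1] + off * np.cos(ang)
        nrr = np.hypot(yy - ncy, xx - ncx)
        nucleus = _soft_disc(nrr, spec.nucleus_radius * radius)
        granules = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 1.0)
        granules *= 0.08 / max(granules.std(), 1e-9)
        img -= nucleus * (spec.nucleus_contrast - granules)
    else:  # hepg2
        theta = np.arctan2(yy - center[0], xx - center[1])
        k = rng.integers(3, 6)
        phase = rng.uniform(0.0, 2.0 * np.pi, 2)
        wobble = 1.0 + spec.irregularity * (
            0.7 * np.sin(k * theta + phase[0]) + 0.3 * np.sin((k + 2) * theta + phase[1])
        )
        body = 1.0 / (1.0 + np.exp((rr - radius * wobble) / 0.6))
        texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 2.0)
        texture *= 0.05 / max(texture.std(), 1e-9)
        img = img * (1.0 - body) + (0.35 + texture) * body

    np.clip(img, 0.0, 1.0, out=img)
    meta = {"cell_type": spec.cell_type, "center": center, "radius": radius}
    return img, meta


def make_library(
    per_type: int = 30,
    size: int = 48,
    seed: int = 0,
    types: Sequence[str] = CELL_TYPES,
) -> ImageLibrary:
    """Generate a labeled HR phantom library (default 30 images per type).

    Diameters jitter by ±10% around the per-type default and morphology
    parameters vary slightly, mimicking the appearance spread of a real
    microscope library.
    """
    root_rng = np.random.default_rng(seed)
    entries: list[LibraryEntry] = []
    for cell_type in sorted(types):
        for i in range(per_type):
            sub = int(root_rng.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub)
            diameter = _DIAMETER_FRACTION[cell_type] * size * rng.uniform(0.9, 1.1)
            spec = PhantomSpec(
                cell_type=cell_type,
                diameter=diameter,
                ring_depth=0.2 * rng.uniform(0.8, 1.2),
                nucleus_contrast=0.2 * rng.uniform(0.8, 1.2),
                irregularity=0.15 * rng.uniform(0.7, 1.3),
                seed=sub,
            )
            # near-centered placement with small jitter: library entries stand
            # for detection-centered crops, as the classifier will see them
            mid = (size - 1) / 2.0
            center = tuple(mid + rng.uniform(-2.0, 2.0, 2))
            img, _ = make_phantom(spec, size, center=center)
            entries.append(
                LibraryEntry(image=img, cell_type=cell_type, id=f"{cell_type}_{i:03d}")
            )
    return ImageLibrary(entries=entries, hr_size=size, types=tuple(sorted(types)))


def degrade_lensless(
    hr: np.ndarray,
    cm: ContrastModel = ContrastModel(),
    cfg: ResampleConfig = ResampleConfig(),
    *,
    d_obj: float = 10.0,
    noise_sigma: float = 0.01,
    blur_per_um: float = 0.05,
    background: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Apply the lensless shadow-imaging degradation chain to an HR image.

    Contrast about the background level is scaled by
    ``contrast(d_obj) / alpha``, the image is blurred with
    ``sigma = blur_per_um * d_obj`` px, decimated by ``cfg.t``, and additive
    Gaussian sensor noise is added before clamping to [0, 1].  At
    ``d_obj = 0`` with zero noise the chain reduces to plain decimation.
    """
    hr = as_gray(hr)
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    factor = cm.contrast(d_obj) / cm.alpha
    bg = float(np.median(hr)) if background is None else background
    sigma = blur_per_um * d_obj
    blurred = gaussian_filter(hr, sigma, mode="nearest") if sigma > 0 else hr
    contrasted = bg + (blurred - bg) * factor
    lr = downsample_bicubic(contrasted, cfg)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        lr = lr + rng.normal(0.0, noise_sigma, lr.shape)
    return np.clip(lr, 0.0, 1.0)


@dataclass
class CellEvent:
    """Ground truth for one cell transiting the channel."""

    cell_id: int
    cell_type: str
    entry_frame: int
    centroids: list[tuple[int, float, float]] = field(default_factory=list)
    # (frame_index, row, col) in LR pixel coordinates


def make_flow_sequence(
    n_cells: int = 12,
    type_mix: Optional[dict[str, float]] = None,
    n_frames: int = 30,
    frame_shape: tuple[int, int] = (40, 120),
    velocity: float = 6.0,
    seed: int = 0,
    cm: ContrastModel = ContrastModel(),
    cfg: ResampleConfig = ResampleConfig(),
    d_obj: float = 10.0,
    noise_sigma: float = 0.01,
    crop_size: int = 12,
    entry_spacing: int = 2,
) -> tuple[list[np.ndarray], list[CellEvent]]:
    """Render a ground-truthed sequence of LR frames of cells in flow.

    Cells appear fully inside the left margin and translate rightward at
    ``velocity`` LR px/frame with sub-pixel jitter, vanishing once they would
    leave the field of view.  Placement follows the channel geometry: cells
    occupy stratified flow lanes spaced wider than the largest phantom so
    simultaneous cells never overlap, and entry frames are staggered (at
    least ``entry_spacing`` frames, more when lanes must be reused) so cells
    sharing a lane stay column-separated — the well-separated regime in which
    counting can be exact.  Frame 0 is always cell-free and serves as the
    background reference.  Returns the frames plus one :class:`CellEvent`
    per cell.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if type_mix is None:
        type_mix = {"rbc": 0.5, "hepg2": 0.5}
    for t in type_mix:
        if t not in CELL_TYPES:
            raise ValueError(f"unknown cell type {t!r} in type_mix")
    h_lr, w_lr = frame_shape
    t = cfg.t
    hr_shape = (h_lr * t, w_lr * t)
    rng = np.random.default_rng(seed)

    # deterministic type allocation honoring the mix, then shuffled
    labels: list[str] = []
    types_sorted = sorted(type_mix)
    weights = np.array([type_mix[k] for k in types_sorted], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n_cells).astype(int)
    while counts.sum() < n_cells:
        counts[int(np.argmax(weights * n_cells - counts))] += 1
    for lbl, c in zip(types_sorted, counts):
        labels.extend([lbl] * int(c))
    rng.shuffle(labels)

    # cells are sized exactly as the library phantoms for a crop of this
    # size, so detection crops classify against a matched-geometry library;
    # the largest type (hepg2) sets the packing scale
    window_hr = crop_size * t
    d_max_hr = _DIAMETER_FRACTION["hepg2"] * window_hr * 1.1
    margin_hr = d_max_hr / 2.0 + 4.0

    # lanes: distinct flow rows far enough apart that blobs never merge;
    # cells sharing a lane enter staggered so they stay column-separated
    lane_lo, lane_hi = margin_hr, hr_shape[0] - 1 - margin_hr
    usable = lane_hi - lane_lo
    n_lanes = max(1, min(n_cells, int(usable // (1.3 * d_max_hr)) + 1))
    lanes = np.linspace(lane_lo, lane_hi, n_lanes) if n_lanes > 1 else np.array([(lane_lo + lane_hi) / 2])
    lane_jitter = 0.0 if n_lanes < 2 else min((lanes[1] - lanes[0]) / 6.0, float(t))
    lane_order = rng.permutation(n_lanes)

    in_lane_gap = int(np.ceil(2.2 * d_max_hr / (velocity * t)))
    spacing = max(entry_spacing, int(np.ceil(in_lane_gap / n_lanes)))
    entries = 1 + spacing * np.arange(n_cells)
    if n_cells and entries[-1] > n_frames - 2:
        warnings.warn(
            f"{n_cells} cells at entry spacing {spacing} need "
            f">= {entries[-1] + 2} frames; late cells will barely transit",
            stacklevel=2,
        )
        entries = np.minimum(entries, n_frames - 2)

    bg_rng = np.random.default_rng(seed + 1)
    bg_hr = BACKGROUND + bg_rng.normal(0.0, 0.003, hr_shape)
    np.clip(bg_hr, 0.0, 1.0, out=bg_hr)

    cells = []
    events: list[CellEvent] = []
    for i in range(n_cells):
        sub = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(sub)
        diameter_hr = _DIAMETER_FRACTION[labels[i]] * window_hr * crng.uniform(0.9, 1.1)
        spec = PhantomSpec(cell_type=labels[i], diameter=diameter_hr, seed=sub)
        tile = int(2 * (diameter_hr / 2.0 + 6.0)) | 1
        sprite, _ = make_phantom(spec, tile)
        sprite_dev = sprite - np.median(sprite)  # deviation from its own bg
        lane = lanes[lane_order[i % n_lanes]]
        row_hr = float(np.clip(lane + crng.uniform(-1, 1) * lane_jitter, lane_lo, lane_hi))
        jitter = crng.normal(0.0, 0.3, (n_frames, 2)).clip(-1.0, 1.0) * t / 4.0
        cells.append(
            {
                "spec": spec, "sprite": sprite_dev, "tile": tile,
                "row_hr": row_hr, "entry": int(entries[i]), "jitter": jitter,
            }
        )
        events.append(CellEvent(cell_id=i, cell_type=labels[i], entry_frame=int(entries[i])))

    frames: list[np.ndarray] = []
    noise_rng = np.random.default_rng(seed + 2)
    for fidx in range(n_frames):
        canvas = bg_hr.copy()
        for cid, c in enumerate(cells):
            age = fidx - c["entry"]
            if age < 0:
                continue
            col_hr = margin_hr + age * velocity * t + c["jitter"][fidx, 1]
            row_hr = c["row_hr"] + c["jitter"][fidx, 0]
            if col_hr > hr_shape[1] - 1 - margin_hr:
                continue  # cell has left the field of view
            _paste(canvas, c["sprite"], row_hr, col_hr)
            events[cid].centroids.append((fidx, row_hr / t, col_hr / t))
        np.clip(canvas, 0.0, 1.0, out=canvas)
        frames.append(
            degrade_lensless(
                canvas, cm, cfg, d_obj=d_obj, noise_sigma=noise_sigma,
                background=BACKGROUND, rng=noise_rng,
            )
        )
    return frames, events


def _paste(canvas: np.ndarray, sprite_dev: np.ndarray, row: float, col: float) -> None:
    """Add a sprite's background-relative deviation at (row, col), clipped."""
    th = sprite_dev.shape[0]
    r0 = int(round(row)) - th // 2
    c0 = int(round(col)) - th // 2
    r1, c1 = r0 + th, c0 + th
    sr0, sc0 = max(0, -r0), max(0, -c0)
    sr1 = th - max(0, r1 - canvas.shape[0])
    sc1 = th - max(0, c1 - canvas.shape[1])
    if sr1 <= sr0 or sc1 <= sc0:
        return
    canvas[max(0, r0) : min(r1, canvas.shape[0]), max(0, c0) : min(c1, canvas.shape[1])] += (
        sprite_dev[sr0:sr1, sc0:sc1]
    )
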