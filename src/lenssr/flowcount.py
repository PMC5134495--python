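"""Temporal-difference cell detection, sequence counting, and summaries.

A moving cell shows up as a blob in ``|frame - background|``.  Detection
thresholds that difference at ``mean + k * std``, cleans it with a 3x3 binary
opening, and keeps 8-connected components within an area gate.  Counting a
sequence follows the "sum of newly appeared cells per frame" rule: detections
are matched to the previous frame's detections by nearest centroid within a
displacement gate around the expected flow displacement, and every unmatched
detection is a new cell, which is optionally super-resolved and classified
against the HR library before being added to its type's tally.

``summarize_groups`` reproduces the per-group count summary of a multi-group
run: per-group ratio of the two cell types, their mean/standard deviation/
coefficient of variation, and per-type mean counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .imgcore import ImageLibrary, as_gray
from .resample import ResampleConfig, upsample_bicubic
from .ssim_classify import SsimConfig, classify_cell

__all__ = [
    "DetectConfig",
    "Detection",
    "FlowCountConfig",
    "CountReport",
    "RatioStats",
    "detect_cells",
    "count_sequence",
    "summarize_groups",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_CROSS = ndimage.generate_binary_structure(2, 1)  # 3x3 cross for opening


@dataclass(frozen=True)
class DetectConfig:
    """Temporal-difference detection parameters.

    ``k`` scales the threshold above the difference-image mean; the area gate
    ``[min_area, max_area]`` (px^2) is sized for 12–20 px LR cell crops.
    ``crop_size`` is the side of the LR crop extracted around each centroid.
    """

    k: float = 4.0
    min_area: int = 4
    max_area: int = 400
    crop_size: int = 12
    min_separation: float | None = None  # default: 0.6 * crop_size

    @property
    def merge_radius(self) -> float:
        return 0.6 * self.crop_size if self.min_separation is None else self.min_separation


@dataclass
class Detection:
    frame_index: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # top, left, height, width
    area: int
    crop: np.ndarray


@dataclass(frozen=True)
class FlowCountConfig:
    """Sequence-counting parameters.

    ``velocity`` is the expected flow displacement in LR px/frame (flow runs
    along image columns); a current detection matches an open track of age
    ``a`` when it lies within ``a * velocity * gate_fraction`` of the track's
    expected position ``a * velocity`` downstream.  A track survives
    up to ``max_missed_frames`` detection dropouts before it is retired, so a
    cell briefly lost to thresholding is not double counted.  ``background``
    selects the reference frame model: the first frame, or a rolling median
    of the previous ``background_window`` frames.
    """

    velocity: float = 6.0
    gate_fraction: float = 0.5
    max_missed_frames: int = 1
    background: str = "first"  # "first" | "rolling"
    background_window: int = 5
    detect: DetectConfig = field(default_factory=DetectConfig)
    ssim: SsimConfig = field(default_factory=SsimConfig)


@dataclass
class CountReport:
    per_type_counts: dict[str, int]
    total: int
    events: list[dict]
    detections_per_frame: list[int]


@dataclass
class RatioStats:
    """Summary statistics of per-group (count_a, count_b) pairs."""

    ratios: list[float]
    mean_count_a: float
    mean_count_b: float
    mean_ratio: float  # ratio of the mean counts (as reported from percentages)
    ratio_mean: float  # mean of the per-group ratios
    ratio_stdev: float  # sample stdev (n - 1) of the per-group ratios
    ratio_cv: float  # ratio_stdev / ratio_mean

    def rounded(self) -> dict:
        """Reporting view: 2-decimal ratios, half-up integer mean counts."""
        return {
            "mean_count_a": int(np.floor(self.mean_count_a + 0.5)),
            "mean_count_b": int(np.floor(self.mean_count_b + 0.5)),
            "mean_ratio": round(self.mean_ratio, 2),
            "ratio_mean": round(self.ratio_mean, 2),
            "ratio_stdev": round(self.ratio_stdev, 2),
            "ratio_cv": round(self.ratio_cv, 2),
        }


def _crop_with_pad(frame: np.ndarray, center: tuple[float, float], side: int) -> np.ndarray:
    """Square crop centered at ``center`` with replicate padding at edges."""
    pad = side  # generous; trimmed by the slice
    fp = np.pad(frame, pad, mode="edge")
    r = int(round(center[0])) + pad - side // 2
    c = int(round(center[1])) + pad - side // 2
    return fp[r : r + side, c : c + side].copy()


def detect_cells(
    frame: np.ndarray, background: np.ndarray, cfg: DetectConfig = DetectConfig()
) -> list[Detection]:
    """Detect cells in one frame against a background reference frame."""
    frame = as_gray(frame)
    background = as_gray(background)
    if frame.shape != background.shape:
        raise ValueError(f"frame/background shape mismatch: {frame.shape} vs {background.shape}")
    diff = np.abs(frame - background)
    thr = _clipped_threshold(diff, cfg.k)
    mask = diff > thr
    mask = ndimage.binary_opening(mask, structure=_CROSS)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    # a cell whose difference dips below threshold mid-body labels as several
    # fragments; components closer than the merge radius are one detection
    raw = []
    slices = ndimage.find_objects(labels)
    for idx, sl in enumerate(slices, start=1):
        area = float(np.sum(labels[sl] == idx))
        cy, cx = ndimage.center_of_mass(diff, labels, idx)
        bbox = (sl[0].start, sl[1].start, sl[0].stop - sl[0].start, sl[1].stop - sl[1].start)
        raw.append([float(cy), float(cx), area, bbox])
    merged = _merge_fragments(raw, cfg.merge_radius)
    detections: list[Detection] = []
    for cy, cx, area, bbox in merged:
        if area < cfg.min_area or area > cfg.max_area:
            continue
        crop = _crop_with_pad(frame, (cy, cx), cfg.crop_size)
        detections.append(
            Detection(
                frame_index=-1, centroid=(cy, cx), bbox=bbox, area=int(area), crop=crop
            )
        )
    detections.sort(key=lambda d: d.centroid)
    return detections


def _clipped_threshold(diff: np.ndarray, k: float, n_iter: int = 3) -> float:
    """``mean + k * std`` of the difference image with sigma clipping.

    Cell pixels are strong outliers of the difference distribution; without
    clipping they inflate the threshold in proportion to how many cells are
    in the frame, making faint cells flicker in and out of detection.  The
    clip starts from the median + k * 1.4826 MAD (immune to any cell
    fraction), then each pass recomputes mean + k * std over the pixels
    below the current threshold, converging onto the background-noise level.
    """
    vals = diff.ravel()
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    thr = med + k * 1.4826 * mad
    for _ in range(n_iter):
        kept = vals[vals <= thr]
        if kept.size < 16:
            break
        new = kept.mean() + k * kept.std()
        if abs(new - thr) < 1e-6:
            break
        thr = new
    return float(thr)


def _merge_fragments(raw: list, radius: float) -> list:
    """Greedily merge component fragments whose centroids are within radius.

    Components are visited largest-first so small satellites attach to their
    parent blob; the effective radius grows with the parent's diameter since
    fragments of a big cell scatter further.  Centroids combine
    area-weighted; bounding boxes take the union.
    """
    merged = []
    for cy, cx, area, bbox in sorted(raw, key=lambda r: -r[2]):
        target = None
        for m in merged:
            eff = max(radius, 0.9 * np.sqrt(m[2]))
            if np.hypot(cy - m[0], cx - m[1]) <= eff:
                target = m
                break
        if target is None:
            merged.append([cy, cx, area, bbox])
            continue
        tot = target[2] + area
        target[0] = (target[0] * target[2] + cy * area) / tot
        target[1] = (target[1] * target[2] + cx * area) / tot
        target[2] = tot
        t, l = min(target[3][0], bbox[0]), min(target[3][1], bbox[1])
        b = max(target[3][0] + target[3][2], bbox[0] + bbox[2])
        r = max(target[3][1] + target[3][3], bbox[1] + bbox[3])
        target[3] = (t, l, b - t, r - l)
    return merged


def _background_for(frames: Sequence[np.ndarray], i: int, cfg: FlowCountConfig) -> np.ndarray:
    if cfg.background == "first":
        return frames[0]
    if cfg.background == "rolling":
        lo = max(0, i - cfg.background_window)
        stack = np.stack(frames[lo:i]) if i > 0 else np.stack([frames[0]])
        return np.median(stack, axis=0)
    raise ValueError(f"unknown background model {cfg.background!r}")


def count_sequence(
    frames: Sequence[np.ndarray],
    lib: Optional[ImageLibrary] = None,
    sr_engine: str = "none",
    cfg: FlowCountConfig = FlowCountConfig(),
    model=None,
) -> CountReport:
    """Count cells entering the field of view across an ordered frame sequence.

    New-cell events are detections with no gated match among the open tracks.
    When a library is given, each new cell's crop is magnified to the library
    size — by the requested SR engine, or plain bicubic for ``sr_engine="none"``
    — and classified by strongest MSSIM; otherwise all cells tally under
    ``"cell"``.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames (background + data)")
    if sr_engine not in ("none", "elm", "cnn"):
        raise ValueError(f"unknown SR engine {sr_engine!r}")
    if sr_engine != "none" and model is None:
        raise ValueError(f"engine {sr_engine!r} requires a trained model")

    magnify = _make_magnifier(sr_engine, model, lib, cfg)

    per_type: dict[str, int] = {}
    events: list[dict] = []
    per_frame: list[int] = []
    # open tracks: (centroid of last sighting, frames since last sighting)
    tracks: list[tuple[tuple[float, float], int]] = []
    for i, frame in enumerate(frames):
        bg = _background_for(frames, i, cfg)
        dets = detect_cells(frame, bg, cfg.detect) if i > 0 else []
        for d in dets:
            d.frame_index = i
        per_frame.append(len(dets))
        taken: set[int] = set()
        new_tracks: list[tuple[tuple[float, float], int]] = []
        for d in dets:
            best_j, best_dist = -1, np.inf
            for j, (cen, age) in enumerate(tracks):
                if j in taken:
                    continue
                # flow is columnwise: a track seen `age` frames ago should
                # have advanced ~age * velocity along the channel
                expected = (cen[0], cen[1] + age * cfg.velocity)
                gate = max(age * cfg.velocity * cfg.gate_fraction, 1.0)
                dist = float(
                    np.hypot(d.centroid[0] - expected[0], d.centroid[1] - expected[1])
                )
                if dist <= gate and dist < best_dist:
                    best_j, best_dist = j, dist
            if best_j >= 0:
                taken.add(best_j)
                new_tracks.append((d.centroid, 1))
                continue
            # unmatched: a newly appeared cell
            label, score = "cell", float("nan")
            if lib is not None:
                hr = magnify(d.crop)
                res = classify_cell(hr, lib, cfg.ssim)
                label, score = res.cell_type, res.best_score
            per_type[label] = per_type.get(label, 0) + 1
            new_tracks.append((d.centroid, 1))
            events.append(
                {
                    "frame": i,
                    "centroid": [round(d.centroid[0], 2), round(d.centroid[1], 2)],
                    "area": d.area,
                    "cell_type": label,
                    "score": None if np.isnan(score) else round(score, 4),
                }
            )
        # coast unmatched tracks for up to max_missed_frames before retiring
        for j, (cen, age) in enumerate(tracks):
            if j not in taken and age <= cfg.max_missed_frames:
                new_tracks.append((cen, age + 1))
        tracks = new_tracks
    return CountReport(
        per_type_counts=per_type,
        total=sum(per_type.values()),
        events=events,
        detections_per_frame=per_frame,
    )


def _make_magnifier(
    sr_engine: str, model, lib: Optional[ImageLibrary], cfg: FlowCountConfig
) -> Callable[[np.ndarray], np.ndarray]:
    if lib is None:
        return lambda crop: crop
    t_needed = None
    if lib is not None:
        t_needed = lib.hr_size // cfg.detect.crop_size
        if t_needed * cfg.detect.crop_size != lib.hr_size:
            raise ValueError(
                f"library size {lib.hr_size} is not an integer multiple of "
                f"crop size {cfg.detect.crop_size}"
            )
    if sr_engine == "none":
        rcfg = ResampleConfig(t=t_needed)
        return lambda crop: np.clip(upsample_bicubic(crop, rcfg), 0.0, 1.0)
    if sr_engine == "elm":
        from .elmsr import apply_elmsr

        if model.config.t != t_needed:
            raise ValueError(
                f"ELM model magnification t={model.config.t} cannot map "
                f"{cfg.detect.crop_size} px crops to {lib.hr_size} px library images"
            )
        return lambda crop: apply_elmsr(crop, model)
    from .cnnsr import apply_cnnsr

    if model.config.t != t_needed:
        raise ValueError(
            f"CNN model magnification t={model.config.t} cannot map "
            f"{cfg.detect.crop_size} px crops to {lib.hr_size} px library images"
        )
    return lambda crop: apply_cnnsr(crop, model)


def summarize_groups(groups: Sequence[tuple[float, float]]) -> RatioStats:
    """Summarize per-group (count_a, count_b) pairs.

    The headline ``mean_ratio`` is the ratio of the per-type mean counts
    (equivalently of the percentage split); ``ratio_mean``/``ratio_stdev``/
    ``ratio_cv`` describe the spread of the per-group ratios, with the
    sample (n - 1) standard deviation.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ratios = []
    for gi, (a, b) in enumerate(groups):
        if b <= 0:
            raise ValueError(f"group {gi}: denominator count must be > 0, got {b}")
        ratios.append(a / b)
    arr = np.asarray(ratios)
    a_mean = float(np.mean([g[0] for g in groups]))
    b_mean = float(np.mean([g[1] for g in groups]))
    rmean = float(arr.mean())
    rstd = float(arr.std(ddof=1))
    return RatioStats(
        ratios=ratios,
        mean_count_a=a_mean,
        mean_count_b=b_mean,
        mean_ratio=a_mean / b_mean,
        ratio_mean=rmean,
        ratio_stdev=rstd,
        ratio_cv=rstd / rmean,
    )
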