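"""Grayscale image model, raster I/O and training-library management.

Every stage of the pipeline exchanges plain 2-D ``float64`` arrays with
intensities in ``[0, 1]`` (row-major, 0-based ``(row, col)`` indexing).
High-frequency residual images are the one exception: they are signed and may
leave ``[0, 1]``.  Images are read from and written to ordinary 8- or 16-bit
PNG/TIFF rasters; a training library is a directory tree with one
sub-directory per cell type::

    library/
        hepg2/hepg2_000.png ...
        rbc/rbc_000.png ...
        wbc/wbc_000.png ...
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "read_image",
    "write_image",
    "LibraryEntry",
    "ImageLibrary",
    "load_library",
    "save_library",
    "as_gray",
]

#: Rec.601 luma coefficients, used when ``rgb_mode="rec601"``.
_REC601 = np.array([0.299, 0.587, 0.114])

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


def as_gray(arr: np.ndarray, *, allow_signed: bool = False) -> np.ndarray:
    """Validate an array as a grayscale image and return it as ``float64``.

    Raises ``ValueError`` for non-2-D input, non-finite values, or (unless
    ``allow_signed``) values outside ``[0, 1]``.
    """
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale array, got shape {a.shape}")
    if a.size == 0:
        raise ValueError("image has zero size")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    if not allow_signed and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
        raise ValueError(
            f"intensities outside [0, 1]: min={a.min():.4g} max={a.max():.4g}"
        )
    return a


def _int_range(dtype: np.dtype) -> float:
    """Full-scale value of an unsigned integer raster dtype."""
    if dtype == np.uint8:
        return 255.0
    if dtype == np.uint16:
        return 65535.0
    if dtype == np.int32:  # 16-bit PNGs surface as int32 through some plugins
        return 65535.0
    raise ValueError(f"unsupported raster dtype {dtype}")


def read_image(path: str | Path, *, rgb_mode: str = "mean") -> np.ndarray:
    """Read an 8/16-bit PNG or TIFF into a ``[0, 1]`` float image.

    RGB inputs are collapsed to one channel, by default with an unweighted
    channel mean (the sensors modelled here are grayscale; microscope library
    images may arrive as color).  Pass ``rgb_mode="rec601"`` for the Rec.601
    luma weighting instead.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3]  # drop alpha
        if rgb_mode == "mean":
            arrf = arr.astype(np.float64).mean(axis=-1)
        elif rgb_mode == "rec601":
            arrf = arr.astype(np.float64) @ _REC601
        else:
            raise ValueError(f"unknown rgb_mode {rgb_mode!r}")
        scale = _int_range(arr.dtype)
        return arrf / scale
    if arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.shape}: {path}")
    scale = _int_range(arr.dtype)
    return arr.astype(np.float64) / scale


def write_image(img: np.ndarray, path: str | Path, *, bit_depth: int = 8) -> None:
    """Write a ``[0, 1]`` float image as an 8- or 16-bit PNG/TIFF raster.

    Values are clamped to ``[0, 1]`` and quantized round-half-up, so a
    write/read round trip differs from ``clip(img, 0, 1)`` by at most one
    quantization step ``1 / (2**bit_depth - 1)`` per pixel.
    """
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("refusing to write non-finite image")
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = Path(path)
    if path.suffix.lower() not in _RASTER_SUFFIXES:
        raise ValueError(f"unsupported raster suffix {path.suffix!r} (use PNG/TIFF)")
    full = 2**bit_depth - 1
    q = np.floor(np.clip(a, 0.0, 1.0) * full + 0.5)
    out = q.astype(np.uint8 if bit_depth == 8 else np.uint16)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, out)
        else:
            iio.imwrite(path, out)
    except OSError as exc:
        raise OSError(f"cannot write image {path}: {exc}") from exc


@dataclass(frozen=True)
class LibraryEntry:
    """One labeled high-resolution single-cell image."""

    image: np.ndarray
    cell_type: str
    id: str


@dataclass
class ImageLibrary:
    """Labeled collection of square HR single-cell images of a common size."""

    entries: list[LibraryEntry] = field(default_factory=list)
    hr_size: int = 0
    types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for e in self.entries:
            h, w = e.image.shape
            if h != self.hr_size or w != self.hr_size:
                raise ValueError(
                    f"entry {e.id!r} has shape {e.image.shape}, "
                    f"expected ({self.hr_size}, {self.hr_size})"
                )
            if e.cell_type not in self.types:
                raise ValueError(f"entry {e.id!r} has unknown type {e.cell_type!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LibraryEntry]:
        return iter(self.entries)

    def by_type(self, cell_type: str) -> list[LibraryEntry]:
        return [e for e in self.entries if e.cell_type == cell_type]

    def images(self) -> list[np.ndarray]:
        return [e.image for e in self.entries]


def load_library(root: str | Path, *, rgb_mode: str = "mean") -> ImageLibrary:
    """Load a directory tree ``root/<cell_type>/<id>.{png,tif}`` as a library.

    Entry order is deterministic: types sorted lexicographically, then file
    names sorted within each type.  All images must be square and share one
    size; offenders are listed in the error message.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"library root {root} is not a directory")
    type_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not type_dirs:
        raise ValueError(f"library root {root} contains no cell-type directories")
    entries: list[LibraryEntry] = []
    sizes: dict[str, tuple[int, int]] = {}
    for tdir in type_dirs:
        files = sorted(
            p for p in tdir.iterdir() if p.suffix.lower() in _RASTER_SUFFIXES
        )
        for f in files:
            img = read_image(f, rgb_mode=rgb_mode)
            entries.append(LibraryEntry(image=img, cell_type=tdir.name, id=f.stem))
            sizes[f"{tdir.name}/{f.name}"] = img.shape
    if not entries:
        raise ValueError(f"library root {root} contains no images")
    shapes = set(sizes.values())
    if len(shapes) > 1 or any(h != w for h, w in shapes):
        offenders = ", ".join(f"{k}:{v}" for k, v in sorted(sizes.items()))
        raise ValueError(f"library images must be square and uniform; got {offenders}")
    hr_size = entries[0].image.shape[0]
    types = tuple(t.name for t in type_dirs)
    return ImageLibrary(entries=entries, hr_size=hr_size, types=types)


def save_library(lib: ImageLibrary, root: str | Path, *, bit_depth: int = 8) -> None:
    """Write a library back to disk as ``root/<type>/<id>.png``."""
    root = Path(root)
    for e in lib.entries:
        tdir = root / e.cell_type
        tdir.mkdir(parents=True, exist_ok=True)
        write_image(e.image, tdir / f"{e.id}.png", bit_depth=bit_depth)
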