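"""Volume I/O: multi-page TIFF stacks, intensity normalisation, paired datasets.

Volumes are frames-first ``(n_frames, height, width)`` float arrays, where the
frame axis is either a confocal/iSIM Z stack or a time-lapse T axis.  The
model consumes low-SNR/high-SNR pairs that are pixel-registered by
acquisition, one :class:`VolumePair` per field of view (and per channel —
multi-channel acquisitions are split into independent single-channel volumes).
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

__all__ = [
    "ImageVolume", "VolumePair", "NormalizationSpec", "DataIOError",
    "PairingError", "read_tiff_volume", "write_tiff_volume",
    "normalize_volume", "denormalize_volume", "load_paired_dataset",
]


class DataIOError(ValueError):
    """Malformed or unreadable volume data."""


class PairingError(DataIOError):
    """Low/high directories cannot be assembled into registered pairs."""


@dataclasses.dataclass
class ImageVolume:
    """A single-channel intensity volume, frames-first.

    Parameters
    ----------
    voxels : ndarray, shape (n_frames, height, width)
        Non-negative real intensities (raw camera counts or normalised).
    axis_kind : {"Z", "T"}
        Whether the leading axis is depth or time.  The model treats both
        identically (attention runs across this axis).
    source_path : str, optional
        Provenance of the volume, if read from disk.
    """

    voxels: np.ndarray
    axis_kind: Literal["Z", "T"] = "Z"
    source_path: str | None = None

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise DataIOError(f"volume must be 3-axis (frames, h, w); got shape {v.shape}")
        if v.shape[0] < 1 or v.shape[1] < 1 or v.shape[2] < 1:
            raise DataIOError(f"degenerate volume shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise DataIOError("volume contains non-finite voxels")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]


@dataclasses.dataclass
class VolumePair:
    """A registered low-SNR / high-SNR pair: the supervised training unit."""

    low: ImageVolume
    high: ImageVolume

    def __post_init__(self):
        if self.low.shape != self.high.shape:
            raise DataIOError(
                f"pair not registered: low {self.low.shape} vs high {self.high.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.low.shape


@dataclasses.dataclass
class NormalizationSpec:
    """Affine intensity normalisation mapping two percentiles to [0, 1].

    Defaults map the 0.5th/99.5th percentiles, which is robust to hot pixels
    and dead pixels; ``minmax`` is percentile with lo=0, hi=100.
    """

    method: Literal["percentile", "minmax"] = "percentile"
    lo_pct: float = 0.5
    hi_pct: float = 99.5

    def __post_init__(self):
        if self.method == "minmax":
            self.lo_pct, self.hi_pct = 0.0, 100.0
        if not (0.0 <= self.lo_pct < self.hi_pct <= 100.0):
            raise DataIOError(
                f"require 0 <= lo_pct < hi_pct <= 100; got ({self.lo_pct}, {self.hi_pct})")


@dataclasses.dataclass
class ScaleParams:
    """Parameters of the affine map applied by :func:`normalize_volume`;
    sufficient to invert it for un-clipped voxels."""

    offset: float
    scale: float
    degenerate: bool = False


def read_tiff_volume(path: str | os.PathLike, axis_kind: str = "Z") -> ImageVolume:
    """Read a single- or multi-page TIFF as an ImageVolume.

    Pages become frames in page order.  Integer data is converted to float32
    without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) == 0:
            raise DataIOError(f"TIFF has zero pages: {path}")
        shapes = {p.shape for p in tf.pages}
        if len(shapes) != 1:
            raise DataIOError(f"inconsistent page shapes {sorted(shapes)} in {path}")
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataIOError(f"unsupported TIFF dimensionality {arr.shape} in {path}")
    if arr.dtype.kind in "iub":
        arr = arr.astype(np.float32)
    return ImageVolume(arr, axis_kind=axis_kind, source_path=str(path))


def write_tiff_volume(vol: ImageVolume, path: str | os.PathLike,
                      dtype: Literal["uint16", "float32"] = "float32") -> Path:
    """Write a volume as a multi-page TIFF, one page per frame."""
    path = Path(path)
    v = vol.voxels
    if dtype == "uint16":
        rounded = np.rint(v)
        if rounded.min() < 0 or rounded.max() > np.iinfo(np.uint16).max:
            raise DataIOError(
                f"values [{v.min():g}, {v.max():g}] out of uint16 range after rounding")
        out = rounded.astype(np.uint16)
    elif dtype == "float32":
        out = v.astype(np.float32)
    else:
        raise DataIOError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(str(path), out, photometric="minisblack")
    return path


def normalize_volume(vol: ImageVolume, spec: NormalizationSpec | None = None
                     ) -> tuple[ImageVolume, ScaleParams]:
    """Map the [lo_pct, hi_pct] intensity range onto [0, 1], clipping outside.

    A constant volume maps to all zeros with ``degenerate=True`` recorded in
    the returned parameters.
    """
    spec = spec or NormalizationSpec()
    v = vol.voxels.astype(np.float32)
    lo = float(np.percentile(v, spec.lo_pct))
    hi = float(np.percentile(v, spec.hi_pct))
    if hi <= lo:
        out = np.zeros_like(v)
        return (ImageVolume(out, vol.axis_kind, vol.source_path),
                ScaleParams(offset=lo, scale=1.0, degenerate=True))
    scale = hi - lo
    out = np.clip((v - lo) / scale, 0.0, 1.0).astype(np.float32)
    return (ImageVolume(out, vol.axis_kind, vol.source_path),
            ScaleParams(offset=lo, scale=scale))


def denormalize_volume(vol: ImageVolume, params: ScaleParams) -> ImageVolume:
    """Invert :func:`normalize_volume` (exact for voxels that were not clipped)."""
    if params.degenerate:
        out = np.full_like(vol.voxels, params.offset, dtype=np.float32)
    else:
        out = vol.voxels * params.scale + params.offset
    return ImageVolume(out.astype(np.float32), vol.axis_kind, vol.source_path)


def _tiff_files(d: Path) -> list[Path]:
    return sorted(p for p in d.iterdir() if p.suffix.lower() in {".tif", ".tiff"})


def load_paired_dataset(low_dir: str | os.PathLike, high_dir: str | os.PathLike,
                        axis_kind: str = "Z") -> list[VolumePair]:
    """Pair volumes from two directories by matching filename.

    Every file must have a partner and every pair must be shape-matched;
    pairing failures name the offending file rather than dropping it.
    Pairs are returned in lexicographic filename order.
    """
    low_dir, high_dir = Path(low_dir), Path(high_dir)
    low_files = {p.name: p for p in _tiff_files(low_dir)}
    high_files = {p.name: p for p in _tiff_files(high_dir)}
    only_low = sorted(set(low_files) - set(high_files))
    only_high = sorted(set(high_files) - set(low_files))
    if only_low or only_high:
        raise PairingError(
            f"unpaired files: low-only {only_low}, high-only {only_high}")
    if not low_files:
        raise PairingError(f"no TIFF files found in {low_dir}")
    pairs = []
    for name in sorted(low_files):
        low = read_tiff_volume(low_files[name], axis_kind)
        high = read_tiff_volume(high_files[name], axis_kind)
        if low.shape != high.shape:
            raise PairingError(
                f"shape mismatch for {name}: low {low.shape} vs high {high.shape}")
        pairs.append(VolumePair(low=low, high=high))
    return pairs
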