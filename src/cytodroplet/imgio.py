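"""Calibrated image stacks and the standard confocal preprocessing steps.

Flat-field (illumination) correction from a homogeneous dye image,
background subtraction, per-acquisition photobleaching factors from a
non-releasing control, Otsu/fixed-threshold binarization and maximum-z
projection. Coordinates are 0-based pixel centers with y increasing
downward; all physical outputs are in μm.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "FlatFieldMap",
    "estimate_background",
    "build_flatfield",
    "apply_flatfield",
    "photobleach_factors",
    "binarize",
    "max_z_projection",
    "read_stack",
    "write_stack",
]


@dataclass
class ImageStack:
    """Intensity raster with axes (t, z, c, y, x) and physical calibration."""

    pixels: np.ndarray
    pixel_size: float  # μm / px
    frame_times: np.ndarray | None = None  # s
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"pixels must have axes (t, z, c, y, x); got ndim={self.pixels.ndim}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.pixels.shape[2])]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def plane(self, t: int = 0, z: int = 0, c: int = 0) -> np.ndarray:
        return self.pixels[t, z, c]


@dataclass
class FlatFieldMap:
    """Per-pixel illumination normalization factors, mean exactly 1."""

    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("flat-field factors must be strictly positive")
        if abs(self.factors.mean() - 1.0) > 1e-6:
            raise ValueError("flat-field factors must have mean 1")


def estimate_background(image: np.ndarray) -> float:
    """Background level: mode of the lowest-quartile intensity histogram."""
    image = np.asarray(image, dtype=float)
    q25 = np.percentile(image, 25)
    low = image[image <= q25]
    hist, edges = np.histogram(low, bins=64)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def build_flatfield(
    dye_image: np.ndarray,
    background: np.ndarray | float = 0.0,
    max_nonpositive_fraction: float = 0.01,
) -> FlatFieldMap:
    """Normalization-factor map from a homogeneous dye image.

    factors = (dye − background) / mean(dye − background). Pixels where
    the corrected dye signal is non-positive are clipped to the smallest
    positive corrected value; if they exceed ``max_nonpositive_fraction``
    of the image the input is rejected.
    """
    corrected = np.asarray(dye_image, dtype=float) - background
    bad = corrected <= 0
    frac = bad.mean()
    if frac > max_nonpositive_fraction:
        raise ValueError(
            f"dye image not above background: {frac:.1%} of pixels non-positive "
            f"after subtraction (limit {max_nonpositive_fraction:.0%})"
        )
    if bad.any():
        corrected[bad] = corrected[~bad].min()
    factors = corrected / corrected.mean()
    factors /= factors.mean()  # pin the mean at exactly 1
    return FlatFieldMap(factors=factors)


def apply_flatfield(
    image: np.ndarray, flatfield: FlatFieldMap, background: float = 0.0
) -> np.ndarray:
    """Illumination-corrected image: (image − background) / factors, clamped at 0."""
    image = np.asarray(image, dtype=float)
    if image.shape != flatfield.factors.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs flat-field {flatfield.factors.shape}"
        )
    return np.clip((image - background) / flatfield.factors, 0.0, None)


def photobleach_factors(
    control_series: list[np.ndarray] | np.ndarray,
    tolerance: float = 0.02,
) -> np.ndarray:
    """Per-acquisition photobleach factors from a non-releasing control.

    The foreground ROI is fixed by Otsu on the first acquisition (so
    bleaching cannot shrink it); factor_i is the ROI mean of acquisition
    i relative to acquisition 0. Factors above 1 + tolerance trigger a
    warning and are clamped to 1. Dividing acquisition i by factor_i
    yields the bleach-corrected series.
    """
    series = [np.asarray(a, dtype=float) for a in control_series]
    if len(series) < 3:
        raise ValueError(f"need >= 3 control acquisitions, got {len(series)}")
    fg = series[0] >= threshold_otsu(series[0])
    ref = series[0][fg].mean()
    factors = np.array([a[fg].mean() / ref for a in series])
    rising = factors > 1.0 + tolerance
    if rising.any():
        warnings.warn(
            f"{rising.sum()} acquisitions brighter than the reference; clamping "
            "photobleach factors at 1",
            stacklevel=2,
        )
    return np.minimum(factors, 1.0)


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Boolean mask (intensity >= threshold) and the threshold used."""
    image = np.asarray(image, dtype=float)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError(
                "constant image: Otsu threshold undefined; use method='fixed'"
            )
        thr = float(threshold_otsu(image))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    logger.info("binarize: method=%s threshold=%g", method, thr)
    return image >= thr, thr


def max_z_projection(stack: ImageStack, t: int = 0, c: int = 0) -> np.ndarray:
    """Per-pixel maximum over the z axis for one time point and channel."""
    return stack.pixels[t, :, c].max(axis=0)


# ---------------------------------------------------------------------------
# TIFF + sidecar JSON persistence


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF (t-z-c-y-x) with a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.pixels.astype(np.float32))
    meta = {
        "axes": "TZCYX",
        "pixel_size_um": stack.pixel_size,
        "channel_names": stack.channel_names,
        "frame_times_s": None
        if stack.frame_times is None
        else list(np.asarray(stack.frame_times, dtype=float)),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF written by :func:`write_stack` (pixel size from sidecar)."""
    path = Path(path)
    pixels = tifffile.imread(path)
    pixels = np.asarray(pixels)
    while pixels.ndim < 5:  # restore squeezed singleton axes
        pixels = pixels[np.newaxis]
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        times = meta.get("frame_times_s")
        return ImageStack(
            pixels=pixels,
            pixel_size=float(meta["pixel_size_um"]),
            frame_times=None if times is None else np.asarray(times, dtype=float),
            channel_names=list(meta.get("channel_names", [])),
        )
    logger.warning("no sidecar JSON for %s; assuming pixel_size=1 μm", path)
    return ImageStack(pixels=pixels, pixel_size=1.0)
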