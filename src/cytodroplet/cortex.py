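"""Spatial statistics of structures inside droplets.

Radial probability profiles P(r/R) — the circular average of a
binarized equatorial slice as a function of distance from the droplet
center — quantify cortex vs lumen placement. Temporal cross-correlation
of binarized projections tracks cortical reorganization; the circular
autocorrelation C(s) of the cortex signal along the contour yields the
correlation length ξ_c (first 1/e crossing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RadialProfile",
    "CorrelationResult",
    "radial_probability",
    "temporal_cross_correlation",
    "contour_correlation",
    "shell_band_signal",
]


@dataclass
class RadialProfile:
    bin_centers: np.ndarray  # r/R
    probability: np.ndarray  # fraction of true pixels per bin
    pixel_counts: np.ndarray
    droplet_id: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "droplet": self.droplet_id,
                "r_over_R": self.bin_centers,
                "probability": self.probability,
                "n_pixels": self.pixel_counts,
            }
        )


@dataclass
class CorrelationResult:
    lags: np.ndarray  # μm (contour) or s/frame index (temporal)
    correlation: np.ndarray
    xi_c: float = float("nan")  # μm, first 1/e crossing


def radial_probability(
    mask: np.ndarray,
    center: tuple[float, float],
    radius: float,
    n_bins: int = 20,
    pixel_size: float = 1.0,
    min_pixels: int = 10,
    droplet_id: int = 0,
) -> RadialProfile:
    """Circular average of a binarized slice in uniform r/R bins.

    ``center`` and ``radius`` are in μm; probability per bin is the
    fraction of true pixels among all pixels whose r/R falls in the
    bin. Bins with fewer than ``min_pixels`` pixels are flagged with a
    warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    r = np.hypot(xx * pixel_size - center[0], yy * pixel_size - center[1]) / radius
    inside = r <= 1.0
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(r[inside], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    hits = np.bincount(idx, weights=mask[inside].astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prob = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    if np.any((counts > 0) & (counts < min_pixels)):
        warnings.warn(
            f"{int(np.sum((counts > 0) & (counts < min_pixels)))} radial bins have "
            f"< {min_pixels} pixels",
            stacklevel=2,
        )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(
        bin_centers=centers,
        probability=prob,
        pixel_counts=counts,
        droplet_id=droplet_id,
    )


def temporal_cross_correlation(
    masks: np.ndarray | list[np.ndarray], roi: np.ndarray | None = None
) -> np.ndarray:
    """Pearson correlation of each binarized frame with the first.

    ``masks`` is a (t, y, x) boolean series of co-registered binarized
    projections; ``roi`` restricts the comparison to the droplet
    region. Returns one value per time point (1 at t = 0); frames with
    zero variance yield NaN with a warning.
    """
    masks = np.asarray(masks, dtype=float)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("need a (t, y, x) series with >= 2 time points")
    if roi is not None:
        flat = masks[:, np.asarray(roi, dtype=bool)]
    else:
        flat = masks.reshape(masks.shape[0], -1)
    ref = flat[0]
    out = np.empty(masks.shape[0])
    for t in range(masks.shape[0]):
        a, b = ref, flat[t]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"constant mask at t={t}: correlation undefined", stacklevel=2)
            out[t] = np.nan
            continue
        out[t] = float(np.corrcoef(a, b)[0, 1])
    return out


def contour_correlation(
    signal: np.ndarray, spacing: float = 1.0, use_binarized: bool = True
) -> CorrelationResult:
    """Circular autocorrelation C(lag) of a periodic cortex signal.

    C(0) = 1; ξ_c is the smallest arclength lag where C first falls
    below 1/e, linearly interpolated between samples. ``spacing`` is
    the arclength step between samples in μm.
    """
    sig = np.asarray(signal, dtype=float)
    if len(sig) < 50:
        raise ValueError("need a periodic signal of >= 50 samples")
    sig = sig - sig.mean()
    var = np.mean(sig**2)
    if var == 0:
        raise ValueError("zero-variance signal: correlation undefined")
    # circular autocorrelation via FFT
    f = np.fft.rfft(sig)
    acf = np.fft.irfft(f * np.conj(f), n=len(sig)) / (len(sig) * var)
    n_half = len(sig) // 2 + 1
    lags = np.arange(n_half) * spacing
    c = acf[:n_half]
    below = np.where(c < 1.0 / np.e)[0]
    if len(below) == 0:
        xi = float(lags[-1])  # never decorrelates within half the perimeter
    else:
        i = int(below[0])
        if i == 0:
            xi = 0.0
        else:
            c0, c1 = c[i - 1], c[i]
            frac = (c0 - 1.0 / np.e) / (c0 - c1)
            xi = float(lags[i - 1] + frac * spacing)
    return CorrelationResult(lags=lags, correlation=c, xi_c=xi)


def shell_band_signal(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    band_width: float | None = None,
    n_samples: int = 360,
    pixel_size: float = 1.0,
    n_radial: int = 5,
) -> tuple[np.ndarray, float]:
    """Mean intensity over the radial band [R − band_width, R] vs angle.

    Samples ``n_samples`` angular positions around the droplet; returns
    the periodic trace and the arclength spacing between samples (μm,
    measured at the band mid-radius). Default band width is 10 % of R.
    """
    if band_width is None:
        band_width = 0.1 * radius
    if band_width >= radius:
        raise ValueError("band wider than the droplet radius")
    image = np.asarray(image, dtype=float)
    angles = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    # sample at bin midpoints, away from the band edges where bilinear
    # interpolation straddles the rasterized boundary
    radii = radius - band_width + (np.arange(n_radial) + 0.5) * band_width / n_radial
    aa, rr = np.meshgrid(angles, radii)
    x = (center[0] + rr * np.cos(aa)) / pixel_size
    y = (center[1] + rr * np.sin(aa)) / pixel_size
    vals = ndimage.map_coordinates(image, np.vstack([y.ravel(), x.ravel()]), order=1)
    trace = vals.reshape(n_radial, n_samples).mean(axis=0)
    mid_r = radius - band_width / 2.0
    spacing = 2 * np.pi * mid_r / n_samples
    return trace, float(spacing)
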