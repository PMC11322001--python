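"""Droplet shape descriptors.

Sphericity is the ratio of the maximum inscribed circle diameter
(D_in, from the interior Euclidean distance transform) to the minimum
circumscribed circle diameter (D_out, exact minimum enclosing circle of
the contour); a droplet is "spherical" when D_in/D_out > 0.8. Solidity
is pixel area over convex-hull area. Local curvature κ(s) comes from a
sliding-window least-squares circle fit along the contour, reported as
|κ|/κ₀ with κ₀ the curvature of the global circle fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "DropletContour",
    "ShapeMetrics",
    "CurvatureProfile",
    "extract_contour",
    "sphericity",
    "solidity",
    "local_curvature",
    "sphericity_vs_size",
    "min_enclosing_circle",
    "fit_circle",
]

SPHERICAL_THRESHOLD = 0.8


@dataclass
class DropletContour:
    """Closed droplet boundary polyline in μm (not repeating the first vertex)."""

    points: np.ndarray  # (n, 2) x, y μm, ordered
    pixel_size: float
    source: str = "slice"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 20:
            raise ValueError(f"contour needs >= 20 vertices, got {len(self.points)}")
        closed = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        self.arclengths = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
        self.perimeter = float(np.sum(seg))

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ShapeMetrics:
    d_in: float  # μm
    d_out: float  # μm
    sphericity: float
    solidity: float
    spherical: bool
    center: tuple[float, float]  # center of the max inscribed circle, μm


@dataclass
class CurvatureProfile:
    arclengths: np.ndarray  # μm
    kappa: np.ndarray  # 1/μm, unsigned magnitude
    kappa0: float  # 1/μm, global circle fit
    ratio: np.ndarray  # |κ|/κ₀


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit: returns (cx, cy, r)."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0 or not np.isfinite(r2):
        raise np.linalg.LinAlgError("degenerate circle fit")
    return float(cx), float(cy), float(np.sqrt(r2))


# -- exact minimum enclosing circle (Welzl, move-to-front) -------------------


def _circle_two(p, q):
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circle_three(p, q, r):
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.linalg.norm(p - c))


def _in_circle(circle, p, eps=1e-9):
    c, r = circle
    return np.linalg.norm(p - c) <= r * (1 + eps) + eps


def min_enclosing_circle(points: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Exact minimum enclosing circle of a 2-D point set (Welzl)."""
    pts = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    pts = pts[order]
    circle = (pts[0].copy(), 0.0)
    for i in range(1, len(pts)):
        if _in_circle(circle, pts[i]):
            continue
        circle = (pts[i].copy(), 0.0)
        for j in range(i):
            if _in_circle(circle, pts[j]):
                continue
            circle = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(circle, pts[k]):
                    continue
                c3 = _circle_three(pts[i], pts[j], pts[k])
                if c3 is not None:
                    circle = c3
    return circle


# -- contour extraction ------------------------------------------------------


def extract_contour(
    mask: np.ndarray, pixel_size: float, smooth_window: int = 3
) -> DropletContour:
    """Marching-squares boundary of the largest filled component.

    Ordered counter-clockwise (image convention: y down), lightly
    smoothed with a circular moving average. Multiple components or
    interior holes are tolerated with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no contour to extract")
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        warnings.warn("multiple components; taking the largest", stacklevel=2)
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    filled = ndimage.binary_fill_holes(mask)
    if filled.sum() != mask.sum():
        warnings.warn("mask contained holes; filled before contour extraction", stacklevel=2)
        mask = filled
    if mask.sum() < 100:
        raise ValueError("component too small (< 100 px) for a reliable contour")
    contours = measure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len)  # (row, col) = (y, x)
    xy = boundary[:, ::-1]
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    # enforce counter-clockwise orientation (positive shoelace in x-right/y-down)
    area2 = np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
    if area2 < 0:
        xy = xy[::-1]
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        xy = np.column_stack(
            [
                np.convolve(np.concatenate([c[-(smooth_window // 2):], c, c[: smooth_window // 2]]), kernel, mode="valid")
                for c in (xy[:, 0], xy[:, 1])
            ]
        )
    logger.info("extract_contour: smooth_window=%d", smooth_window)
    return DropletContour(points=xy * pixel_size, pixel_size=pixel_size)


# -- metrics -----------------------------------------------------------------


def solidity(mask: np.ndarray) -> float:
    """Pixel area of the largest component over its convex-hull area."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        raise ValueError("empty mask")
    regions = measure.regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    return float(largest.solidity)


def sphericity(
    mask: np.ndarray, contour: DropletContour | None = None, pixel_size: float = 1.0
) -> ShapeMetrics:
    """D_in/D_out shape metrics from a filled droplet mask.

    D_in is twice the maximum of the interior Euclidean distance
    transform; D_out is the diameter of the exact minimum enclosing
    circle of the contour vertices.
    """
    mask = np.asarray(mask, dtype=bool)
    if contour is None:
        contour = extract_contour(mask, pixel_size)
    else:
        pixel_size = contour.pixel_size
    filled = ndimage.binary_fill_holes(mask)
    dt = ndimage.distance_transform_edt(filled)
    d_in = 2.0 * float(dt.max()) * pixel_size
    iy, ix = np.unravel_index(int(np.argmax(dt)), dt.shape)
    _, r_out = min_enclosing_circle(contour.points)
    d_out = 2.0 * r_out
    ratio = d_in / d_out
    return ShapeMetrics(
        d_in=d_in,
        d_out=d_out,
        sphericity=float(ratio),
        solidity=solidity(mask),
        spherical=bool(ratio > SPHERICAL_THRESHOLD),
        center=(float(ix * pixel_size), float(iy * pixel_size)),
    )


def local_curvature(contour: DropletContour, window: float | None = None) -> CurvatureProfile:
    """Sliding-window circle-fit curvature κ(s) along a closed contour.

    ``window`` is the full arclength of the fitting window in μm;
    default 10 % of the perimeter. Windows whose points are collinear
    (degenerate fit) record κ = 0.
    """
    if window is None:
        window = 0.1 * contour.perimeter
    spacing = contour.perimeter / len(contour.points)
    half = max(int(round(window / spacing / 2)), 2)
    if 2 * half < 5:
        raise ValueError("curvature window must span >= 5 vertex spacings")
    logger.info("local_curvature: window=%.3g μm (%d vertices)", window, 2 * half + 1)
    pts = contour.points
    n = len(pts)
    _, _, r0 = fit_circle(pts)
    kappa0 = 1.0 / r0
    kappa = np.empty(n)
    for i in range(n):
        idx = (np.arange(i - half, i + half + 1)) % n
        try:
            _, _, r = fit_circle(pts[idx])
            kappa[i] = 1.0 / r
        except np.linalg.LinAlgError:
            kappa[i] = 0.0
    return CurvatureProfile(
        arclengths=contour.arclengths,
        kappa=kappa,
        kappa0=kappa0,
        ratio=kappa / kappa0,
    )


def sphericity_vs_size(
    metrics: pd.DataFrame, threshold: float = SPHERICAL_THRESHOLD
) -> dict:
    """Size at which droplets start deviating from sphericity.

    Fits sphericity vs D_in with a logistic in log size,
    s(D) = s_max / (1 + exp(-(ln D - ln D50)/w)), and reports the size
    where the fitted curve crosses ``threshold``. Needs >= 10 droplets.
    """
    if len(metrics) < 10:
        raise ValueError("need >= 10 droplets spanning sizes")
    d = np.asarray(metrics["d_in"], dtype=float)
    s = np.asarray(metrics["sphericity"], dtype=float)

    def model(log_d, s_max, log_d50, w):
        return s_max / (1.0 + np.exp(-(log_d - log_d50) / w))

    p0 = [min(s.max(), 1.0), np.log(np.median(d)), 0.5]
    try:
        popt, _ = optimize.curve_fit(
            model, np.log(d), s, p0=p0,
            bounds=([0.5, np.log(d.min()) - 3, 0.01], [1.0, np.log(d.max()) + 3, 5.0]),
            maxfev=10000,
        )
    except RuntimeError:
        popt = None
    if popt is None or model(np.log(d.min()), *popt) > threshold:
        return {
            "threshold_size": float("nan"),
            "note": f"< min size observed ({d.min():.3g} μm)",
            "params": None if popt is None else list(map(float, popt)),
        }
    s_max, log_d50, w = popt
    if s_max <= threshold:  # fitted curve never reaches the threshold
        return {"threshold_size": float("inf"), "note": "never spherical", "params": list(map(float, popt))}
    log_cross = log_d50 - w * np.log(s_max / threshold - 1.0)
    resid = s - model(np.log(d), *popt)
    return {
        "threshold_size": float(np.exp(log_cross)),
        "note": "",
        "params": list(map(float, popt)),
        "residual_sd": float(resid.std()),
    }


def turning_angle_sum(contour: DropletContour) -> float:
    """Integrated turning angle around the closed contour (≈ 2π)."""
    d = np.diff(np.vstack([contour.points, contour.points[:2]]), axis=0)
    angles = np.arctan2(d[:, 1], d[:, 0])
    turns = np.diff(angles)
    turns = (turns + np.pi) % (2 * np.pi) - np.pi
    return float(np.abs(np.sum(turns)))
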