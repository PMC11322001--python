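"""Filament bending stiffness from thermal shape fluctuations.

A semiflexible filament of contour length ``L`` imaged over many frames
explores transverse shapes ``u(s, t)``. Expanding each shape on the
free-end bending eigenmodes ``y_q(s)`` gives per-mode amplitudes
``a_q(t)``; equipartition fixes their variance,

    var(a_q) = k_B T / (kappa q^4),

so the bending stiffness ``kappa`` (and persistence length
``L_p = kappa / k_B T``) follows from the q-dependence of the measured
amplitude variances. Amplitudes are evaluated from the local tangent
angle θ(s) via integration by parts, a_q = -∫ θ(s) ỹ_q(s) ds, which
avoids differentiating noisy backbone coordinates twice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, ndimage, optimize
from skimage import measure, morphology

from .units import kbt

__all__ = [
    "Backbone",
    "ModeSpectrum",
    "StiffnessEstimate",
    "eigenvalue_alpha",
    "eigenfunctions",
    "trace_backbone",
    "tangent_angles",
    "mode_amplitudes",
    "estimate_kappa",
]

MAX_MODE = 10

#: Warn when tangent angles leave the small-slope regime (rad).
SMALL_SLOPE_LIMIT = 0.35


@dataclass
class Backbone:
    """Ordered filament backbone coordinates for one frame.

    Coordinates are in μm; ``arclengths`` run from 0 to the contour
    length ``L``.
    """

    points: np.ndarray  # (n, 2) x, y in μm
    frame: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 10:
            raise ValueError(f"backbone needs >= 10 points, got {len(self.points)}")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("backbone contains duplicate consecutive points")
        self.arclengths = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Contour length L in μm."""
        return float(self.arclengths[-1])


@dataclass
class ModeSpectrum:
    """Eigenmode amplitudes a_q for a set of frames.

    ``amplitudes`` has one row per frame and one column per mode
    ``k = 1..k_max``; units are μm^(3/2), following the 1/sqrt(L)
    eigenfunction normalization.
    """

    modes: np.ndarray  # mode numbers k
    wavenumbers: np.ndarray  # q = alpha_k / L, 1/μm
    amplitudes: np.ndarray  # (n_frames, n_modes)
    length: float  # μm

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")


@dataclass
class StiffnessEstimate:
    kappa: float  # pN·μm²
    persistence_length: float  # μm
    fit_modes: np.ndarray
    mode_variances: np.ndarray  # var(a_q) per fitted mode, μm³
    free_exponent: float  # diagnostic: freely fitted q exponent
    r_squared: float = field(default=np.nan)


def eigenvalue_alpha(k: int, convention: str = "exact") -> float:
    """Dimensionless eigenvalue α_k of the k-th free-end bending mode.

    ``"exact"`` (default) solves the free–free beam eigenvalue
    condition — tan(α/2) = −tanh(α/2) for odd (symmetric) modes,
    tan(α/2) = +tanh(α/2) for even (antisymmetric) modes, jointly the
    roots of cos α · cosh α = 1 — for which the mode set is orthonormal
    and orthogonal to rigid translation and rotation. ``"pi"`` uses the
    asymptotic approximation α_k = (k + ½)π; ``"literal"`` uses
    α_k = k + ½ (no π), for cross-checks against analyses that used
    that convention.
    """
    if not 1 <= k <= MAX_MODE:
        raise ValueError(f"mode number k must be in 1..{MAX_MODE}, got {k}")
    if convention == "exact":
        guess = (k + 0.5) * np.pi / 2
        if k % 2 == 1:
            f = lambda x: np.tan(x) + np.tanh(x)  # noqa: E731
        else:
            f = lambda x: np.tan(x) - np.tanh(x)  # noqa: E731
        return 2.0 * optimize.brentq(f, guess - 0.3, guess + 0.3, xtol=1e-14)
    if convention == "pi":
        return (k + 0.5) * np.pi
    if convention == "literal":
        return k + 0.5
    raise ValueError(f"unknown alpha convention {convention!r}")


def eigenfunctions(
    k: int, length: float, s: np.ndarray, convention: str = "exact"
) -> tuple[np.ndarray, np.ndarray]:
    """Free-end eigenfunction y_q(s) and its antiderivative ỹ_q(s).

    Odd modes are symmetric (cosh/cos form), even modes antisymmetric
    (sinh/sin form), both normalized with a 1/sqrt(L) prefactor so that
    ∫ y_q² ds = 1. Returns ``(y_q, y_tilde_q)`` evaluated on ``s``.

    The even-mode antiderivative carries a minus sign on its cos term
    (d/ds of −cos is +sin); with the exact eigenvalues, ỹ_q then
    vanishes at both filament ends, so the tangent-angle projection
    a_q = −∫ θ ỹ_q ds equals the direct projection ∫ u y_q ds with no
    boundary terms.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    alpha = eigenvalue_alpha(k, convention)
    q = alpha / length
    x = np.asarray(s, dtype=float) - length / 2.0
    if k % 2 == 1:
        denom_h, denom_t = np.cosh(alpha / 2), np.cos(alpha / 2)
        if abs(denom_t) < 1e-8:
            raise ValueError(f"degenerate eigenvalue for mode {k}: cos(alpha/2) ~ 0")
        y = (np.cosh(q * x) / denom_h + np.cos(q * x) / denom_t) / np.sqrt(length)
        ytil = (np.sinh(q * x) / denom_h + np.sin(q * x) / denom_t) * np.sqrt(length) / alpha
    else:
        denom_h, denom_t = np.sinh(alpha / 2), np.sin(alpha / 2)
        if abs(denom_t) < 1e-8:
            raise ValueError(f"degenerate eigenvalue for mode {k}: sin(alpha/2) ~ 0")
        y = (np.sinh(q * x) / denom_h + np.sin(q * x) / denom_t) / np.sqrt(length)
        ytil = (np.cosh(q * x) / denom_h - np.cos(q * x) / denom_t) * np.sqrt(length) / alpha
    return y, ytil


def eigenfunction_slope(
    k: int, length: float, s: np.ndarray, convention: str = "exact"
) -> np.ndarray:
    """Derivative y'_q(s) of the free-end eigenfunction.

    This is the tangent-angle profile of a unit-amplitude mode: a
    filament bent as u = a_q y_q has θ(s) = a_q y'_q(s) in the
    small-slope regime.
    """
    alpha = eigenvalue_alpha(k, convention)
    q = alpha / length
    x = np.asarray(s, dtype=float) - length / 2.0
    if k % 2 == 1:
        return (
            q
            * (np.sinh(q * x) / np.cosh(alpha / 2) - np.sin(q * x) / np.cos(alpha / 2))
            / np.sqrt(length)
        )
    return (
        q
        * (np.cosh(q * x) / np.sinh(alpha / 2) + np.cos(q * x) / np.sin(alpha / 2))
        / np.sqrt(length)
    )


def tangent_angles(backbone: Backbone, unwrap: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Local tangent angle θ at segment midpoints.

    θ_i = atan2(y_{i+1} - y_i, x_{i+1} - x_i), unwrapped to remove ±π
    jumps. Returns ``(s_mid, theta)`` with s at segment midpoints.
    """
    d = np.diff(backbone.points, axis=0)
    theta = np.arctan2(d[:, 1], d[:, 0])
    if unwrap:
        theta = np.unwrap(theta)
    s_mid = 0.5 * (backbone.arclengths[:-1] + backbone.arclengths[1:])
    return s_mid, theta


def mode_amplitudes(
    theta: np.ndarray,
    s: np.ndarray,
    length: float,
    k_max: int,
    convention: str = "exact",
) -> np.ndarray:
    """Project tangent angles onto the first ``k_max`` bending modes.

    a_q = -∫₀ᴸ θ(s) ỹ_q(s) ds by the trapezoid rule. The mean angle is
    subtracted first: a rigid rotation adds a constant to θ which the
    free-end ỹ_q integrate to ~0 anyway, and removing it keeps the
    projection in the small-slope regime.
    """
    if k_max > MAX_MODE:
        raise ValueError(f"k_max must be <= {MAX_MODE} (mode resolution limit)")
    theta = np.asarray(theta, dtype=float)
    s = np.asarray(s, dtype=float)
    theta0 = theta - theta.mean()
    if np.max(np.abs(theta0)) > SMALL_SLOPE_LIMIT:
        warnings.warn(
            "tangent angles exceed the small-slope regime (|theta| > 0.35 rad); "
            "mode amplitudes may be biased",
            stacklevel=2,
        )
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        _, ytil = eigenfunctions(k, length, s, convention)
        out[k - 1] = -np.trapezoid(theta0 * ytil, s)
    return out


def spectrum_from_backbones(
    backbones: list[Backbone], k_max: int = 4, convention: str = "exact"
) -> ModeSpectrum:
    """Mode spectrum over a frame ensemble of backbones.

    All frames are projected with the mean contour length, so frame-to-
    frame tracing jitter in L does not masquerade as mode amplitude.
    """
    length = float(np.mean([b.length for b in backbones]))
    amps = []
    for b in backbones:
        s_mid, theta = tangent_angles(b)
        amps.append(mode_amplitudes(theta, s_mid, length, k_max, convention))
    alphas = np.array([eigenvalue_alpha(k, convention) for k in range(1, k_max + 1)])
    return ModeSpectrum(
        modes=np.arange(1, k_max + 1),
        wavenumbers=alphas / length,
        amplitudes=np.array(amps),
        length=length,
    )


def estimate_kappa(
    spectrum: ModeSpectrum,
    temperature: float = 293.0,
    fit_modes: range | None = None,
    min_frames: int = 100,
) -> StiffnessEstimate:
    """Bending stiffness κ from the q-dependence of amplitude variances.

    Fits var(a_q) = k_B T / (κ q⁴) in log–log with the exponent fixed at
    −4 (intercept-only least squares); a freely fitted exponent is
    reported as a diagnostic of equipartition behaviour.
    """
    n_frames = spectrum.amplitudes.shape[0]
    if n_frames < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {n_frames}")
    if fit_modes is None:
        fit_modes = range(1, len(spectrum.modes) + 1)
    idx = [list(spectrum.modes).index(k) for k in fit_modes]
    if len(idx) < 2:
        raise ValueError("fit requires at least 2 modes")
    var = spectrum.amplitudes[:, idx].var(axis=0, ddof=1)
    if np.any(var <= 1e-30):
        raise ValueError("zero amplitude variance: rigid filament or duplicated frames")
    q = spectrum.wavenumbers[idx]
    log_var, log_q = np.log(var), np.log(q)
    # intercept-only fit with the q^-4 exponent fixed
    intercept = np.mean(log_var + 4.0 * log_q)
    kb_t = kbt(temperature)
    kappa = kb_t / np.exp(intercept)
    slope_free, b_free = np.polyfit(log_q, log_var, 1)
    pred = intercept - 4.0 * log_q
    ss_res = np.sum((log_var - pred) ** 2)
    ss_tot = np.sum((log_var - log_var.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return StiffnessEstimate(
        kappa=float(kappa),
        persistence_length=float(kappa / kb_t),
        fit_modes=np.asarray(list(fit_modes)),
        mode_variances=var,
        free_exponent=float(slope_free),
        r_squared=float(r2),
    )


# ---------------------------------------------------------------------------
# backbone tracing from a binary mask (plumbing around skeletonization)

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def trace_backbone(
    mask: np.ndarray, pixel_size: float, smoothing: float = 2.0, n_points: int = 100
) -> Backbone:
    """Trace a single unbranched filament mask into an ordered backbone.

    Skeletonizes the mask, orders the skeleton pixels end to end,
    smooths with a parametric spline and resamples at uniform arclength.
    Raises on branched skeletons or multiple components.
    """
    mask = np.asarray(mask, dtype=bool)
    n_comp = int(measure.label(mask, connectivity=2).max())
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one component, found {n_comp}")
    skel = morphology.skeletonize(mask)
    coords = {tuple(p) for p in np.argwhere(skel)}
    degree = {
        p: sum((p[0] + dy, p[1] + dx) in coords for dy, dx in _NEIGHBOURS) for p in coords
    }
    branches = [p for p, d in degree.items() if d > 2]
    if branches:
        raise ValueError(f"branched skeleton; branch points at {sorted(branches)[:5]}")
    ends = [p for p, d in degree.items() if d == 1]
    if len(ends) != 2:
        raise ValueError(f"expected 2 skeleton endpoints, found {len(ends)}")
    # walk from one endpoint to the other
    path = [ends[0]]
    seen = {ends[0]}
    while True:
        y, x = path[-1]
        nxt = [
            (y + dy, x + dx)
            for dy, dx in _NEIGHBOURS
            if (y + dy, x + dx) in coords and (y + dy, x + dx) not in seen
        ]
        if not nxt:
            break
        # prefer 4-connected continuation to avoid diagonal shortcuts
        nxt.sort(key=lambda p: abs(p[0] - y) + abs(p[1] - x))
        path.append(nxt[0])
        seen.add(nxt[0])
    xy = np.array([(x, y) for y, x in path], dtype=float) * pixel_size
    if len(xy) < 4:
        raise ValueError("skeleton too short to trace")
    tck, _ = interpolate.splprep([xy[:, 0], xy[:, 1]], s=smoothing * pixel_size**2, k=3)
    u = np.linspace(0, 1, 10 * n_points)
    fine = np.column_stack(interpolate.splev(u, tck))
    seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, arc[-1], n_points)
    resampled = np.column_stack(
        [np.interp(targets, arc, fine[:, 0]), np.interp(targets, arc, fine[:, 1])]
    )
    return Backbone(points=resampled)


def backbone_length_with_tips(mask: np.ndarray, pixel_size: float) -> float:
    """Skeleton path length plus distance-transform tip corrections (μm)."""
    bb = trace_backbone(mask, pixel_size)
    dt = ndimage.distance_transform_edt(mask) * pixel_size
    tips = []
    for p in (bb.points[0], bb.points[-1]):
        iy = int(round(p[1] / pixel_size))
        ix = int(round(p[0] / pixel_size))
        iy = np.clip(iy, 0, mask.shape[0] - 1)
        ix = np.clip(ix, 0, mask.shape[1] - 1)
        tips.append(dt[iy, ix])
    return bb.length + float(sum(tips))
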