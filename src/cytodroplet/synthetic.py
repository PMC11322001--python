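"""Synthetic data with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed:
thermally fluctuating filaments whose mode amplitudes obey
equipartition at a known bending stiffness, droplet scenes with
structures placed at cortex or lumen, Brownian and harmonically caged
trajectories at known diffusion coefficients, two-channel images with a
known peptide bleed-through ratio, intensity time series with known
release rate and per-acquisition photobleaching, and smooth
inhomogeneous illumination fields. Ground truth is imposed, not
emergent: no hybridization or hydrodynamics is simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import mechanics
from .units import kbt

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig",
    "FilamentTruth",
    "DropletTruth",
    "KineticsTruth",
    "Disk",
    "Shell",
    "Spindle",
    "Segment",
    "gen_fluctuating_filament",
    "render_scene",
    "gen_trajectories",
    "gen_release_series",
    "gen_illumination_field",
]


@dataclass
class SceneConfig:
    """Raster geometry and noise model shared by all rendered scenes."""

    image_shape: tuple[int, int] = (512, 512)  # (height, width) px
    pixel_size: float = 0.2  # μm / px
    psf_sigma: float = 0.2  # μm
    background_level: float = 10.0  # a.u.
    noise_sd: float = 1.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be non-negative")


@dataclass
class FilamentTruth:
    """Ground truth for a thermally fluctuating filament ensemble."""

    length: float = 6.0  # μm
    kappa: float = 0.04  # pN·μm²
    temperature: float = 293.0  # K
    k_max: int = 4
    frames: int = 500
    n_points: int = 100
    backbones: list = field(default_factory=list)
    mode_amplitudes: np.ndarray | None = None  # (frames, k_max) sampled a_q

    def __post_init__(self) -> None:
        if self.length <= 0 or self.kappa <= 0:
            raise ValueError("length and kappa must be positive")
        if not 1 <= self.k_max <= 10:
            raise ValueError("k_max must be in 1..10")


@dataclass
class DropletTruth:
    """Ground truth for one droplet scene."""

    center: tuple[float, float] = (51.2, 51.2)  # μm
    radius: float = 25.0  # μm
    placement: str = "cortex"  # cortex | lumen | both
    bundle_specs: list = field(default_factory=list)  # (length, width, r/R, angle)
    trapped_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.placement not in ("cortex", "lumen", "both"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if not 0 <= self.trapped_fraction <= 1:
            raise ValueError("trapped_fraction must be in [0, 1]")
        for spec in self.bundle_specs:
            if not 0 <= spec[2] <= 1:
                raise ValueError("bundle radial position r/R must be in [0, 1]")


@dataclass
class KineticsTruth:
    """Ground truth for payload diffusion and release kinetics."""

    d_free: float = 0.31  # μm²/s (free diffusion in the droplet interior)
    cage_radius: float = 0.3  # μm (MSD plateau ~ cage_radius²)
    cage_tau: float | None = None  # OU relaxation time, s; default 2·dt
    release_rate: float = 0.05  # 1/min
    bleach_factor: float = 1.0  # multiplicative per acquisition
    i0: float = 100.0  # initial intensity a.u.
    i_inf: float = 10.0  # plateau intensity a.u.

    def __post_init__(self) -> None:
        if self.d_free < 0 or self.release_rate < 0:
            raise ValueError("d_free and release_rate must be non-negative")
        if not 0 < self.bleach_factor <= 1:
            raise ValueError("bleach_factor must be in (0, 1]")
        if not self.i0 >= self.i_inf >= 0:
            raise ValueError("require i0 >= i_inf >= 0")


# ---------------------------------------------------------------------------
# fluctuating filaments


def gen_fluctuating_filament(truth: FilamentTruth, seed: int = 0) -> FilamentTruth:
    """Sample an equipartition ensemble of filament backbones.

    Per frame, mode amplitudes a_q are drawn independently from
    N(0, k_B·T / (κ q⁴)) and the backbone is the straight baseline of
    length L plus the transverse deflection u(s) = Σ_q a_q y_q(s),
    rescaled so the contour length is exactly L.
    """
    rng = np.random.default_rng(seed)
    L, k_max = truth.length, truth.k_max
    s = np.linspace(0.0, L, truth.n_points)
    slope_basis = np.stack(
        [mechanics.eigenfunction_slope(k, L, s) for k in range(1, k_max + 1)]
    )  # (k_max, n_points): tangent-angle profile per unit mode amplitude
    alphas = np.array([mechanics.eigenvalue_alpha(k) for k in range(1, k_max + 1)])
    q = alphas / L
    sd = np.sqrt(kbt(truth.temperature) / (truth.kappa * q**4))
    amps = rng.normal(0.0, sd, size=(truth.frames, k_max))
    ds = s[1] - s[0]
    backbones = []
    for i in range(truth.frames):
        # lay the curve down at unit speed along its tangent angle; the
        # contour length is then exactly L with no rescaling distortion
        theta = amps[i] @ slope_basis
        tx, ty = np.cos(theta), np.sin(theta)
        x = np.concatenate([[0.0], np.cumsum(0.5 * (tx[1:] + tx[:-1]) * ds)])
        y = np.concatenate([[0.0], np.cumsum(0.5 * (ty[1:] + ty[:-1]) * ds)])
        backbones.append(mechanics.Backbone(points=np.column_stack([x, y]), frame=i))
    truth.backbones = backbones
    truth.mode_amplitudes = amps
    return truth


# ---------------------------------------------------------------------------
# scene rendering

@dataclass
class Disk:
    center: tuple[float, float]  # μm
    radius: float  # μm
    intensity: float = 100.0


@dataclass
class Shell:
    """Annular ring: a droplet cortex seen in an equatorial slice."""

    center: tuple[float, float]  # μm
    radius: float  # μm
    thickness: float  # μm
    intensity: float = 100.0
    gap: tuple[float, float] | None = None  # angular gap (start, stop) rad


@dataclass
class Spindle:
    """Tactoid: pointed-ended spindle with a parabolic width taper."""

    center: tuple[float, float]  # μm
    length: float  # μm
    width: float  # μm (maximal, at the midpoint)
    angle: float = 0.0  # rad
    intensity: float = 100.0


@dataclass
class Segment:
    """Straight ridge of constant width (a filament or thin bundle)."""

    p0: tuple[float, float]  # μm
    p1: tuple[float, float]  # μm
    width: float  # μm
    intensity: float = 100.0


def _coordinate_grids(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    h, w = config.image_shape
    y, x = np.mgrid[0:h, 0:w]
    return x * config.pixel_size, y * config.pixel_size


def _paint(obj, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    if isinstance(obj, Disk):
        r2 = (xx - obj.center[0]) ** 2 + (yy - obj.center[1]) ** 2
        return np.where(r2 <= obj.radius**2, obj.intensity, 0.0)
    if isinstance(obj, Shell):
        dx, dy = xx - obj.center[0], yy - obj.center[1]
        r = np.hypot(dx, dy)
        m = (r <= obj.radius) & (r >= obj.radius - obj.thickness)
        if obj.gap is not None:
            ang = np.mod(np.arctan2(dy, dx), 2 * np.pi)
            a0, a1 = np.mod(obj.gap[0], 2 * np.pi), np.mod(obj.gap[1], 2 * np.pi)
            in_gap = (ang >= a0) & (ang <= a1) if a0 <= a1 else (ang >= a0) | (ang <= a1)
            m &= ~in_gap
        return np.where(m, obj.intensity, 0.0)
    if isinstance(obj, Spindle):
        c, s_ = np.cos(obj.angle), np.sin(obj.angle)
        dx, dy = xx - obj.center[0], yy - obj.center[1]
        ax = c * dx + s_ * dy  # axial offset
        tr = -s_ * dx + c * dy  # transverse offset
        half = obj.length / 2.0
        taper = 1.0 - (ax / half) ** 2  # parabolic taper -> pointed ends
        m = (np.abs(ax) <= half) & (np.abs(tr) <= (obj.width / 2.0) * np.clip(taper, 0, 1))
        return np.where(m, obj.intensity, 0.0)
    if isinstance(obj, Segment):
        p0 = np.asarray(obj.p0, dtype=float)
        d = np.asarray(obj.p1, dtype=float) - p0
        length2 = float(d @ d)
        if length2 == 0:
            raise ValueError("segment endpoints coincide")
        t = np.clip(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / length2, 0.0, 1.0)
        dist = np.hypot(xx - p0[0] - t * d[0], yy - p0[1] - t * d[1])
        return np.where(dist <= obj.width / 2.0, obj.intensity, 0.0)
    raise TypeError(f"cannot render object of type {type(obj).__name__}")


def _truth_row(label: int, obj) -> dict:
    row = {"label": label, "kind": type(obj).__name__.lower()}
    for name in ("center", "p0", "p1"):
        if hasattr(obj, name):
            val = getattr(obj, name)
            row[f"{name}_x_um"], row[f"{name}_y_um"] = float(val[0]), float(val[1])
    for name in ("radius", "thickness", "length", "width", "angle", "intensity"):
        if hasattr(obj, name):
            row[f"{name}" + ("_rad" if name == "angle" else "_um" if name != "intensity" else "")] = float(
                getattr(obj, name)
            )
    return row


def render_scene(
    config: SceneConfig, objects: list
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize objects as PSF-blurred shapes on a noisy background.

    Returns the image (float, a.u.) and a ground-truth table with one
    row per rendered object carrying its generating parameters.
    """
    xx, yy = _coordinate_grids(config)
    image = np.zeros(config.image_shape, dtype=float)
    rows = []
    if not objects:
        logger.warning("render_scene called with an empty object list")
    for label, obj in enumerate(objects, start=1):
        image = np.maximum(image, _paint(obj, xx, yy))
        rows.append(_truth_row(label, obj))
    if config.psf_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=config.psf_sigma / config.pixel_size)
    image += config.background_level
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    truth = pd.DataFrame(rows)
    return image, truth


def place_droplet_scene(
    config: SceneConfig, truth: DropletTruth, rng: np.random.Generator | None = None
) -> list:
    """Build the object list for a droplet with cortex and/or lumen content."""
    rng = rng or np.random.default_rng(config.seed)
    objects: list = []
    if truth.placement in ("cortex", "both"):
        objects.append(
            Shell(center=truth.center, radius=truth.radius, thickness=0.1 * truth.radius)
        )
    for length, width, r_over_r, angle in truth.bundle_specs:
        phi = rng.uniform(0, 2 * np.pi)
        cx = truth.center[0] + r_over_r * truth.radius * np.cos(phi)
        cy = truth.center[1] + r_over_r * truth.radius * np.sin(phi)
        objects.append(Spindle(center=(cx, cy), length=length, width=width, angle=angle))
    return objects


# ---------------------------------------------------------------------------
# trajectories


def gen_trajectories(
    truth: KineticsTruth,
    n_particles: int,
    n_steps: int,
    dt: float,
    trapped_fraction: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate free Brownian and harmonically caged 2-D trajectories.

    Free particles take Gaussian steps with per-axis variance 2·D·dt.
    Trapped particles follow a stationary Ornstein–Uhlenbeck process
    whose long-lag MSD plateaus at cage_radius² (per-axis stationary
    variance cage_radius²/4). The returned table carries the hidden
    ``true_class`` column for recovery tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 10:
        raise ValueError("need at least 10 steps")
    if not 0 <= trapped_fraction <= 1:
        raise ValueError("trapped_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_trapped = int(round(trapped_fraction * n_particles))
    tau = truth.cage_tau if truth.cage_tau is not None else 2.0 * dt
    sigma = truth.cage_radius / 2.0  # per-axis stationary SD
    rho = np.exp(-dt / tau)
    times = np.arange(n_steps) * dt
    records = []
    for pid in range(n_particles):
        trapped = pid < n_trapped
        if trapped:
            xy = np.empty((n_steps, 2))
            xy[0] = rng.normal(0.0, sigma, 2)
            innov = rng.normal(0.0, sigma * np.sqrt(1 - rho**2), size=(n_steps - 1, 2))
            for i in range(1, n_steps):
                xy[i] = xy[i - 1] * rho + innov[i - 1]
        else:
            steps = rng.normal(0.0, np.sqrt(2 * truth.d_free * dt), size=(n_steps, 2))
            steps[0] = 0.0
            xy = np.cumsum(steps, axis=0)
        records.append(
            pd.DataFrame(
                {
                    "particle": pid,
                    "t": times,
                    "x_um": xy[:, 0],
                    "y_um": xy[:, 1],
                    "true_class": "trapped" if trapped else "diffusive",
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# release kinetics and illumination


def gen_release_series(
    truth: KineticsTruth,
    frame_times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed release intensity series and a matched no-release control.

    I_obs(t_i) = [I∞ + (I0 − I∞) e^(−k t_i)] · bleach_factor^i + noise;
    the control series is generated with k = 0 and the same bleaching.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(frame_times))
    bleach = truth.bleach_factor**idx
    clean = truth.i_inf + (truth.i0 - truth.i_inf) * np.exp(
        -truth.release_rate * frame_times
    )
    series = clean * bleach
    control = truth.i0 * bleach
    if noise_sd > 0:
        series = series + rng.normal(0.0, noise_sd, size=series.shape)
        control = control + rng.normal(0.0, noise_sd, size=control.shape)
    return series, control


def gen_illumination_field(
    config: SceneConfig, gradient_amplitude: float
) -> np.ndarray:
    """Smooth positive illumination field with spatial mean exactly 1.

    A seeded random tilted-plane-plus-quadratic surface scaled into
    [1 − amplitude, 1 + amplitude].
    """
    if not 0 <= gradient_amplitude < 1:
        raise ValueError("gradient_amplitude must be in [0, 1)")
    h, w = config.image_shape
    if gradient_amplitude == 0:
        return np.ones((h, w))
    rng = np.random.default_rng(config.seed)
    y, x = np.mgrid[0:h, 0:w]
    u = (x - (w - 1) / 2) / max(w - 1, 1)
    v = (y - (h - 1) / 2) / max(h - 1, 1)
    a, b, c = rng.uniform(-1, 1, 3)
    g = a * u + b * v + c * (u**2 - v**2)
    g -= g.mean()
    peak = np.max(np.abs(g))
    if peak > 0:
        g *= gradient_amplitude / peak
    field = 1.0 + g
    return field / field.mean()
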