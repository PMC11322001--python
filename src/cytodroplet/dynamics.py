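"""Payload particle dynamics: tracking, MSD, diffusion classification.

Trajectories are linked from per-frame detections by greedy nearest
neighbours with one-frame gap closing. Time-averaged mean square
displacements are fitted with MSD = 4Dτ + offset over short lags; a
particle is classified trapped when its fitted D falls below an
absolute cutoff or its MSD plateaus (small long/short lag ratio),
mirroring the two subpopulations seen in droplets — particles caged in
the cortex mesh vs freely diffusing in the lumen. A Stokes–Einstein
reference gives the free-diffusion expectation for a sphere in water.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .units import kbt

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "link_detections",
    "msd",
    "ensemble_msd",
    "classify_and_fit",
    "classify_population",
    "stokes_einstein",
]

#: Absolute diffusion cutoff below which a particle is trapped (μm²/s).
D_TRAP_THRESHOLD = 0.01
#: MSD(10·dt)/MSD(dt) below this indicates a plateau (caged motion).
PLATEAU_RATIO_THRESHOLD = 3.0


@dataclass
class Trajectory:
    particle: int
    times: np.ndarray  # s
    xy: np.ndarray  # (n, 2) μm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.times) < 10:
            raise ValueError("trajectory needs >= 10 time points")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class MSDCurve:
    lags: np.ndarray  # s
    msd: np.ndarray  # μm²
    n_pairs: np.ndarray


@dataclass
class DiffusionEstimate:
    d: float  # μm²/s
    classification: str  # diffusive | trapped
    offset: float  # μm², localization-noise intercept
    plateau_ratio: float


def trajectories_from_frame(table: pd.DataFrame) -> list[Trajectory]:
    """Split a (particle, t, x_um, y_um) table into Trajectory objects."""
    out = []
    for pid, grp in table.groupby("particle"):
        grp = grp.sort_values("t")
        out.append(
            Trajectory(
                particle=int(pid),
                times=grp["t"].to_numpy(),
                xy=grp[["x_um", "y_um"]].to_numpy(),
            )
        )
    return out


def link_detections(
    detections: pd.DataFrame, max_step: float, max_gap: int = 1
) -> pd.DataFrame:
    """Greedy nearest-neighbour linking of (t, x_um, y_um) detections.

    Links within ``max_step`` μm per frame (scaled by the gap length
    when closing gaps of up to ``max_gap`` missed frames); ties go to
    the smallest displacement. Returns the table with a ``particle``
    column.
    """
    det = detections.sort_values("t").reset_index(drop=True).copy()
    det["particle"] = -1
    frames = np.sort(det["t"].unique())
    next_id = 0
    # active tracks: particle id -> (last frame index, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    frame_index = {t: i for i, t in enumerate(frames)}
    for t in frames:
        fi = frame_index[t]
        rows = det.index[det["t"] == t].to_numpy()
        candidates = []
        for pid, (last_fi, px, py) in active.items():
            gap = fi - last_fi
            if gap > max_gap + 1:
                continue
            for ridx in rows:
                d = float(np.hypot(det.at[ridx, "x_um"] - px, det.at[ridx, "y_um"] - py))
                if d <= max_step * gap:
                    candidates.append((d, pid, ridx))
        candidates.sort()
        used_pids, used_rows = set(), set()
        for d, pid, ridx in candidates:
            if pid in used_pids or ridx in used_rows:
                continue
            det.at[ridx, "particle"] = pid
            active[pid] = (fi, float(det.at[ridx, "x_um"]), float(det.at[ridx, "y_um"]))
            used_pids.add(pid)
            used_rows.add(ridx)
        for ridx in rows:
            if ridx not in used_rows:
                det.at[ridx, "particle"] = next_id
                active[next_id] = (fi, float(det.at[ridx, "x_um"]), float(det.at[ridx, "y_um"]))
                next_id += 1
        # drop stale tracks
        active = {p: v for p, v in active.items() if fi - v[0] <= max_gap}
    return det


def msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all frame pairs at each lag."""
    n = len(traj.times)
    max_lag = max(int(n * max_lag_fraction), 1)
    lags = np.arange(1, max_lag + 1)
    out = np.empty(len(lags))
    pairs = np.empty(len(lags), dtype=int)
    for i, lag in enumerate(lags):
        disp = traj.xy[lag:] - traj.xy[:-lag]
        out[i] = np.mean(np.sum(disp**2, axis=1))
        pairs[i] = len(disp)
    return MSDCurve(lags=lags * traj.dt, msd=out, n_pairs=pairs)


def ensemble_msd(trajs: list[Trajectory], max_lag_fraction: float = 0.25) -> MSDCurve:
    """Pair-weighted ensemble average of per-trajectory MSD curves."""
    curves = [msd(t, max_lag_fraction) for t in trajs]
    n_lags = min(len(c.lags) for c in curves)
    lags = curves[0].lags[:n_lags]
    num = sum(c.msd[:n_lags] * c.n_pairs[:n_lags] for c in curves)
    den = sum(c.n_pairs[:n_lags] for c in curves)
    return MSDCurve(lags=lags, msd=num / den, n_pairs=den)


def classify_and_fit(
    curve: MSDCurve,
    dt: float,
    d_trap_threshold: float = D_TRAP_THRESHOLD,
    plateau_ratio_threshold: float = PLATEAU_RATIO_THRESHOLD,
    fit_lags: int = 10,
) -> DiffusionEstimate:
    """Diffusion coefficient and trapped/diffusive class from one MSD.

    D comes from a pair-count-weighted linear fit MSD = 4Dτ + offset
    over lags 1..``fit_lags``·dt. Trapped if D < ``d_trap_threshold``
    OR MSD(10·dt)/MSD(dt) < ``plateau_ratio_threshold``.
    """
    if len(curve.lags) < 5:
        raise ValueError("need >= 5 lags to classify")
    sel = curve.lags <= fit_lags * dt + 1e-9
    tau, y, w = curve.lags[sel], curve.msd[sel], curve.n_pairs[sel].astype(float)
    coeffs = np.polyfit(tau, y, 1, w=np.sqrt(w))
    d = coeffs[0] / 4.0
    if d < 0:
        logger.warning("negative fitted D (%.3g) clamped to 0", d)
        d = 0.0
    i_short = 0
    i_long = int(np.argmin(np.abs(curve.lags - 10 * dt)))
    denom = curve.msd[i_short]
    ratio = float(curve.msd[i_long] / denom) if denom > 0 else np.inf
    trapped = (d < d_trap_threshold) or (ratio < plateau_ratio_threshold)
    return DiffusionEstimate(
        d=float(d),
        classification="trapped" if trapped else "diffusive",
        offset=float(coeffs[1]),
        plateau_ratio=ratio,
    )


def classify_population(
    trajs: list[Trajectory], dt: float, **kwargs
) -> pd.DataFrame:
    """Per-particle diffusion estimates for a trajectory ensemble."""
    rows = []
    for t in trajs:
        est = classify_and_fit(msd(t), dt, **kwargs)
        rows.append(
            {
                "particle": t.particle,
                "d_um2_s": est.d,
                "class": est.classification,
                "plateau_ratio": est.plateau_ratio,
            }
        )
    return pd.DataFrame(rows)


def stokes_einstein(
    diameter: float, temperature: float = 293.15, viscosity: float = 1.00
) -> float:
    """Stokes–Einstein diffusion coefficient D = k_B·T/(3π·η·d) in μm²/s.

    ``diameter`` in μm, ``viscosity`` in mPa·s (1 mPa·s = 1e-3 pN·s/μm²).
    Defaults are a 20 °C water reference.
    """
    if diameter <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("diameter, temperature and viscosity must be positive")
    eta = viscosity * 1e-3  # pN·s/μm²
    return kbt(temperature) / (3.0 * np.pi * eta * diameter)
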