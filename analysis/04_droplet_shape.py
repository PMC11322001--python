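#!/usr/bin/env python
"""Droplet shape metrics across a synthetic size series.

Builds a droplet population in which small droplets deform (sphericity
drops below 0.8 under ~40 μm, mimicking stiff encapsulated fibres),
computes D_in/D_out, solidity and local curvature per droplet, and
fits the sphericity-vs-size threshold.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cytodroplet import shape

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 31
TARGET_CROSSING = 40.0  # μm: droplets below this deform past sphericity 0.8
# lobed perturbations of relative depth ε give measured D_in/D_out ≈ 1 − 0.6ε,
# so sphericity crosses 0.8 where ε ≈ 0.33 on the logistic profile below
EPS_MAX = 0.4
D_MID = 55.0


def droplet_mask(diameter_um: float, deform: float, px: float, rng) -> np.ndarray:
    """Disk with a cosine perimeter perturbation of relative depth ``deform``."""
    r_px = diameter_um / 2.0 / px
    size = int(4 * r_px) + 40
    yy, xx = np.mgrid[0:size, 0:size]
    ang = np.arctan2(yy - size / 2, xx - size / 2)
    lobes = rng.integers(2, 5)
    phase = rng.uniform(0, 2 * np.pi)
    r_eff = r_px * (1.0 - deform * 0.5 * (1 + np.cos(lobes * ang + phase)))
    return np.hypot(xx - size / 2, yy - size / 2) <= r_eff


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    px = 0.4
    rows = []
    for _ in range(40):
        d = rng.uniform(10.0, 90.0)
        # deformation grows smoothly as droplets shrink
        deform = EPS_MAX / (1.0 + np.exp((np.log(d) - np.log(D_MID)) / 0.2))
        mask = droplet_mask(d, deform, px, rng)
        m = shape.sphericity(mask, pixel_size=px)
        contour = shape.extract_contour(mask, px, smooth_window=7)
        curv = shape.local_curvature(contour)
        rows.append(
            {"d_in": m.d_in, "d_out": m.d_out, "sphericity": m.sphericity,
             "solidity": m.solidity, "spherical": m.spherical,
             "max_curvature_ratio": float(curv.ratio.max())}
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "droplet_shapes.csv", index=False)

    fit = shape.sphericity_vs_size(table)
    (OUT / "sphericity_threshold.json").write_text(json.dumps(fit, indent=1))
    frac = table["spherical"].mean()
    print(f"{len(table)} droplets, {100 * frac:.0f} % spherical (D_in/D_out > 0.8)")
    print(f"sphericity crosses 0.8 at {fit['threshold_size']:.1f} μm "
          f"(population constructed to cross near {TARGET_CROSSING} μm)")
    print(f"deformed droplets reach κ/κ₀ up to "
          f"{table['max_curvature_ratio'].max():.1f}")


if __name__ == "__main__":
    main()
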