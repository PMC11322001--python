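#!/usr/bin/env python
"""Where structures live in droplets, and how the cortex reorganizes.

Renders droplets with bundles placed at the cortex, in the lumen, or
both; computes radial probability profiles P(r/R) of the binarized
equatorial slices; then emulates cortical reorganization (a shell whose
filament clusters coarsen over time) and quantifies it with temporal
cross-correlation and the contour correlation length ξ_c.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cytodroplet import cortex, imgio, synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 41
R = 20.0  # droplet radius μm
CENTER = (25.6, 25.6)
PX = 0.2


def droplet_scene(placement: str, rng) -> np.ndarray:
    specs = [(rng.uniform(3, 6), rng.uniform(0.8, 1.2), r, rng.uniform(0, np.pi))
             for r in {"cortex": [0.95] * 6, "lumen": rng.uniform(0, 0.6, 6),
                       "both": [0.95, 0.95, 0.95, 0.2, 0.3, 0.4]}[placement]]
    truth = syn.DropletTruth(center=CENTER, radius=R, placement=placement,
                             bundle_specs=specs)
    cfg = syn.SceneConfig(image_shape=(256, 256), pixel_size=PX, psf_sigma=0.15,
                          background_level=10.0, noise_sd=1.0,
                          seed=int(rng.integers(2**31)))
    objects = syn.place_droplet_scene(cfg, truth, rng)
    img, _ = syn.render_scene(cfg, objects)
    return img


def clustered_shell(n_clusters: int, rng) -> np.ndarray:
    """Binarized shell trace with the given number of angular clusters."""
    sig = np.zeros(720)
    width = 720 // (2 * n_clusters)
    for i in range(n_clusters):
        start = i * (720 // n_clusters) + int(rng.integers(0, 10))
        sig[np.arange(start, start + width) % 720] = 1.0
    return sig


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    rows = []
    for placement in ("cortex", "lumen", "both"):
        img = droplet_scene(placement, rng)
        mask, _ = imgio.binarize(img)
        prof = cortex.radial_probability(mask, CENTER, R, n_bins=10, pixel_size=PX)
        for c, p in zip(prof.bin_centers, prof.probability):
            rows.append({"placement": placement, "r_over_R": c, "probability": p})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "radial_profiles.csv", index=False)
    for placement in ("cortex", "lumen", "both"):
        sub = table[table.placement == placement]
        peak_bin = sub.loc[sub.probability.idxmax(), "r_over_R"]
        print(f"{placement:>6}: P(r/R) peaks at r/R = {peak_bin:.2f}")

    # cortical reorganization: clusters coarsen 24 -> 6 over "heating"
    spacing = 2 * np.pi * R / 720
    traces = [clustered_shell(n, rng) for n in (24, 16, 10, 6)]
    masks = np.stack([t[None, :].repeat(4, axis=0) for t in traces])
    corr = cortex.temporal_cross_correlation(masks)
    xi = [cortex.contour_correlation(t, spacing).xi_c for t in traces]
    report = {"cross_correlation_vs_time": list(map(float, corr)),
              "xi_c_um": list(map(float, xi))}
    (OUT / "cortex_correlation.json").write_text(json.dumps(report, indent=1))
    print(f"cross-correlation with t0: {np.round(corr, 2).tolist()}")
    print(f"ξ_c grows with clustering: {np.round(xi, 2).tolist()} μm")


if __name__ == "__main__":
    main()
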