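#!/usr/bin/env python
"""Acridine-orange unmixing and payload release kinetics.

First estimates the peptide bleed-through ratio β from a synthetic
peptide-only two-channel scene and verifies the unmixed map vanishes.
Then emulates toehold-mediated payload release at a low and a high
invader dose (k = 0.02 and 0.08 per min) under per-acquisition
photobleaching, corrects the cortex intensity series with the control-
derived bleach factors, and fits the single-exponential decay constants.
"""

import json
from pathlib import Path

import numpy as np

from cytodroplet import imgio, kinetics as kin, synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 53
BETA_TRUE = 1.4
BLEACH = 0.93
DOSES = {"low": 0.02, "high": 0.08}  # 1/min


def beta_from_synthetic_scene(rng) -> kin.UnmixModel:
    red = np.full((128, 128), 40.0)
    red[32:96, 32:96] = 180.0
    green = BETA_TRUE * red
    red = red + rng.normal(0, 4.0, red.shape)
    green = green + rng.normal(0, 4.0, green.shape)
    fg = np.zeros_like(red, bool)
    fg[32:96, 32:96] = True
    return kin.estimate_beta(green, red, fg), green, red, fg


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    model, green, red, fg = beta_from_synthetic_scene(rng)
    residual = float(np.abs(kin.unmix(green, red, model)[fg]).mean())
    print(f"β = {model.beta:.3f} (true {BETA_TRUE}); "
          f"peptide-only unmixed residual {residual:.1f} a.u. (noise-level)")

    # ~2.4 decay times of the slow dose: a shorter window cannot separate
    # the rate from the plateau intensity
    times = np.arange(0.0, 120.0, 5.0)  # min
    # photobleach factors from a non-releasing control image series
    base = np.full((64, 64), 12.0)
    base[16:48, 16:48] = 110.0
    control_images = [base * BLEACH**i for i in range(len(times))]
    factors = imgio.photobleach_factors(control_images)

    report = {"beta": model.beta, "unmix_residual": residual}
    for name, k_true in DOSES.items():
        truth = syn.KineticsTruth(release_rate=k_true, bleach_factor=BLEACH,
                                  i0=100.0, i_inf=10.0)
        observed, _ = syn.gen_release_series(truth, times, noise_sd=1.5,
                                             seed=int(rng.integers(2**31)))
        fit = kin.fit_release(times, observed / factors, seed=SEED)
        report[name] = {"k_true_per_min": k_true, "k_fit_per_min": fit.k,
                        "k_ci": list(fit.k_ci)}
        print(f"{name:>4} dose: k = {fit.k:.3f} /min "
              f"(true {k_true}, 95 % CI {fit.k_ci[0]:.3f}–{fit.k_ci[1]:.3f})")
    print("decay constant increases with invader dose"
          if report["high"]["k_fit_per_min"] > report["low"]["k_fit_per_min"]
          else "WARNING: dose ordering not recovered")

    (OUT / "release_kinetics.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
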