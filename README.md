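# cytodroplet

Quantitative image and trajectory analysis for **peptide–DNA synthetic
cytoskeletons in cell-sized droplets** — for researchers building
artificial cells from self-assembling peptide filaments (e.g. Fmoc-FF)
crosslinked by programmable DNA duplexes and confined in water-in-oil
droplets.

The package implements the full measurement chain such experiments
need, each stage verifiable by parameter recovery on synthetic data
with known ground truth:

| stage | what it computes |
|---|---|
| `synthetic` | ground-truth generators: equipartition filament ensembles, droplet scenes, Brownian/caged trajectories, release series, illumination fields |
| `imgio` | TIFF stacks, flat-field and photobleach correction, binarization, max-z projection |
| `mechanics` | bending stiffness κ and persistence length L_p from shape fluctuations via free-end eigenmodes: var(a_q) = k_B T/(κ q⁴) |
| `bundles` | tactoid/bundle length, width, aspect ratio; thin/large classes; aspect-ratio power law vs crosslinker fraction; structure-tensor alignment |
| `shape` | droplet sphericity D_in/D_out (max inscribed / min circumscribed circle), solidity, local curvature κ/κ₀ |
| `cortex` | radial probability P(r/R), temporal cross-correlation of binarized projections, contour correlation length ξ_c |
| `dynamics` | particle linking, MSD = 4Dτ fits, trapped/diffusive classification, Stokes–Einstein reference |
| `kinetics` | acridine-orange unmixing I_green − β·I_red, photobleach-corrected release curves, exponential decay-constant fits |

The `analysis/` directory holds numbered drivers (simulate →
stiffness → morphometry → shape → cortex → dynamics → release) that
run each stage end to end and write tables under `results/`.

## Worked example: recovering bending stiffness

```python
import warnings
from cytodroplet import mechanics, synthetic

truth = synthetic.FilamentTruth(kappa=0.04, length=6.0,
                                temperature=293.0, frames=500)
truth = synthetic.gen_fluctuating_filament(truth, seed=11)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")   # floppy regime: slope warning expected
    spectrum = mechanics.spectrum_from_backbones(truth.backbones, k_max=4)
    est = mechanics.estimate_kappa(spectrum, temperature=293.0)
print(f"kappa = {est.kappa:.4f} pN um^2, L_p = {est.persistence_length:.1f} um, "
      f"free exponent = {est.free_exponent:.2f}")
```

prints

```
kappa = 0.0400 pN um^2, L_p = 9.9 um, free exponent = -4.04
```

i.e. the eigenmode pipeline recovers the generating stiffness
(0.04 pN·μm²) from 500 simulated frames; the freely fitted exponent
near −4 confirms equipartition scaling, and L_p ≈ 10 μm says these
6-μm fibres are in the floppy, strongly fluctuating regime. Running
`python analysis/06_particle_dynamics.py` likewise prints the
Stokes–Einstein reference `0.43 μm²/s` for a 1-μm probe in 20 °C water
and recovers the interior diffusion coefficient 0.31 μm²/s and the
trapped fractions from simulated droplet trajectories.

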