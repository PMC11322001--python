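# Methods

`cytodroplet` quantifies synthetic cytoskeletons built from peptide
filaments crosslinked by DNA, both in bulk and confined in cell-sized
water-in-oil droplets. Every analysis stage is paired with a synthetic
generator that imposes known ground truth, so the whole pipeline is
validated by parameter recovery rather than against deposited data.
All lengths are μm, times s (release kinetics in minutes), forces pN;
k_B = 1.380649e-5 pN·μm/K, so k_B·T ≈ 4.045e-3 pN·μm at 293 K.

## Bending stiffness from shape fluctuations (`mechanics`)

A filament of contour length L imaged over many frames explores
transverse shapes u(s, t). These are expanded on the free-end bending
eigenmodes

    y_q(s) = L^{-1/2} [cosh(q(s−L/2))/cosh(α_k/2) + cos(q(s−L/2))/cos(α_k/2)]   (k odd)
    y_q(s) = L^{-1/2} [sinh(q(s−L/2))/sinh(α_k/2) + sin(q(s−L/2))/sin(α_k/2)]   (k even)

with wavenumber q = α_k/L. Equipartition fixes the amplitude variances,
var(a_q) = k_B T/(κ q⁴), and κ follows from an intercept-only log–log
fit with the exponent pinned at −4 (a freely fitted exponent is
reported as a diagnostic). The persistence length is L_p = κ/(k_B T).

Two numerical decisions matter here:

- **Eigenvalues.** The default α_k are the exact roots of the free–free
  beam condition cos α · cosh α = 1 (α_1 = 4.7300, α_2 = 7.8532, …),
  solved per mode from tan(α/2) = ∓tanh(α/2). Only at these roots is
  the mode set orthonormal (quadrature cross-terms < 1e-6) and
  orthogonal to rigid translation and rotation; the common asymptotic
  approximation α_k = (k+½)π leaves ~0.6 % normalization error on
  mode 1 and measurable mode cross-talk. Both the approximation
  (`convention="pi"`) and a literal α_k = k+½ (`"literal"`) are kept as
  options for cross-checks against other conventions.
- **Antiderivative.** Amplitudes are evaluated from the tangent angle,
  a_q = −∫ θ(s) ỹ_q(s) ds, which avoids double-differentiating noisy
  coordinates. The even-mode antiderivative is
  ỹ_q = (√L/α_k)[cosh(·)/sinh(α_k/2) **−** cos(·)/sin(α_k/2)]: the
  minus sign is required for dỹ/ds = y_q, and with the exact
  eigenvalues ỹ_q then vanishes at both filament ends, so the
  integration-by-parts identity holds with no boundary terms. Each
  projection subtracts the mean tangent angle, making the estimate
  exactly invariant under rigid rotation.

The synthetic ensemble is generated in the same tangent-angle picture:
a frame is laid down as a unit-speed curve with
θ(s) = Σ_q a_q y'_q(s), a_q ~ N(0, k_B T/(κ q⁴)). This construction has
contour length exactly L and is identical to "straight baseline plus
transverse deflection" to O(θ²), but it remains exactly decodable by
the analysis at the floppy study conditions (κ = 0.04 pN·μm², L = 6 μm,
L_p ≈ 10 μm), where a literal Monge-gauge construction plus arclength
rescaling would bias recovered variances by 5–15 %. At 500 frames the
pipeline recovers κ within ~2 % (tested at 10 %).

A small-slope warning fires when |θ − θ̄| exceeds 0.35 rad. Frames are
treated as statistically independent; no correlation-time correction
is applied. Backbones are traced from masks by skeletonization,
end-to-end ordering (branched skeletons are rejected with their branch
points listed), spline smoothing and uniform-arclength resampling.

## Image preprocessing (`imgio`)

Flat-field correction follows the homogeneous-dye recipe: factors =
(dye − background)/mean(dye − background), applied as
(image − background)/factors, clamped at zero. Background defaults to
the mode of the lowest intensity quartile (the acquisition protocol
defines no rule); it is applied per image. Photobleach factors come
from a non-releasing control series: the foreground ROI is fixed by
Otsu on the first acquisition so that bleaching cannot shrink it, and
factor_i is the ROI mean relative to acquisition 0, clamped at 1 with
a warning if the series brightens. Binarization is Otsu by default
with a fixed-threshold alternative; the threshold used is always
recorded. Coordinates are 0-based pixel centers, y down.

## Bundle morphometry (`bundles`)

Bundles/tactoids are connected components of the binarized image.
Length is the longest geodesic path of the component's skeleton —
smoothed with a 7-point moving average to remove the digital-staircase
overrun (up to ~8 % at oblique angles), endpoints pinned — plus the
medial radius at each end, so lengths reach the object tips. Width is
twice the mean medial radius along that path, where radii are measured
sub-pixel by marching the bilinearly interpolated mask along the local
path normals to the 0.5 crossing; this removes the angle-dependent
half-pixel bias of pixel-center distance transforms and keeps aspect
ratios rotation-stable within ~5 % for bar-shaped objects at 5-px
widths. Thin vs large classification uses a strict width < 1 μm.

Otsu thresholding truncates the faint pointed tips of rendered
tactoids (a ~10 % mean length deficit at width ≲ 1 μm); recovery
analyses therefore binarize tactoid fields at a fixed low threshold
(background + 5 × noise SD), which is logged like any other threshold.

Aspect-ratio scaling with crosslinker mole fraction is an OLS fit of
log(aspect) on log(fraction) (statsmodels, with standard errors).
Alignment is quantified as the intensity-weighted mean structure-tensor
coherence (λ₁−λ₂)/(λ₁+λ₂); the tensor scale (default 1 μm, 2 μm in the
isotropy tests) sets the neighbourhood over which orientations are
compared and is the knob that trades locality against noise.

## Droplet shape (`shape`)

Contours are marching-squares boundaries of the largest filled
component, counter-clockwise, lightly smoothed (window logged).
D_in is twice the maximum of the interior Euclidean distance
transform; D_out is the diameter of the exact minimum enclosing circle
(Welzl's algorithm — the circumscribed circle, not an ellipse fit).
A droplet is spherical when D_in/D_out > 0.8 (strict). Solidity is
area over convex-hull area (skimage). Local curvature κ(s) is a
least-squares (Kåsa) circle fit in a sliding arclength window,
normalized by the global circle-fit curvature κ₀. The window defaults
to 10 % of the perimeter and must be stated with any result: windows
much below ~15 % of the perimeter on pixel-quantized contours carry a
few-percent ripple (the residual staircase, ~0.1 px, divided by the
window sagitta). The sphericity-vs-size threshold is the 0.8 crossing
of a logistic in log-size fitted to the population; when the fitted
curve never drops below 0.8 the threshold is reported as below the
smallest observed droplet.

## Radial and cortical statistics (`cortex`)

P(r/R) is the circular average of a binarized equatorial slice:
the fraction of true pixels per uniform r/R bin (bins with < 10 pixels
are flagged). Cortical reorganization is tracked as the Pearson
correlation of each binarized projection with the first frame over the
droplet ROI; Pearson keeps values in [−1, 1] and equals overlap-based
normalizations up to affine terms. The cortex trace is the mean
intensity over the shell band [R − w, R] (default w = 0.1 R) versus
angle; its circular autocorrelation C(lag) is computed by FFT with
C(0) = 1, and the correlation length ξ_c is the first 1/e crossing,
linearly interpolated. 1/e is a convention; it is recorded with every
result. Frames are assumed co-registered (droplets are surface-adhered
in the intended acquisitions).

## Particle dynamics (`dynamics`)

Detections are linked greedily by nearest neighbour with one-frame gap
closing and a per-frame step cap. Time-averaged MSDs use all frame
pairs per lag up to a quarter of the trajectory span. D comes from a
pair-count-weighted linear fit MSD = 4Dτ + offset over lags 1–10
frames; the offset absorbs static localization error. A trajectory is
trapped when D < 0.01 μm²/s **or** MSD(10 dt)/MSD(dt) < 3 (both
thresholds configurable and logged) — the dual rule mirrors the two
observed subpopulations: cortex-caged particles plateau, lumen
particles stay linear. Caged motion is simulated as a stationary
Ornstein–Uhlenbeck process with per-axis SD cage_radius/2, so the MSD
plateaus at cage_radius² (relaxation time defaults to 2 dt); this is
the minimal stationary confined model. The Stokes–Einstein reference
D = k_B T/(3πηd) with T = 293.15 K, η = 1.00 mPa·s gives
0.43 μm²/s for a 1 μm sphere — 20 °C water.

## Unmixing and release kinetics (`kinetics`)

With acridine orange, green reports dsDNA and red ssDNA, but the
peptide bleeds into both channels. β is the median over peptide-only
foreground pixels of green/red (median, not a regression through the
origin: robust to segmentation bleed); the unmixed map
I_green − β·I_red equals I_dsDNA − β·I_ssDNA. Negative values mean
ssDNA excess and are never clamped. Only the contrast is recovered —
no absolute concentration calibration is attempted.

Release curves are bleach-corrected mean cortex-band intensities,
optionally normalized by a no-invader baseline, fitted with a single
exponential I(t) = I∞ + (I0 − I∞)e^(−kt), k ≥ 0 (a single decay
constant is the model reported throughout; residual diagnostics are
emitted). Confidence intervals come from seeded residual-resampling
bootstrap (200 resamples). A curve with no decay amplitude returns
k = 0 flagged. Identifiability: k and I∞ trade off unless the series
spans ≳ 2 decay times — the release driver observes 120 min for a
0.02/min dose for exactly this reason. Skipping bleach correction
biases k upward; this is demonstrated in the tests.

## Synthetic scenes and their limits

Scenes are rasterized binary geometry (disks, shells with optional
angular gaps, constant-width segments, spindles with parabolic width
taper) blurred by an ideal Gaussian PSF, on a constant background with
Gaussian read noise; illumination fields are smooth low-order surfaces
with mean exactly 1. There is no optical sectioning model, no Poisson
photon statistics, no depth-dependent aberration, no filament overlap
within bundles, and droplet content is placed, not assembled. Passing
recovery tests therefore demonstrates correctness of the measurement
chain on well-posed inputs, not robustness to every confocal artefact;
thresholding behaviour on low-SNR real data must still be reviewed per
dataset. Defaults (0.2 μm/pixel, 512² frames) are configurable; the
acquisitions they emulate did not state pixel geometry.

## Problem sizes

The test suite and drivers use 500-frame filament ensembles, 40–100
bundles per condition, 200–500 trajectories of 60–100 steps, and
droplet rasters up to 1280×640 px; the full suite runs in about half a
minute on one CPU, and the acceptance script in a few seconds.
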