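# Methods

## Scope

`mupol` implements an end-to-end processing chain for wide-field imaging
Mueller polarimetry of brain tissue: derivation of per-pixel Mueller
matrices from 16-state intensity tensors, Lu–Chipman polar decomposition
into scalar biomarker maps, a denoising diffusion model for single-shot
low-quality acquisitions with classical baselines, and a circular-statistics
evaluation suite. Everything is exercisable on a synthetic brain-tissue
phantom; no external data are required.

## Polarimetric forward and inverse model

A pixel's measurement is the 4×4 intensity block `I = A M G`, where `G` and
`A` are the calibrated polarisation state generator and analyser matrices
(global, or per-pixel `H×W×4×4`) and `M` is the tissue Mueller matrix. The
inverse map `M = A⁻¹ I G⁻¹` is evaluated as a closed-form vectorised batch
product; the 4×4 inverses use an adjugate/cofactor expansion so the whole
image costs `O(H·W)` with constant-size algebra and no Python-level pixel
loop. `numpy.linalg.inv` is kept as an independent oracle in the tests only.
Calibration blocks are validated at construction (condition number below
1e8 by default); the phantom simulates calibrations as identity plus a
small random perturbation with condition number < 10, so the inversion is
exercised nontrivially.

The 16 channels are ordered row-major over (analyser state, generator
state). The order is written into file metadata and asserted on load; no
convention is silently assumed.

`M` is normalised by its `M₁₁` element before decomposition (the standard
convention making diattenuation and depolarisation dimensionless); pixels
with `|M₁₁| ≤ eps` are flagged invalid rather than raised, because full
frames always contain unusable background.

## Lu–Chipman decomposition

`M = M_Δ · M_R · M_D` with the diattenuator peeled off first:

1. diattenuation vector `d = (M₁₂, M₁₃, M₁₄)`; `M_D` is the canonical
   diattenuator (identity when `|d| = 0`, invalid when `|d| ≥ 1`);
2. `M' = M · M_D⁻¹` using the analytic diattenuator inverse;
3. the 3×3 depolariser block is the symmetric eigen-square-root of
   `m'(m')ᵀ`, signed by `det m'`; the polarizance column of `M'` stays with
   the depolariser;
4. `m_R = m_Δ⁻¹ m'` is the retarder.

Degenerate pixels (non-finite entries, `|d| ≥ 1` from noise, eigenvalues
below `−1e-9`, singular depolarisers) are masked in `valid`, never thrown.

Scalar maps:

- `D = √(M_D₁₂² + M_D₁₃² + M_D₁₄²)` ∈ [0, 1];
- `Δ = 1 − |tr m_Δ|/3` over the **3×3** depolariser submatrix, which
  guarantees `Δ ∈ [0, 1]`. The literal 4×4-trace variant (whose trace
  includes the unit `(1,1)` element and can push `Δ` outside the unit
  interval) is available behind `delta_literal_4x4`.
- `R = acos(√((M_R₂₂+M_R₃₃)² + (M_R₃₂−M_R₂₃)²) − 1)` with the inner
  argument clamped to [−1, 1]; degrees in [0°, 180°]. For a linear
  retarder this reduces to `R = δ` via `M_R₂₂+M_R₃₃ = 1+cos δ`.
- `φ = ½·atan2(−M_R₂₄, −M_R₄₃)` wrapped to [0°, 180°). With this package's
  retarder sign convention (quarter-wave plate at θ=0 has rows
  `(1,0,0,0),(0,1,0,0),(0,0,0,1),(0,0,−1,0)`), a linear retarder has
  `M_R₂₄ = −sin 2θ sin δ` and `M_R₄₃ = −cos 2θ sin δ`, so this
  quadrant-aware form returns the fast-axis azimuth θ itself everywhere,
  and coincides with the plain half-arctangent of the ratio on its
  principal branch. Pixels with `sin R ≈ 0` have no defined optical axis
  and are excluded from `phi_valid`.

All angular outputs are degrees. A dense grid round trip
(θ ∈ {0…179°}, δ ∈ {5…175°}) recovers both parameters to below 1e-6°.

## Synthetic phantom

The generator emulates the study design of an ex-vivo brain acquisition
session, not tissue microphysics:

- **Tissue classes** (background, grey matter, white matter, tumour centre,
  tumour infiltration) drawn as smooth thresholded random fields with a
  lesion disc placed in white matter. Default optics per class (all
  configurable): WM δ=40°, depolariser diag (0.85, 0.85, 0.80), d=0.05;
  GM δ=10°, (0.70, 0.70, 0.65), 0.03; tumour centre δ=8°,
  (0.60, 0.60, 0.55), 0.03; infiltration midway between WM and the core.
  These are plausibility choices reproducing the qualitative contrasts of
  polarimetric brain imaging (clear WM azimuth patterns, disrupted core);
  they are configuration, not truth.
- **Orientation field**: a smooth low-frequency axial flow plus spatially
  correlated Gaussian jitter (1.5 px correlation length) scaled to the
  class dispersion — WM 3°, GM 14°, infiltration 30° — and per-pixel
  uniform orientations in the tumour centre, where fibre architecture is
  destroyed. Fibre dispersion varies continuously at the ~50 µm pixel
  scale, hence correlated rather than white jitter. By construction the
  local circular standard deviation of the azimuth orders as
  tumour centre > infiltration > white matter and WM < GM.
- **Diattenuation axis** follows the local fibre orientation.
- **Noise**: zero-mean two-component Gaussian scale mixture added in the
  intensity domain: `N(0, σ²)` with probability `1−κ`, `N(0, (wσ)²)` with
  probability `κ` (defaults κ=0.05, w=3) — symmetric, bell-shaped,
  slightly heavier-tailed than Normal, as polarimetric sensor noise is.
  The default σ=0.012 (normalised intensity units, `M₁₁`-scale ≈ 1) places
  the single-shot error at the magnitude reported for real low-quality
  acquisitions and at the first-step corruption level `√β₁ = 0.01` of the
  canonical diffusion schedule — the premise that makes single-pass t=1
  denoising meaningful.
- **Shots and averaging**: n independent shots, arithmetic running
  averages for n ∈ {1, 8, 16} (LQ/HQ/SHQ regimes).

What the phantom does **not** model: optical scattering and photon
transport, specular reflections beyond a maskable option, wavelength
dependence, motion or bleeding artefacts, and — importantly — the strong
noise amplification of heavily depolarising real tissue. With the default
class optics the cascade amplifies intensity noise into only a few degrees
of azimuth error, whereas real low-quality acquisitions show tens of
degrees. Consequences: (i) passing tests demonstrate correctness of the
processing chain, not clinical-level error magnitudes; (ii) at the default
low noise, any spatial blur *increases* the azimuth error against ground
truth, because it destroys genuine per-pixel orientation signal (above all
the uniform-random tumour core). Tests of the classical-baseline ordering
(Gaussian blur better than raw LQ) therefore run in a noise-dominated
regime (σ=0.1), where the raw single-shot azimuth error is ~20° and
spatial smoothing pays off, as it does for real LQ data.

## Denoising diffusion model

Forward corruption over `T` time-points with a linear variance schedule
`β_t` from 1e-4 to 0.02 (the canonical choice; the schedule is
configuration). Closed-form marginal
`x_t = √ᾱ_t x₀ + √(1−ᾱ_t) ε`, `ᾱ_t = Π(1−β_s)`.

The ε-prediction network is a time-conditioned U-Net: four resolution
levels with channel multipliers (1, 2, 4, 8), wide residual blocks
(3×3 convolutions, unit stride, group normalisation with 8 groups, SiLU),
sinusoidal time embedding injected per block as a channel bias,
single-head self-attention at the two coarsest levels and in the
bottleneck, average-pool down / nearest-neighbour up, skip connections.
The network, its automatic differentiation and the Adam optimiser are
implemented on NumPy inside the package (`mupol.nn`): a compact
reverse-mode engine over exactly the operator set the model needs. All
arithmetic is float32 and fully deterministic under a fixed seed.

Training is self-supervised on unpaired high-quality (multi-shot averaged)
intensities: sample a patch, rescale linearly to [−1, 1], augment (random
crop with mirror padding, rotations, flips), mask supra-threshold specular
reflections out of the loss, draw `t` and ε, minimise
`L1(model(x_t, t), ε)` with Adam. Rescaling is **per frame** (each
training image by its own bounds, each inference frame by its own, with
the bounds recorded so the rescale inverts): acquisitions brighter or
darker than the training set would otherwise be clipped by the [−1, 1]
projection of the reverse step and destroyed rather than denoised.

Two named presets:

| preset | patch | width | T | steps | batch | lr | t-sampling |
|--------|-------|-------|------|--------|-------|------|------------|
| desk   | 48    | 8     | 200  | 3000   | 4     | 1e-3, cosine decay | log-uniform |
| full   | 128   | 64    | 1000 | 100000 | 32    | 1e-4, constant     | uniform |

The desk preset departs from canonical uniform time sampling deliberately:
single-pass denoising only ever evaluates the model at small `t`, and with
a 3k-step budget uniform sampling leaves the terminal regime undertrained
(a few dozen samples at `t ≤ 5`). Log-uniform sampling concentrates
optimisation where inference happens. An exponential moving average of the
weights (decay 0.998 desk / 0.999 full) is used at inference — standard
stabilisation for diffusion models.

**Single-pass inference**: the low-quality frame is rescaled to [−1, 1]
and treated as the diffusion state `x_{t*}` with default `t* = 1`;
`x̂₀ = (x_t − √(1−ᾱ_t) ε̂)/√ᾱ_t`, clipped to [−1, 1]. For `t* > 1` the
posterior mean `q(x_{t*−1} | x_{t*}, x̂₀)` is returned, with no noise
injection at the terminal step. A noise-matching helper picks `t*` by
equating `√(1−ᾱ_t)` (in data units) to an estimated noise level. Frames
larger than the training patch are processed as overlapped tiles blended
with a raised-cosine window; interior pixels agree with untiled inference
up to blending tolerance.

Baselines, applied channel-wise: 3×3 median filter; 5×5 normalised
Gaussian kernel (σ=1.1); Perona–Malik gradient anisotropic diffusion,
5 iterations, conductance 1, time step 0.125 (via SimpleITK).

## Evaluation

- **RMSE** over the ROI; axial quantities (R, φ) wrap differences into
  (−90°, 90°] — 179° and 1° are 2° apart.
- **nPSNR** `= 20·log₁₀(range/RMSE)` with the peak set to the reference's
  dynamic range inside the ROI (axial quantities use the fixed 180°
  support). The normalisation is recorded in the report. Zero RMSE maps to
  a `+inf` sentinel.
- **SSIM** via scikit-image (uniform 7×7 window, k₁=0.01, k₂=0.03,
  per-quantity dynamic range), reported in percent and averaged over the
  ROI; axial maps are compared on their wrapped-residual representation.
- **csd(φ)**: per pixel over the valid 5×5 neighbourhood, angles doubled
  (axial → circular), mean resultant length `R̄`, `csd = ½√(−2 ln R̄)` in
  degrees. `R̄ = 0` maps to a configurable cap (default 1e3°) instead of
  propagating infinities; pixels with fewer than 3 valid neighbours are
  flagged.
- **Wilcoxon rank-sum** between independent per-image score samples
  (two-sided; exact distribution for combined n ≤ 20 without ties, normal
  approximation with tie correction otherwise), each method against the
  designated reference.
- **Summaries** as q1/median/q3 with linear interpolation between order
  statistics (the rule is stated in the report).

Every metric is pinned to an independent brute-force per-pixel oracle on
16×16 instances in the test suite; the rank-sum test against full
enumeration of rank assignments.

A note on measuring denoising through `csd(φ)`: in the mixed-tissue
phantom the white-matter csd median carries a noise-independent boundary
term (neighbourhoods straddling tissue classes), which is identical for
single-shot and 16-shot data and therefore cannot respond to denoising;
the noise-driven headroom under default conditions is ~0.04°. The
denoising effect on azimuth dispersion is therefore measured on a
homogeneous white-matter frame (single class, constant orientation),
where the clean csd is ~0 and the observed csd is purely noise-driven.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by the package's own
choice: phantoms 48–128 px on a side (the full 512×384 camera frame is the
generator default for production use), Lu–Chipman bulk checks on 10⁴
random products, Monte-Carlo moment checks at 1e5–8e5 draws, diffusion
training on six 128×128 HQ frames with the desk preset, evaluation on two
held-out 64×64 LQ frames. Tie-break and degeneracy rules: decomposition
failures mask rather than raise; `acos` arguments clamped; azimuth
flagged where `sin R ≈ 0`; `csd` capped at zero resultant length;
normalisation bounds recorded so the [−1, 1] rescale is invertible.

## Known limitations

- The NumPy network trains at desk scale only; the full-scale preset is
  defined and runnable but intended for long offline runs.
- The phantom's noise amplification is milder than real depolarising brain
  tissue (see above), so absolute error magnitudes are not comparable to
  clinical acquisitions — orderings and scaling laws are.
- Single-pass improvements at the default noise level are real but small
  (a few percent of intensity RMSE); the t=1 correction amplitude is
  bounded by `√β₁` of the schedule.
- No physical calibration procedure: `G`, `A` are inputs.
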