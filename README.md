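# mupol — Mueller polarimetric image processing

Wide-field imaging Mueller polarimetry is a label-free optical modality
that, pointed at brain tissue, can reveal the in-plane orientation of white
matter fibre bundles — visual feedback a neurosurgeon could use to trace
tumour boundaries. The catch is noise: robust polarimetric parameters
conventionally require averaging many repeated intensity acquisitions,
which is incompatible with real-time use. `mupol` implements the full
processing chain for this problem, exercisable end-to-end on a synthetic
brain-tissue phantom:

- **Mueller derivation** — per pixel, the 4×4 Mueller matrix solves
  `M = A⁻¹ I G⁻¹`, where `I` is the 4×4 block of measured intensities for
  all generator/analyser polarisation state pairs and `G`, `A` are the
  calibration matrices. Implemented as closed-form vectorised batch
  algebra (adjugate 4×4 inverses), plus the forward model `I = A M G`
  used by the simulator.
- **Lu–Chipman decomposition** — `M = M_Δ · M_R · M_D` (depolariser,
  retarder, diattenuator), yielding the scalar biomarker maps:
  diattenuation `D`, depolarisation `Δ = 1 − |tr m_Δ|/3`, retardance
  `R = acos(√((M_R₂₂+M_R₃₃)² + (M_R₃₂−M_R₂₃)²) − 1)` and the optical-axis
  azimuth `φ = ½ atan2(−M_R₂₄, −M_R₄₃)` — the fibre-orientation proxy,
  axial on [0°, 180°).
- **Denoising diffusion model (PDDN)** — an ε-prediction, time-conditioned
  U-Net trained self-supervised on high-quality (multi-shot averaged)
  intensity patches; at inference a single-shot noisy frame is treated as
  the `t = 1` diffusion state and restored with one reverse
  posterior-mean step. Classical baselines (3×3 median, 5×5 Gaussian
  blur, Perona–Malik anisotropic diffusion) are included. The network and
  its reverse-mode autodiff run on NumPy inside the package — no deep
  learning framework required.
- **Synthetic phantom** — tissue-class maps (grey/white matter, tumour
  centre/infiltration), smooth fibre-orientation fields disrupted inside
  the lesion, per-class optics, pseudo-Gaussian shot noise and n-shot
  averaging (LQ n=1, HQ n=8, SHQ n=16).
- **Evaluation** — RMSE / nPSNR / SSIM with axial (180°-periodic)
  handling for angular maps, the local azimuth dispersion map `csd(φ)`
  (5×5 circular standard deviation), quartile summaries and the Wilcoxon
  rank-sum test.

## Worked example

```python
import numpy as np
from mupol import (CalibrationPair, derive_mueller, forward_intensities,
                   decompose, scalar_params, make_linear_retarder,
                   make_depolariser, make_diattenuator)

rng = np.random.default_rng(0)
M_true = (make_depolariser([0.85, 0.85, 0.8])
          @ make_linear_retarder(40.0, 30.0)      # fibre at 40 deg, 30 deg retardance
          @ make_diattenuator([0.1, 0.0, 0.0]))
calib = CalibrationPair(np.eye(4) + 0.05 * rng.normal(size=(4, 4)),
                        np.eye(4) + 0.05 * rng.normal(size=(4, 4)))

I = forward_intensities(M_true[None, None], calib)   # what the camera sees
M = derive_mueller(I, calib)                          # per-pixel M = A^-1 I G^-1
p = scalar_params(decompose(M))
print(p.D[0, 0], p.Delta[0, 0], p.R[0, 0], p.phi[0, 0])
```

Running `python examples/01_derive_and_decompose.py` prints:

```
max |M - M_true| after the round trip: 4.440892098500626e-16
diattenuation  D     = 0.1000   (true 0.10)
depolarisation Delta = 0.1667   (true 1 - 2.5/3 = 0.1667)
retardance     R     = 30.00 deg (true 30)
azimuth        phi   = 40.00 deg (true 40)
```

i.e. the derivation is exact to machine precision and the decomposition
returns the optics the scene was built from: 10% diattenuation, the
depolarisation index of the diag(0.85, 0.85, 0.8) depolariser, and the
retarder's retardance and fast-axis azimuth. The other scripts under
`examples/` walk through phantom generation and the 1/√n shot-averaging
law, smoke-scale diffusion training, and the metric/orientation-dispersion
suite, each printing the quantities it computes.

A thin CLI chains the same stages on files:

```bash
mupol phantom --out-dir out          # synthetic acquisition set
mupol derive --input out/avg_n1.tiff --calib out/calibration.npz --out M.tiff
mupol decompose --input out/avg_n1.tiff --calib out/calibration.npz --out-dir maps
mupol pipeline --seed 1 --out-dir run
```

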