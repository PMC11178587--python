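"""Synthetic brain-tissue phantom for polarimetric acquisitions.

The generator emulates the measurement chain of a wide-field imaging Mueller
polarimeter pointed at an ex-vivo brain sample:

1. a tissue-class map (background, grey matter, white matter, tumour centre,
   tumour infiltration) drawn as smooth random blobs with a lesion disc;
2. a fibre-orientation field: a smooth low-frequency azimuth flow in white
   matter, larger angular dispersion in grey matter, uniform-random
   orientations in the tumour centre (fibre architecture destroyed) and
   intermediate dispersion in the infiltration rim;
3. per-pixel ground-truth Mueller matrices composed as
   M = M_Delta(class) . LR(theta(pixel), delta(class)) . M_D(class);
4. forward imaging I = A M G through a calibration pair (by default a small
   random perturbation of the identity, condition number < 10, so the
   linear-system inversion is exercised nontrivially);
5. pseudo-Gaussian zero-mean acquisition noise added in the intensity
   domain, modelled as a two-component Gaussian scale mixture;
6. n-shot arithmetic averaging for the acquisition regimes LQ (n=1),
   HQ (n=8) and SHQ (n=16).

The default noise level sigma=0.012 (normalised intensity units, M11 = 1)
places the single-shot error at the magnitude reported for low-quality
acquisitions of the real instrument; the mixture tail (kappa, w) makes the
noise bell-shaped but slightly heavier-tailed than Normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .luchipman import (ParameterMaps, decompose, make_diattenuator,
                        make_depolariser, make_linear_retarder, scalar_params)
from .mueller import CalibrationPair, forward_intensities, normalise_m11

__all__ = [
    "CLASS_LABELS", "ClassOptics", "PhantomSpec", "AcquisitionSet",
    "make_phantom", "sample_noise", "average_shots", "random_calibration",
]

CLASS_LABELS = {
    "background": 0,
    "grey_matter": 1,
    "white_matter": 2,
    "tumour_centre": 3,
    "tumour_infiltration": 4,
}


@dataclass
class ClassOptics:
    """Optical parameters of one tissue class.

    delta_deg: linear retardance (degrees); white matter is strongly
    birefringent through myelin, grey matter and tumour much less.
    depol_diag: diagonal (a, b, c) of the depolariser, entries in (0, 1].
    d_mag: diattenuation magnitude (< 1); the diattenuation axis follows the
    local fibre orientation.
    jitter_deg: per-pixel axial dispersion added to the smooth orientation
    flow (``None`` = orientation uniform at random, as in a destroyed
    tumour core).
    """

    delta_deg: float
    depol_diag: tuple[float, float, float]
    d_mag: float
    jitter_deg: float | None


DEFAULT_OPTICS: dict[str, ClassOptics] = {
    # background: almost fully depolarising, no meaningful orientation
    "background": ClassOptics(0.0, (0.04, 0.04, 0.04), 0.0, None),
    "grey_matter": ClassOptics(10.0, (0.70, 0.70, 0.65), 0.03, 14.0),
    "white_matter": ClassOptics(40.0, (0.85, 0.85, 0.80), 0.05, 3.0),
    "tumour_centre": ClassOptics(8.0, (0.60, 0.60, 0.55), 0.03, None),
    "tumour_infiltration": ClassOptics(24.0, (0.725, 0.725, 0.675), 0.04, 30.0),
}


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic acquisition."""

    H: int = 384
    W: int = 512
    optics: dict[str, ClassOptics] = field(
        default_factory=lambda: dict(DEFAULT_OPTICS))
    sigma: float = 0.012        # acquisition noise std, normalised intensity units
    kappa: float = 0.05         # contamination fraction of the wide component
    w: float = 3.0              # contamination width multiplier
    n_shots: int = 16
    averages: tuple[int, ...] = (1, 8, 16)
    seed: int = 0
    class_map: np.ndarray | None = None     # explicit label map overrides blobs
    orientation: np.ndarray | None = None   # explicit azimuth field (deg)
    calib: CalibrationPair | None = None
    lesion: bool = True

    def validate(self) -> None:
        for name, o in self.optics.items():
            if name not in CLASS_LABELS:
                raise ValueError(f"unknown tissue class {name!r}")
            if not (0 <= o.delta_deg < 180):
                raise ValueError(f"{name}: retardance must be in [0, 180) deg")
            if not all(0 < a <= 1 for a in o.depol_diag):
                raise ValueError(f"{name}: depolariser diagonal must be in (0, 1]")
            if not (0 <= o.d_mag < 1):
                raise ValueError(f"{name}: diattenuation must be < 1")
        if self.sigma < 0 or not (0 <= self.kappa < 1) or self.w <= 1:
            raise ValueError("invalid noise parameters")


@dataclass
class AcquisitionSet:
    """Ground truth plus simulated shots and their running averages."""

    ground_truth_M: np.ndarray          # (H, W, 4, 4)
    gt_params: ParameterMaps
    shots: list[np.ndarray]             # each (H, W, 4, 4)
    averaged: dict[int, np.ndarray]     # n -> (H, W, 4, 4)
    roi: np.ndarray                     # (H, W) bool, excludes background
    class_map: np.ndarray               # (H, W) int labels
    orientation: np.ndarray             # (H, W) deg, axial ground truth
    calib: CalibrationPair


def sample_noise(shape, sigma: float, kappa: float = 0.0, w: float = 3.0,
                 rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Pseudo-Gaussian acquisition noise: a zero-mean Gaussian scale mixture.

    With probability 1-kappa a draw is N(0, sigma^2), with probability kappa
    it is N(0, (w*sigma)^2); kappa=0 gives a pure Gaussian.  The mixture is
    symmetric, zero-mean and bell-shaped with variance
    sigma^2 (1 - kappa + kappa w^2) and positive excess kurtosis for
    kappa > 0 — the empirical signature of polarimetric sensor noise.
    """
    if sigma < 0 or not (0 <= kappa < 1) or w <= 1:
        raise ValueError("require sigma >= 0, kappa in [0,1), w > 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if sigma == 0:
        return np.zeros(shape)
    eps = rng.normal(0.0, sigma, size=shape)
    if kappa > 0:
        wide = rng.random(shape) < kappa
        eps = np.where(wide, rng.normal(0.0, w * sigma, size=shape), eps)
    return eps


def average_shots(shots: list[np.ndarray], n: int) -> np.ndarray:
    """Pixelwise arithmetic mean of the first ``n`` shots."""
    if n > len(shots):
        raise ValueError(f"requested n={n} but only {len(shots)} shots available")
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.mean(shots[:n], axis=0)


def random_calibration(rng: np.random.Generator, scale: float = 0.1,
                       cond_max: float = 10.0) -> CalibrationPair:
    """Generator/analyser pair: identity plus a small random perturbation,
    re-drawn until both condition numbers fall below ``cond_max``."""
    while True:
        G = np.eye(4) + scale * rng.normal(size=(4, 4))
        A = np.eye(4) + scale * rng.normal(size=(4, 4))
        if max(np.linalg.cond(G), np.linalg.cond(A)) < cond_max:
            return CalibrationPair(G, A, cond_max=1e8)


def _smooth_field(rng: np.random.Generator, H: int, W: int,
                  sigma_px: float) -> np.ndarray:
    """Unit-variance low-frequency Gaussian random field."""
    f = ndimage.gaussian_filter(rng.normal(size=(H, W)), sigma_px, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def _default_class_map(rng: np.random.Generator, H: int, W: int,
                       lesion: bool) -> np.ndarray:
    """Smooth random blobs: GM/WM split by thresholded smoothed noise, a
    background margin, and (optionally) a lesion disc with infiltration rim
    placed inside white matter."""
    labels = np.full((H, W), CLASS_LABELS["grey_matter"], dtype=int)
    split = _smooth_field(rng, H, W, sigma_px=min(H, W) / 6)
    labels[split > -0.1] = CLASS_LABELS["white_matter"]

    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2, (W - 1) / 2
    rr = np.sqrt(((yy - cy) / (H / 2)) ** 2 + ((xx - cx) / (W / 2)) ** 2)
    edge = _smooth_field(rng, H, W, sigma_px=min(H, W) / 8)
    labels[rr + 0.15 * edge > 0.92] = CLASS_LABELS["background"]

    if lesion:
        wm = labels == CLASS_LABELS["white_matter"]
        if wm.any():
            idx = np.argwhere(wm)
            ly, lx = idx[rng.integers(len(idx))]
        else:
            ly, lx = int(cy), int(cx)
        r_core = 0.12 * min(H, W)
        r_inf = 0.2 * min(H, W)
        dist = np.sqrt((yy - ly) ** 2 + (xx - lx) ** 2)
        fg = labels != CLASS_LABELS["background"]
        labels[(dist <= r_inf) & fg] = CLASS_LABELS["tumour_infiltration"]
        labels[(dist <= r_core) & fg] = CLASS_LABELS["tumour_centre"]
    return labels


def _orientation_field(rng: np.random.Generator, H: int, W: int,
                       class_map: np.ndarray, optics: dict[str, ClassOptics],
                       jitter_corr_px: float = 1.5) -> np.ndarray:
    """Axial azimuth field in degrees on [0, 180).

    A smooth base flow (half the argument of a low-pass-filtered complex
    field) is perturbed per class by a spatially correlated Gaussian axial
    jitter scaled to the class dispersion — fibre dispersion varies
    continuously at the ~50 um pixel scale, it is not white — or replaced by
    per-pixel uniform orientations where ``jitter_deg`` is None (destroyed
    architecture in the tumour core).
    """
    z = (_smooth_field(rng, H, W, min(H, W) / 5)
         + 1j * _smooth_field(rng, H, W, min(H, W) / 5))
    base = np.degrees(np.angle(z)) / 2.0 % 180.0
    theta = base.copy()
    for name, lab in CLASS_LABELS.items():
        sel = class_map == lab
        if not sel.any():
            continue
        o = optics[name]
        if o.jitter_deg is None:
            theta[sel] = rng.uniform(0.0, 180.0, size=sel.sum())
        elif o.jitter_deg > 0:
            j = ndimage.gaussian_filter(rng.normal(size=(H, W)),
                                        jitter_corr_px, mode="reflect")
            j *= o.jitter_deg / max(j.std(), 1e-12)
            theta[sel] = (theta[sel] + j[sel]) % 180.0
    return theta


def make_phantom(spec: PhantomSpec) -> AcquisitionSet:
    """Simulate one acquisition session from a phantom specification."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.H, spec.W

    class_map = (spec.class_map if spec.class_map is not None
                 else _default_class_map(rng, H, W, spec.lesion))
    theta = (spec.orientation if spec.orientation is not None
             else _orientation_field(rng, H, W, class_map, spec.optics))

    delta = np.zeros((H, W))
    diag = np.zeros((H, W, 3))
    dmag = np.zeros((H, W))
    for name, lab in CLASS_LABELS.items():
        sel = class_map == lab
        o = spec.optics[name]
        delta[sel] = o.delta_deg
        diag[sel] = o.depol_diag
        dmag[sel] = o.d_mag

    # diattenuation axis aligned with the fibre orientation
    two_th = np.radians(2 * theta)
    dvec = dmag[..., None] * np.stack(
        [np.cos(two_th), np.sin(two_th), np.zeros_like(two_th)], axis=-1)

    M = (make_depolariser(diag)
         @ make_linear_retarder(theta, delta)
         @ make_diattenuator(dvec))

    calib = spec.calib if spec.calib is not None else random_calibration(rng)
    clean = forward_intensities(M, calib)

    shots = []
    for _ in range(spec.n_shots):
        eps = sample_noise(clean.shape, spec.sigma, spec.kappa, spec.w, rng)
        shots.append(clean + eps)
    averaged = {n: average_shots(shots, n)
                for n in spec.averages if n <= spec.n_shots}

    roi = class_map != CLASS_LABELS["background"]
    Mn, valid = normalise_m11(M)
    gt_params = scalar_params(decompose(Mn, valid))

    return AcquisitionSet(ground_truth_M=M, gt_params=gt_params, shots=shots,
                          averaged=averaged, roi=roi, class_map=class_map,
                          orientation=theta, calib=calib)
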