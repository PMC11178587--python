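"""Lu-Chipman product decomposition and scalar polarimetric parameters.

A (normalised) Mueller matrix is factorised per pixel into the product of a
depolariser, a retarder and a diattenuator,

    M = M_Delta . M_R . M_D,

from which the clinically relevant scalar maps follow:

* total diattenuation        D   = |(M_D12, M_D13, M_D14)|            in [0, 1]
* total depolarisation       Delta = 1 - |tr m_Delta| / 3             in [0, 1]
* scalar retardance          R   = acos(sqrt((M_R22+M_R33)^2
                                   + (M_R32-M_R23)^2) - 1)            in [0, 180] deg
* azimuth of the optical axis  phi, the fast-axis orientation, an axial
  quantity on [0, 180) deg recovered from (M_R24, M_R43) with a
  quadrant-aware arctangent halved.

For brain tissue the retardance is driven by the birefringence of myelinated
fibres and phi is a proxy for the in-plane fibre-bundle direction.

The decomposition sequence is the classical one: the diattenuator is peeled
off first, the depolariser is the signed symmetric square root of
m' m'^T (sign from det m'), and the retarder is what remains.  Degenerate
pixels (background noise pushing |d| >= 1, singular depolarisers, non-finite
entries) are masked in ``valid``, never raised, so full frames with noisy
off-sample regions survive processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LuChipmanFactors",
    "ParameterMaps",
    "decompose",
    "scalar_params",
    "make_linear_retarder",
    "make_diattenuator",
    "make_depolariser",
]


@dataclass
class LuChipmanFactors:
    """Per-pixel factor triplet with reconstruction contract M = M_Delta M_R M_D."""

    M_Delta: np.ndarray  # (..., 4, 4) depolariser
    M_R: np.ndarray      # (..., 4, 4) retarder
    M_D: np.ndarray      # (..., 4, 4) diattenuator
    valid: np.ndarray    # (...) bool

    def reconstruct(self) -> np.ndarray:
        return self.M_Delta @ self.M_R @ self.M_D


@dataclass
class ParameterMaps:
    """Scalar maps: D, Delta dimensionless in [0,1]; R in [0,180] deg;
    phi axial in [0,180) deg.  ``phi_valid`` additionally flags pixels where
    sin(R) ~ 0 and the azimuth is undefined."""

    D: np.ndarray
    Delta: np.ndarray
    R: np.ndarray
    phi: np.ndarray
    valid: np.ndarray
    phi_valid: np.ndarray


def make_linear_retarder(theta_deg, delta_deg) -> np.ndarray:
    """Mueller matrix of a linear retarder, fast axis at azimuth ``theta_deg``
    and retardance ``delta_deg``.  Broadcasts over array inputs, returning
    (..., 4, 4)."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    de = np.deg2rad(np.asarray(delta_deg, dtype=float))
    c2, s2 = np.cos(2 * th), np.sin(2 * th)
    cd, sd = np.broadcast_arrays(*np.broadcast_arrays(np.cos(de), np.sin(de)))
    c2, s2, cd, sd = np.broadcast_arrays(c2, s2, cd, sd)
    z = np.zeros_like(c2)
    o = np.ones_like(c2)
    rows = [
        [o, z, z, z],
        [z, c2**2 + s2**2 * cd, c2 * s2 * (1 - cd), -s2 * sd],
        [z, c2 * s2 * (1 - cd), s2**2 + c2**2 * cd, c2 * sd],
        [z, s2 * sd, -c2 * sd, cd],
    ]
    m = np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)
    return m


def make_diattenuator(dvec) -> np.ndarray:
    """Canonical diattenuator from a diattenuation vector, |dvec| < 1.

    First row is (1, d^T) and first column its transpose; the 3x3 block is
    sqrt(1-D^2) I + (1 - sqrt(1-D^2)) dhat dhat^T.  Broadcasts over leading
    axes of a (..., 3) input.
    """
    d = np.asarray(dvec, dtype=float)
    if d.shape[-1] != 3:
        raise ValueError("diattenuation vector must have 3 components")
    D = np.linalg.norm(d, axis=-1)
    if np.any(D >= 1):
        raise ValueError("diattenuation magnitude must be < 1")
    sq = np.sqrt(1 - D**2)
    dhat = np.where(D[..., None] > 0, d / np.maximum(D[..., None], 1e-300), 0.0)
    eye3 = np.eye(3)
    m3 = sq[..., None, None] * eye3 + (1 - sq)[..., None, None] * (
        dhat[..., :, None] * dhat[..., None, :]
    )
    out = np.zeros(d.shape[:-1] + (4, 4))
    out[..., 0, 0] = 1.0
    out[..., 0, 1:] = d
    out[..., 1:, 0] = d
    out[..., 1:, 1:] = m3
    return out


def make_depolariser(diag) -> np.ndarray:
    """Diagonal depolariser diag(1, a, b, c) with a, b, c in (0, 1]."""
    d = np.asarray(diag, dtype=float)
    if d.shape[-1] != 3:
        raise ValueError("depolariser diagonal must have 3 components")
    out = np.zeros(d.shape[:-1] + (4, 4))
    out[..., 0, 0] = 1.0
    for i in range(3):
        out[..., i + 1, i + 1] = d[..., i]
    return out


def decompose(M: np.ndarray, valid: np.ndarray | None = None,
              eig_tol: float = 1e-9) -> LuChipmanFactors:
    """Polar (product) decomposition M = M_Delta M_R M_D, batched over pixels.

    Parameters
    ----------
    M:
        (..., 4, 4) Mueller image, M11-normalised where valid.
    valid:
        Optional incoming validity mask; failures are AND-ed into it.
    eig_tol:
        Eigenvalues of m' m'^T below ``-eig_tol`` mark the pixel invalid;
        small negatives within tolerance are clipped to zero.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[-2:] != (4, 4):
        raise ValueError("expected trailing (4, 4) Mueller blocks")
    batch = M.shape[:-2]
    ok = np.ones(batch, dtype=bool) if valid is None else np.asarray(valid, bool).copy()
    ok &= np.isfinite(M).all(axis=(-2, -1))

    Msafe = np.where(ok[..., None, None], M, np.eye(4))

    # 1) diattenuator from the first row
    d = Msafe[..., 0, 1:]
    D = np.linalg.norm(d, axis=-1)
    ok &= D < 1.0
    d = np.where(ok[..., None], d, 0.0)
    D = np.where(ok, D, 0.0)
    M_D = make_diattenuator(d)

    # analytic diattenuator inverse: (1/(1-D^2)) [[1, -d^T], [-d, ...]]
    sq = np.sqrt(1 - D**2)
    dhat = np.where(D[..., None] > 0, d / np.maximum(D[..., None], 1e-300), 0.0)
    inv3 = (1.0 / sq)[..., None, None] * np.eye(3) + (
        1.0 / (1 - D**2) - 1.0 / sq
    )[..., None, None] * (dhat[..., :, None] * dhat[..., None, :])
    M_D_inv = np.zeros_like(M_D)
    M_D_inv[..., 0, 0] = 1.0 / (1 - D**2)
    M_D_inv[..., 0, 1:] = -d / (1 - D**2)[..., None]
    M_D_inv[..., 1:, 0] = -d / (1 - D**2)[..., None]
    M_D_inv[..., 1:, 1:] = inv3
    Mp = Msafe @ M_D_inv

    # 2) depolariser: signed symmetric square root of m' m'^T
    mp = Mp[..., 1:, 1:]
    S = mp @ np.swapaxes(mp, -1, -2)
    lam, V = np.linalg.eigh(S)
    ok &= lam[..., 0] > -eig_tol
    lam = np.clip(lam, 0.0, None)
    detmp = np.linalg.det(mp)
    sign = np.where(detmp < 0, -1.0, 1.0)
    mD3 = (V * np.sqrt(lam)[..., None, :]) @ np.swapaxes(V, -1, -2)
    mDelta = sign[..., None, None] * mD3

    M_Delta = np.zeros_like(M)
    M_Delta[..., 0, 0] = 1.0
    M_Delta[..., 1:, 0] = Mp[..., 1:, 0]  # polarizance of the depolariser
    M_Delta[..., 1:, 1:] = mDelta

    # 3) retarder: m_R = m_Delta^-1 m'
    detD = np.linalg.det(mDelta)
    ok &= np.abs(detD) > 1e-12
    mDelta_safe = np.where(ok[..., None, None], mDelta, np.eye(3))
    mR = np.linalg.solve(mDelta_safe, np.where(ok[..., None, None], mp, np.eye(3)))
    M_R = np.zeros_like(M)
    M_R[..., 0, 0] = 1.0
    M_R[..., 1:, 1:] = mR

    return LuChipmanFactors(M_Delta=M_Delta, M_R=M_R, M_D=M_D, valid=ok)


def scalar_params(f: LuChipmanFactors, *, delta_literal_4x4: bool = False,
                  phi_sin_tol: float = 1e-6) -> ParameterMaps:
    """Scalar parameter maps from decomposed factors.

    ``delta_literal_4x4`` switches the depolarisation to the literal 4x4
    trace form 1 - |tr M_Delta|/3 (which can exceed 1); the default uses the
    3x3 depolariser submatrix, guaranteeing Delta in [0, 1].

    The azimuth is computed as ``0.5 * atan2(-M_R24, -M_R43)`` wrapped into
    [0, 180): the quadrant-aware form of the half-angle arctangent that, with
    this package's retarder sign convention, returns the fast-axis azimuth
    itself.  Pixels with sin(R) ~ 0 have an undefined optical axis and are
    flagged out of ``phi_valid``.
    """
    MD, MR, MDel = f.M_D, f.M_R, f.M_Delta
    D = np.sqrt(MD[..., 0, 1] ** 2 + MD[..., 0, 2] ** 2 + MD[..., 0, 3] ** 2)

    if delta_literal_4x4:
        tr = np.trace(MDel, axis1=-2, axis2=-1)
    else:
        tr = np.trace(MDel[..., 1:, 1:], axis1=-2, axis2=-1)
    Delta = 1.0 - np.abs(tr) / 3.0

    arg = np.sqrt(
        (MR[..., 1, 1] + MR[..., 2, 2]) ** 2 + (MR[..., 2, 1] - MR[..., 1, 2]) ** 2
    ) - 1.0
    R = np.degrees(np.arccos(np.clip(arg, -1.0, 1.0)))

    phi = np.degrees(0.5 * np.arctan2(-MR[..., 1, 3], -MR[..., 3, 2])) % 180.0
    phi_valid = f.valid & (np.abs(np.sin(np.radians(R))) > phi_sin_tol)

    return ParameterMaps(D=D, Delta=Delta, R=R, phi=phi,
                         valid=f.valid.copy(), phi_valid=phi_valid)
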