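"""Per-pixel Stokes-Mueller linear algebra.

A wide-field imaging Mueller polarimeter probes a sample with four
polarisation states (generator ``G``) and analyses the backscattered light
with four states (analyser ``A``), producing a 4x4 intensity block ``I`` per
pixel.  The sample's Mueller matrix follows from the linear system

    M = A^-1 I G^-1

and the forward imaging model is ``I = A M G``.  Both maps are evaluated as
closed-form vectorised batch algebra: the 4x4 inverses use an adjugate
(cofactor) expansion so the whole image is processed with constant-size
matrix arithmetic and no per-pixel Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationPair",
    "derive_mueller",
    "forward_intensities",
    "normalise_m11",
    "inv4x4",
    "channels_to_blocks",
    "blocks_to_channels",
]

#: 16 polarisation-state channels are ordered row-major over
#: (generator state g, analyser state a): channel = 4*(a-1) + (g-1),
#: i.e. flattening the 4x4 intensity block I[a, g] in C order.
CHANNEL_ORDER = "row-major (analyser, generator)"


def channels_to_blocks(x: np.ndarray) -> np.ndarray:
    """View an H x W x 16 channel stack as H x W x 4 x 4 blocks."""
    if x.shape[-1] != 16:
        raise ValueError(f"expected 16 channels, got {x.shape[-1]}")
    return x.reshape(x.shape[:-1] + (4, 4))


def blocks_to_channels(x: np.ndarray) -> np.ndarray:
    """View an ... x 4 x 4 block tensor as ... x 16 channels."""
    if x.shape[-2:] != (4, 4):
        raise ValueError(f"expected trailing 4x4 blocks, got {x.shape[-2:]}")
    return x.reshape(x.shape[:-2] + (16,))


@dataclass
class CalibrationPair:
    """Polarisation state generator/analyser matrices, global or per-pixel.

    Parameters
    ----------
    G, A:
        Shape (4, 4) for a single global calibration or (H, W, 4, 4) for a
        pixel-wise one.  Every 4x4 block must be invertible with condition
        number below ``cond_max``.
    """

    G: np.ndarray
    A: np.ndarray
    cond_max: float = 1e8
    mode: str = field(init=False)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.G.shape != self.A.shape:
            raise ValueError("G and A must have the same shape")
        if self.G.shape == (4, 4):
            self.mode = "global"
        elif self.G.ndim == 4 and self.G.shape[-2:] == (4, 4):
            self.mode = "per-pixel"
        else:
            raise ValueError(f"calibration must be (4,4) or (H,W,4,4), got {self.G.shape}")
        for name, mat in (("generator", self.G), ("analyser", self.A)):
            self._check(name, mat)

    def _check(self, name: str, mat: np.ndarray) -> None:
        cond = np.linalg.cond(mat)
        bad = ~np.isfinite(cond) | (cond > self.cond_max)
        if np.any(bad):
            if self.mode == "global":
                raise np.linalg.LinAlgError(f"singular {name} matrix")
            ij = np.argwhere(bad)[0]
            raise np.linalg.LinAlgError(
                f"singular {name} matrix at pixel ({ij[0]}, {ij[1]})"
            )

    @classmethod
    def identity(cls) -> "CalibrationPair":
        return cls(np.eye(4), np.eye(4))


def inv4x4(m: np.ndarray) -> np.ndarray:
    """Closed-form inverse of batched 4x4 matrices via cofactor expansion.

    Exactly vectorisable: every entry of the adjugate is a polynomial in the
    entries of ``m``, so the inverse of an (..., 4, 4) stack costs O(batch)
    with constant 4x4 algebra.  ``numpy.linalg.inv`` serves as the oracle in
    the tests, never here.
    """
    m = np.asarray(m, dtype=float)
    if m.shape[-2:] != (4, 4):
        raise ValueError("inv4x4 expects trailing (4, 4)")
    a = np.moveaxis(m, (-2, -1), (0, 1))  # a[i, j, ...]

    # 2x2 minors of rows 2,3 (0-based): s[kl] = a2k*a3l - a2l*a3k
    def minor2(r0, r1, c0, c1):
        return a[r0, c0] * a[r1, c1] - a[r0, c1] * a[r1, c0]

    s01 = minor2(2, 3, 0, 1)
    s02 = minor2(2, 3, 0, 2)
    s03 = minor2(2, 3, 0, 3)
    s12 = minor2(2, 3, 1, 2)
    s13 = minor2(2, 3, 1, 3)
    s23 = minor2(2, 3, 2, 3)

    # cofactors of rows 0,1 via Laplace along rows 2,3
    c00 = a[1, 1] * s23 - a[1, 2] * s13 + a[1, 3] * s12
    c01 = -(a[1, 0] * s23 - a[1, 2] * s03 + a[1, 3] * s02)
    c02 = a[1, 0] * s13 - a[1, 1] * s03 + a[1, 3] * s01
    c03 = -(a[1, 0] * s12 - a[1, 1] * s02 + a[1, 2] * s01)

    c10 = -(a[0, 1] * s23 - a[0, 2] * s13 + a[0, 3] * s12)
    c11 = a[0, 0] * s23 - a[0, 2] * s03 + a[0, 3] * s02
    c12 = -(a[0, 0] * s13 - a[0, 1] * s03 + a[0, 3] * s01)
    c13 = a[0, 0] * s12 - a[0, 1] * s02 + a[0, 2] * s01

    t01 = minor2(0, 1, 0, 1)
    t02 = minor2(0, 1, 0, 2)
    t03 = minor2(0, 1, 0, 3)
    t12 = minor2(0, 1, 1, 2)
    t13 = minor2(0, 1, 1, 3)
    t23 = minor2(0, 1, 2, 3)

    c20 = a[3, 1] * t23 - a[3, 2] * t13 + a[3, 3] * t12
    c21 = -(a[3, 0] * t23 - a[3, 2] * t03 + a[3, 3] * t02)
    c22 = a[3, 0] * t13 - a[3, 1] * t03 + a[3, 3] * t01
    c23 = -(a[3, 0] * t12 - a[3, 1] * t02 + a[3, 2] * t01)

    c30 = -(a[2, 1] * t23 - a[2, 2] * t13 + a[2, 3] * t12)
    c31 = a[2, 0] * t23 - a[2, 2] * t03 + a[2, 3] * t02
    c32 = -(a[2, 0] * t13 - a[2, 1] * t03 + a[2, 3] * t01)
    c33 = a[2, 0] * t12 - a[2, 1] * t02 + a[2, 2] * t01

    det = a[0, 0] * c00 + a[0, 1] * c01 + a[0, 2] * c02 + a[0, 3] * c03
    adjT = np.stack(
        [
            np.stack([c00, c10, c20, c30], axis=0),
            np.stack([c01, c11, c21, c31], axis=0),
            np.stack([c02, c12, c22, c32], axis=0),
            np.stack([c03, c13, c23, c33], axis=0),
        ],
        axis=0,
    )  # adjT[i, j, ...] = cofactor[j, i] = adjugate
    with np.errstate(divide="ignore", invalid="ignore"):
        out = adjT / det
    return np.moveaxis(out, (0, 1), (-2, -1))


def _as_blocks(I: np.ndarray) -> np.ndarray:
    I = np.asarray(I, dtype=float)
    if I.shape[-1] == 16:
        return channels_to_blocks(I)
    if I.shape[-2:] == (4, 4):
        return I
    raise ValueError(f"expected trailing 16 channels or 4x4 blocks, got shape {I.shape}")


def derive_mueller(I: np.ndarray, calib: CalibrationPair) -> np.ndarray:
    """Solve M = A^-1 I G^-1 per pixel.

    Parameters
    ----------
    I:
        Intensity tensor, H x W x 16 (channels-last) or H x W x 4 x 4.
    calib:
        Generator/analyser pair; global calibrations broadcast over pixels.

    Returns
    -------
    H x W x 4 x 4 Mueller image.
    """
    Ib = _as_blocks(I)
    Ainv = inv4x4(calib.A)
    Ginv = inv4x4(calib.G)
    return Ainv @ Ib @ Ginv


def forward_intensities(M: np.ndarray, calib: CalibrationPair) -> np.ndarray:
    """Forward imaging model I = A M G per pixel (H x W x 4 x 4 in and out)."""
    Mb = _as_blocks(M)
    return calib.A @ Mb @ calib.G


def normalise_m11(M: np.ndarray, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Divide each 4x4 block by its M11 element (index [0, 0]).

    Normalisation makes diattenuation and depolarisation dimensionless, the
    standard polarimetric convention.  Blocks with \\|M11\\| <= eps are flagged
    invalid and left untouched.

    Returns
    -------
    (normalised Mueller image, validity mask).
    """
    Mb = _as_blocks(M).copy()
    m11 = Mb[..., 0, 0]
    valid = np.abs(m11) > eps
    Mb[valid] = Mb[valid] / m11[valid, None, None]
    return Mb, valid
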