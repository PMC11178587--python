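"""Deterministic denoising baselines applied channel-wise to the 16 states.

MEDF: 3x3 median filter.  GBLR: 5x5 normalised Gaussian kernel (sigma 1.1,
the conventional width for a radius-2 kernel).  GRAD: Perona-Malik gradient
anisotropic diffusion, 5 iterations with conductance 1 (via SimpleITK).
"""

from __future__ import annotations

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = ["baseline_filter", "gaussian_kernel5", "mask_reflections"]


def gaussian_kernel5(sigma: float = 1.1) -> np.ndarray:
    """5x5 Gaussian kernel normalised to unit DC gain."""
    r = np.arange(-2, 3)
    g = np.exp(-(r ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def _grad_channel(img: np.ndarray, iterations: int, conductance: float,
                  time_step: float) -> np.ndarray:
    im = sitk.GetImageFromArray(img.astype(np.float64))
    f = sitk.GradientAnisotropicDiffusionImageFilter()
    f.SetNumberOfIterations(iterations)
    f.SetConductanceParameter(conductance)
    f.SetTimeStep(time_step)
    return sitk.GetArrayFromImage(f.Execute(im))


def baseline_filter(x: np.ndarray, method: str, params: dict | None = None) -> np.ndarray:
    """Apply a channel-wise baseline filter to an H x W x C stack.

    ``method`` is one of MEDF, GBLR, GRAD (case-insensitive); 2-D inputs are
    treated as a single channel.
    """
    params = dict(params or {})
    x = np.asarray(x, float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[..., None]
    if x.ndim == 4 and x.shape[-2:] == (4, 4):
        out = baseline_filter(x.reshape(x.shape[:2] + (16,)), method, params)
        return out.reshape(x.shape)
    if x.ndim != 3:
        raise ValueError(f"expected H x W x C stack, got shape {x.shape}")

    m = method.upper()
    out = np.empty_like(x)
    if m == "MEDF":
        size = params.get("size", 3)
        for c in range(x.shape[-1]):
            out[..., c] = ndimage.median_filter(x[..., c], size=size,
                                                mode="reflect")
    elif m == "GBLR":
        k = gaussian_kernel5(params.get("sigma", 1.1))
        for c in range(x.shape[-1]):
            out[..., c] = ndimage.correlate(x[..., c], k, mode="reflect")
    elif m == "GRAD":
        it = params.get("iterations", 5)
        cond = params.get("conductance", 1.0)
        ts = params.get("time_step", 0.125)
        for c in range(x.shape[-1]):
            out[..., c] = _grad_channel(x[..., c], it, cond, ts)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return out[..., 0] if squeeze else out


def mask_reflections(x: np.ndarray, threshold: float, *,
                     quantile: bool = False, dilation: int = 1) -> np.ndarray:
    """Boolean mask of supra-threshold specular reflections.

    A pixel is masked when its maximum across the 16 channels exceeds the
    threshold (given in intensity units, or as a quantile of that per-pixel
    maximum when ``quantile``); the mask is then dilated by ``dilation``
    pixels so filter supports touching a reflection are excluded too.
    """
    x = np.asarray(x, float)
    if x.ndim == 4 and x.shape[-2:] == (4, 4):
        x = x.reshape(x.shape[:2] + (16,))
    peak = x.max(axis=-1) if x.ndim == 3 else x
    if quantile:
        if not (0 <= threshold <= 1):
            raise ValueError("quantile threshold must be in [0, 1]")
        if threshold >= 1.0:
            return np.zeros(peak.shape, bool)  # nothing is supra-maximum
        threshold = np.quantile(peak, threshold)
    mask = peak > threshold
    if dilation > 0 and mask.any():
        st = np.ones((2 * dilation + 1, 2 * dilation + 1), bool)
        mask = ndimage.binary_dilation(mask, structure=st)
    return mask
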