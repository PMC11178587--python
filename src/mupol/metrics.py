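"""Image-quality scores and circular statistics for polarimetric maps.

Linear quantities (intensities, Mueller coefficients, D, Delta) use ordinary
RMSE / nPSNR / SSIM.  Angular maps are *axial* — an azimuth of 179 deg and
1 deg are 2 deg apart, not 178 — so their errors wrap into (-90, 90] deg and
their dispersion statistics double the angles first (the standard treatment
for orientation data on [0, 180)).

nPSNR is a normalised peak signal-to-noise ratio,
20 log10(range / RMSE), where the peak is the dynamic range of the reference
quantity inside the ROI (axial quantities use the fixed 180 deg support);
this makes scores comparable across quantities with different units.  The
normalisation is recorded in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage, stats
from skimage.metrics import structural_similarity

__all__ = ["rmse", "npsnr", "ssim", "csd_map", "wilcoxon_ranksum",
           "summarize", "MetricReport", "wrap_axial_difference"]


def wrap_axial_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Difference of axial angles (degrees) wrapped into (-90, 90]."""
    d = (np.asarray(a, float) - np.asarray(b, float)) % 180.0
    return np.where(d > 90.0, d - 180.0, d)


def _check_roi(x, y, roi):
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch between compared maps")
    roi = (np.ones(x.shape[:2], bool) if roi is None
           else np.asarray(roi, bool))
    if not roi.any():
        raise ValueError("empty ROI")
    return x, y, roi


def rmse(x, y, roi=None, circular: bool = False) -> float:
    """Root-mean-squared error over the ROI; axial wrap when ``circular``."""
    x, y, roi = _check_roi(x, y, roi)
    d = wrap_axial_difference(x, y) if circular else x - y
    d = d[roi]
    return float(np.sqrt(np.mean(d ** 2)))


def npsnr(x, ref, roi=None, circular: bool = False) -> float:
    """Normalised PSNR in decibels: 20 log10(range_ref / RMSE)."""
    x, ref, roi_ = _check_roi(x, ref, roi)
    if circular:
        rng = 180.0
    else:
        r = ref[roi_]
        rng = float(r.max() - r.min())
        if rng == 0:
            raise ValueError("reference has zero dynamic range in ROI")
    e = rmse(x, ref, roi, circular=circular)
    if e == 0:
        return float("inf")
    return float(20.0 * np.log10(rng / e))


def ssim(x, ref, roi=None, *, win_size: int = 7, k1: float = 0.01,
         k2: float = 0.03, data_range: float | None = None,
         circular: bool = False) -> float:
    """Mean local structural similarity over the ROI, in percent.

    Axial maps are compared on their wrapped residual representation
    (reference plus wrapped difference), so 0 and 180 deg count as identical.
    """
    x, ref, roi_ = _check_roi(x, ref, roi)
    if circular:
        x = ref + wrap_axial_difference(x, ref)
        rng = 180.0 if data_range is None else data_range
    else:
        rng = (float(max(x.max(), ref.max()) - min(x.min(), ref.min()))
               if data_range is None else data_range)
        if rng == 0:
            rng = 1.0  # identical constants: SSIM is 1 regardless of range
    if min(x.shape[:2]) < win_size:
        raise ValueError("SSIM window larger than image extent")
    _, smap = structural_similarity(
        ref, x, win_size=win_size, K1=k1, K2=k2, data_range=rng,
        gaussian_weights=False, full=True, channel_axis=None)
    return float(np.mean(smap[roi_]) * 100.0)


def csd_map(phi, valid=None, window: int = 5, max_csd: float = 1e3,
            min_neighbours: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Local circular standard deviation of an axial angle map, in degrees.

    Per pixel, over the valid ``window x window`` neighbourhood (truncated at
    the image border): angles are doubled to map the axial support onto the
    circle, the mean resultant length Rbar of the unit vectors at 2*phi is
    formed, and csd = 0.5 * sqrt(-2 ln Rbar) converted to degrees.  Low csd
    marks coherent fibre tracts; high csd marks directional disruption, e.g.
    a tumour core.  Rbar ~ 0 (antipodal doubled vectors) is capped at
    ``max_csd``.  Pixels with fewer than ``min_neighbours`` valid neighbours
    are flagged out of the returned mask.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    phi = np.asarray(phi, float)
    valid = np.ones(phi.shape, bool) if valid is None else np.asarray(valid, bool)
    ang = np.radians(2.0 * phi)
    c = np.where(valid, np.cos(ang), 0.0)
    s = np.where(valid, np.sin(ang), 0.0)
    kern = np.ones((window, window))
    cnt = ndimage.correlate(valid.astype(float), kern, mode="constant")
    cs = ndimage.correlate(c, kern, mode="constant")
    ss = ndimage.correlate(s, kern, mode="constant")
    ok = valid & (cnt >= min_neighbours)
    with np.errstate(divide="ignore", invalid="ignore"):
        rbar = np.sqrt(cs ** 2 + ss ** 2) / np.maximum(cnt, 1.0)
        rbar = np.clip(rbar, 0.0, 1.0)
        rbar[rbar < 1e-12] = 0.0  # exact cancellation up to roundoff
        csd = 0.5 * np.sqrt(-2.0 * np.log(rbar))
    csd = np.degrees(csd)
    csd = np.where(np.isfinite(csd), csd, max_csd)
    csd = np.minimum(csd, max_csd)
    csd[~ok] = np.nan
    return csd, ok


def wilcoxon_ranksum(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value between two
    independent per-image score samples.  Exact distribution for combined
    n <= 20 without ties, normal approximation with tie correction
    otherwise."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    n = a.size + b.size
    ties = len(np.unique(np.concatenate([a, b]))) < n
    method = "exact" if (n <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class MetricReport:
    """Quartile summaries of per-image scores with pairwise significance.

    ``scores[metric][quantity][method]`` holds (q1, median, q3);
    ``pvalues[metric][quantity][method]`` the two-sided rank-sum p-value
    against the reference method.
    """

    scores: dict[str, dict[str, dict[str, tuple[float, float, float]]]]
    pvalues: dict[str, dict[str, dict[str, float]]]
    reference: str
    quartile_rule: str = "linear interpolation between order statistics"
    npsnr_normalisation: str = "reference dynamic range within ROI (180 deg for axial)"
    meta: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scores": self.scores,
            "pvalues": self.pvalues,
            "reference": self.reference,
            "quartile_rule": self.quartile_rule,
            "npsnr_normalisation": self.npsnr_normalisation,
            "meta": self.meta,
        }


def _quartiles(v) -> tuple[float, float, float]:
    q = np.percentile(np.asarray(v, float), [25, 50, 75], method="linear")
    return (float(q[0]), float(q[1]), float(q[2]))


def summarize(per_image_scores: dict[str, dict[str, dict[str, list[float]]]],
              reference: str, alpha: float = 0.05) -> MetricReport:
    """Build a report from ``per_image_scores[metric][quantity][method]``
    (a list of per-image scores), comparing every method against
    ``reference`` with the rank-sum test."""
    scores: dict = {}
    pvals: dict = {}
    for metric, by_q in per_image_scores.items():
        scores[metric] = {}
        pvals[metric] = {}
        for quantity, by_m in by_q.items():
            scores[metric][quantity] = {m: _quartiles(v) for m, v in by_m.items()}
            pvals[metric][quantity] = {}
            if reference in by_m:
                ref_scores = by_m[reference]
                for m, v in by_m.items():
                    if m == reference or len(v) < 3 or len(ref_scores) < 3:
                        continue
                    pvals[metric][quantity][m] = wilcoxon_ranksum(v, ref_scores)
    return MetricReport(scores=scores, pvalues=pvals, reference=reference,
                        meta={"alpha": alpha})
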