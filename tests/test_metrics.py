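"""Image-quality metrics, circular statistics and the rank-sum test,
each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mupol import csd_map, npsnr, rmse, ssim, summarize, wilcoxon_ranksum
from mupol.metrics import wrap_axial_difference


# ---------------------------------------------------------------- oracles
def rmse_loop_oracle(x, y, roi, circular):
    acc = []
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            if roi[i, j]:
                d = x[i, j] - y[i, j]
                if circular:
                    d = (d + 90.0) % 180.0 - 90.0
                    if d == -90.0:
                        d = 90.0
                acc.append(d * d)
    return np.sqrt(np.mean(acc))


def csd_loop_oracle(phi, valid, window=5, max_csd=1e3):
    H, W = phi.shape
    r = window // 2
    out = np.full((H, W), np.nan)
    for i in range(H):
        for j in range(W):
            if not valid[i, j]:
                continue
            vs = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < H and 0 <= jj < W and valid[ii, jj]:
                        vs.append(np.radians(2 * phi[ii, jj]))
            if len(vs) < 3:
                continue
            rbar = np.abs(np.mean(np.exp(1j * np.array(vs))))
            val = (0.5 * np.degrees(np.sqrt(-2 * np.log(rbar)))
                   if rbar > 0 else max_csd)
            out[i, j] = min(val, max_csd)
    return out


def ranksum_enumeration_oracle(a, b):
    """Exact two-sided p-value by enumerating all rank assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[: len(a)].sum()
    n = len(pooled)
    stats = [sum(c) for c in itertools.combinations(ranks, len(a))]
    mu = np.mean(stats)
    extreme = sum(abs(s - mu) >= abs(w_obs - mu) - 1e-9 for s in stats)
    return extreme / len(stats)


# ------------------------------------------------------------------ tests
class TestRMSE:
    def test_identical_fields_zero(self, rng):
        x = rng.normal(size=(8, 8))
        assert rmse(x, x) == 0.0

    def test_axial_wrap_near_boundary(self):
        x = np.full((4, 4), 179.0)
        y = np.full((4, 4), 1.0)
        assert rmse(x, y, circular=True) == pytest.approx(2.0)

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_loop_oracle(self, rng, circular):
        x = rng.uniform(0, 180, (16, 16))
        y = rng.uniform(0, 180, (16, 16))
        roi = rng.random((16, 16)) > 0.3
        assert rmse(x, y, roi, circular) == pytest.approx(
            rmse_loop_oracle(x, y, roi, circular), abs=1e-12)

    def test_empty_roi_rejected(self, rng):
        x = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="ROI"):
            rmse(x, x, np.zeros((4, 4), bool))


class TestNPSNR:
    def test_rmse_equal_to_range_is_zero_db(self):
        ref = np.zeros((8, 8))
        ref[0, 0] = 1.0  # range 1
        x = ref + 1.0
        assert npsnr(x, ref) == pytest.approx(0.0, abs=1e-9)

    def test_halving_error_adds_six_db(self, rng):
        ref = rng.uniform(0, 1, (8, 8))
        e = rng.normal(size=(8, 8))
        a = npsnr(ref + e, ref)
        b = npsnr(ref + 0.5 * e, ref)
        assert b - a == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_identical_gives_infinity(self, rng):
        x = rng.normal(size=(8, 8))
        assert npsnr(x, x) == np.inf

    def test_axial_range_is_180(self):
        ref = np.full((8, 8), 10.0)
        x = ref + 18.0
        assert npsnr(x, ref, circular=True) == pytest.approx(20 * np.log10(10))


class TestSSIM:
    def test_identical_is_100_percent(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        assert ssim(x, x) == pytest.approx(100.0)

    def test_decreases_with_noise_level(self, rng):
        ref = rng.uniform(0, 1, (32, 32))
        vals = [ssim(ref + s * rng.normal(size=ref.shape), ref, data_range=1.0)
                for s in (0.05, 0.2, 0.6)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[0] < 100.0

    def test_constant_shift_equals_luminance_term(self):
        c1 = (0.01 * 1.0) ** 2
        mx, my = 0.4, 0.6  # constant images, data_range 1
        x = np.full((16, 16), mx)
        y = np.full((16, 16), my)
        expected = (2 * mx * my + c1) / (mx**2 + my**2 + c1) * 100
        assert ssim(x, y, data_range=1.0) == pytest.approx(expected, rel=1e-6)

    def test_window_larger_than_image_rejected(self, rng):
        x = rng.uniform(0, 1, (5, 5))
        with pytest.raises(ValueError, match="window"):
            ssim(x, x, win_size=7)


class TestCsdMap:
    def test_constant_field_zero(self):
        csd, ok = csd_map(np.full((9, 9), 42.0))
        assert ok.all()
        assert np.allclose(csd, 0.0, atol=1e-5)

    def test_cancelling_doubled_vectors_capped(self):
        # columns cycle through five equally spaced axial angles, so the
        # doubled unit vectors sum to zero over every 5-wide window
        phi = (np.indices((8, 10))[1] * 36.0) % 180.0
        csd, _ = csd_map(phi, max_csd=500.0)
        centre = csd[2:6, 2:8]
        assert np.all(centre >= 499.0)

    def test_matches_loop_oracle(self, rng):
        phi = rng.uniform(0, 180, (16, 16))
        valid = rng.random((16, 16)) > 0.2
        csd, ok = csd_map(phi, valid)
        oracle = csd_loop_oracle(phi, valid)
        both = ok & np.isfinite(oracle)
        assert np.allclose(csd[both], oracle[both], atol=1e-9)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_axial_invariance_adding_180(self, seed):
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0, 180, (10, 10))
        shifted = phi + 180.0 * (rng.random((10, 10)) < 0.5)
        a, _ = csd_map(phi)
        b, _ = csd_map(shifted % 360.0 % 180.0)
        c, _ = csd_map(shifted)  # values outside [0,180) double to same circle
        assert np.allclose(a, b, atol=1e-9)
        assert np.allclose(a, c, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            csd_map(np.zeros((8, 8)), window=4)


class TestWilcoxon:
    def test_identical_samples_no_separation(self):
        p = wilcoxon_ranksum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p >= 0.99

    def test_fully_separated_triples_exact(self):
        # all ranks separated: two-sided tail = 2 / C(6,3) = 0.1
        assert wilcoxon_ranksum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(loc=0.8, size=5)
            p = wilcoxon_ranksum(a, b)
            assert p == pytest.approx(ranksum_enumeration_oracle(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestSummarize:
    def test_single_image_quartiles_collapse(self):
        rep = summarize({"RMSE": {"phi": {"PDDN": [3.0], "LQ": [5.0]}}},
                        reference="PDDN")
        assert rep.scores["RMSE"]["phi"]["LQ"] == (5.0, 5.0, 5.0)

    def test_quartile_rule_linear_interpolation(self):
        rep = summarize({"m": {"q": {"A": list(range(1, 9))}}}, reference="A")
        assert rep.scores["m"]["q"]["A"] == pytest.approx((2.75, 4.5, 6.25))

    def test_order_invariance_and_pvalues(self, rng):
        a = list(rng.normal(size=6))
        b = list(rng.normal(loc=1.0, size=6))
        r1 = summarize({"m": {"q": {"A": a, "B": b}}}, reference="A")
        r2 = summarize({"m": {"q": {"A": a[::-1], "B": b[::-1]}}}, reference="A")
        assert r1.scores == r2.scores
        assert r1.pvalues["m"]["q"]["B"] == pytest.approx(
            r2.pvalues["m"]["q"]["B"])
        assert r1.pvalues["m"]["q"]["B"] == pytest.approx(
            wilcoxon_ranksum(b, a))

    def test_quartiles_ordered(self, rng):
        rep = summarize({"m": {"q": {"A": list(rng.normal(size=9))}}},
                        reference="A")
        q1, med, q3 = rep.scores["m"]["q"]["A"]
        assert q1 <= med <= q3


def test_wrap_axial_difference_range(rng):
    d = wrap_axial_difference(rng.uniform(-720, 720, 100),
                              rng.uniform(-720, 720, 100))
    assert np.all((d > -90.0 - 1e-12) & (d <= 90.0 + 1e-12))
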