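"""Diffusion schedule, forward corruption, training and single-pass inference."""

import numpy as np
import pytest

from mupol import (PDDN, TrainConfig, baseline_filter, denoise_frame,
                   denoise_single_pass, make_schedule, q_sample, train_pddn)
from mupol.diffusion import NormalisationSpec, match_t_star


class TestSchedule:
    def test_constant_beta_alpha_bar_by_hand(self):
        s = make_schedule(4, 0.5, 0.5)
        assert np.allclose(s.alpha_bar, [0.5, 0.25, 0.125, 0.0625])

    def test_alpha_bar_strictly_decreasing(self):
        s = make_schedule(200, 1e-4, 0.02)
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert s.alpha_bar[0] == pytest.approx(1.0, abs=1e-3)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_schedule(10, 0.5, 0.2)
        with pytest.raises(ValueError):
            make_schedule(10, 0.0, 0.2)

    def test_abar_range_checked(self):
        s = make_schedule(10, 1e-4, 0.02)
        with pytest.raises(ValueError):
            s.abar(11)


class TestQSample:
    def test_t_zero_is_identity(self, rng):
        s = make_schedule(10, 1e-4, 0.02)
        x0 = rng.normal(size=(4, 4, 16))
        assert np.array_equal(q_sample(x0, 0, np.zeros_like(x0), s), x0)

    def test_zero_eps_scales_by_sqrt_alpha_bar(self, rng):
        s = make_schedule(10, 0.1, 0.1)
        x0 = rng.normal(size=(3, 3))
        out = q_sample(x0, 2, np.zeros_like(x0), s)
        assert np.allclose(out, np.sqrt(0.81) * x0)

    def test_marginal_moments(self, rng):
        s = make_schedule(50, 1e-3, 0.05)
        t = 30
        x0 = 0.4
        eps = rng.standard_normal(100_000)
        xt = q_sample(np.full_like(eps, x0), t, eps, s)
        ab = s.abar(t)
        assert xt.mean() == pytest.approx(np.sqrt(ab) * x0, abs=0.01)
        assert xt.var() == pytest.approx(1 - ab, rel=0.02)


class _PerfectEpsModel(PDDN):
    """Stub whose network returns the exact noise used to corrupt x0."""

    def __init__(self, sched, norm, eps):
        super().__init__(net=None, sched=sched, norm=norm)
        self._eps = eps

    def predict_eps(self, x, t):
        return self._eps


class TestSinglePass:
    def test_perfect_eps_oracle_recovers_x0(self, rng):
        sched = make_schedule(50, 1e-3, 0.05)
        norm = NormalisationSpec(-1.0, 1.0)  # identity rescale
        x0 = rng.uniform(-0.9, 0.9, size=(8, 8, 16))
        t = 7
        eps = rng.standard_normal((1, 16, 8, 8))
        x0c = np.transpose(x0, (2, 0, 1))[None]
        xt = q_sample(x0c, t, eps, sched)[0]
        model = _PerfectEpsModel(sched, norm, eps)
        out = denoise_single_pass(np.transpose(xt, (1, 2, 0)), model, t_star=t)
        # algebraic inversion of the forward corruption, up to the posterior
        # shrinkage toward x_t for t > 1; at t = 1 recovery is exact
        model1 = _PerfectEpsModel(sched, norm, eps)
        xt1 = q_sample(x0c, 1, eps, sched)[0]
        out1 = denoise_single_pass(np.transpose(xt1, (1, 2, 0)), model1, t_star=1)
        assert np.max(np.abs(out1 - x0)) < 1e-6

    def test_t_star_out_of_range(self, smoke_model):
        x = np.zeros((16, 16, 16))
        with pytest.raises(ValueError):
            denoise_single_pass(x, smoke_model, t_star=0)
        with pytest.raises(ValueError):
            denoise_single_pass(x, smoke_model, t_star=smoke_model.sched.T + 1)

    def test_shape_preserved_and_block_layout_supported(self, smoke_model, rng):
        x = rng.uniform(0, 1, (16, 16, 4, 4))
        out = denoise_single_pass(x, smoke_model)
        assert out.shape == x.shape

    def test_tiled_matches_untiled_on_interior(self, smoke_model, rng):
        x = rng.uniform(0.1, 0.9, (32, 32, 16))
        whole = denoise_single_pass(x, smoke_model)
        tiled = denoise_frame(x, smoke_model, tile=24, overlap=16)
        interior = (slice(8, 24), slice(8, 24))
        scale = np.max(np.abs(whole)) + 1e-12
        assert np.max(np.abs(whole[interior] - tiled[interior])) / scale < 0.05

    def test_noise_matching_t_star_monotone(self, smoke_model):
        assert match_t_star(smoke_model, 1e-6) == 1
        lo = match_t_star(smoke_model, 0.01)
        hi = match_t_star(smoke_model, 0.1)
        assert 1 <= lo <= hi <= smoke_model.sched.T


class TestTraining:
    def test_smoke_training_decreases_loss(self, smoke_model):
        curve = smoke_model.manifest["loss_curve"]
        assert curve[-1][2] < curve[0][2]  # running L1 falls

    def test_training_deterministic_given_seed(self, rng):
        imgs = [rng.uniform(0, 1, (24, 24, 16))]
        cfg = TrainConfig(patch=16, width=8, T=20, steps=10, batch=2, seed=4)
        a = train_pddn(imgs, cfg)
        b = train_pddn(imgs, cfg)
        assert a.manifest["loss_curve"] == b.manifest["loss_curve"]
        for ka, kb in zip(a.net.params(), b.net.params()):
            assert np.array_equal(ka.data, kb.data)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_pddn([], TrainConfig(steps=1))

    def test_checkpoint_roundtrip(self, smoke_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        smoke_model.save(path)
        loaded = PDDN.load(path)
        x = rng.uniform(0.1, 0.9, (16, 16, 16))
        assert np.allclose(denoise_single_pass(x, smoke_model),
                           denoise_single_pass(x, loaded))
        assert loaded.manifest["seed"] == smoke_model.manifest["seed"]


class TestChannelCoupling:
    def test_baselines_equivariant_to_channel_permutation(self, rng):
        x = rng.uniform(0, 1, (12, 12, 16))
        perm = rng.permutation(16)
        for method in ("medf", "gblr", "grad"):
            a = baseline_filter(x, method)[..., perm]
            b = baseline_filter(x[..., perm], method)
            assert np.allclose(a, b, atol=1e-10)

    def test_pddn_couples_channels(self, smoke_model, rng):
        x = rng.uniform(0.1, 0.9, (16, 16, 16))
        perm = np.roll(np.arange(16), 5)
        a = denoise_single_pass(x, smoke_model)[..., perm]
        b = denoise_single_pass(x[..., perm], smoke_model)
        assert not np.allclose(a, b, atol=1e-6)
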