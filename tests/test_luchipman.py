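"""Lu-Chipman decomposition and scalar parameter maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mupol import (decompose, make_diattenuator, make_depolariser,
                   make_linear_retarder, scalar_params)

from conftest import random_physical_mueller


class TestConstructors:
    def test_zero_retardance_is_identity(self):
        assert np.allclose(make_linear_retarder(73.0, 0.0), np.eye(4))

    def test_quarter_wave_at_zero_azimuth(self):
        expected = np.array([[1, 0, 0, 0],
                             [0, 1, 0, 0],
                             [0, 0, 0, 1],
                             [0, 0, -1, 0]], float)
        assert np.allclose(make_linear_retarder(0.0, 90.0), expected, atol=1e-15)

    def test_retarder_3x3_block_is_rotation(self, rng):
        m = make_linear_retarder(rng.uniform(0, 180, 20), rng.uniform(0, 180, 20))
        r3 = m[..., 1:, 1:]
        assert np.allclose(r3 @ np.swapaxes(r3, -1, -2), np.eye(3), atol=1e-12)
        assert np.allclose(np.linalg.det(r3), 1.0, atol=1e-12)

    def test_zero_diattenuation_is_identity(self):
        assert np.allclose(make_diattenuator([0, 0, 0]), np.eye(4))

    def test_diattenuator_first_row_and_magnitude(self):
        m = make_diattenuator([0.3, 0.0, 0.0])
        assert np.allclose(m[0], [1, 0.3, 0, 0])
        p = scalar_params(decompose(m[None]))
        assert np.allclose(p.D, 0.3, atol=1e-12)

    def test_diattenuator_rejects_unit_vector(self):
        with pytest.raises(ValueError, match="< 1"):
            make_diattenuator([1.0, 0.0, 0.0])


class TestDecompose:
    def test_identity_gives_identity_factors(self):
        f = decompose(np.eye(4)[None])
        for fac in (f.M_D, f.M_R, f.M_Delta):
            assert np.allclose(fac[0], np.eye(4), atol=1e-12)
        assert f.valid.all()

    def test_pure_retarder_is_its_own_factor(self):
        M = make_linear_retarder(40.0, 30.0)
        f = decompose(M[None])
        assert np.allclose(f.M_D[0], np.eye(4), atol=1e-10)
        assert np.allclose(f.M_Delta[0], np.eye(4), atol=1e-10)
        assert np.allclose(f.M_R[0], M, atol=1e-10)

    def test_pure_depolariser_is_its_own_factor(self):
        M = np.diag([1.0, 0.7, 0.6, 0.5])
        f = decompose(M[None])
        assert np.allclose(f.M_D[0], np.eye(4), atol=1e-12)
        assert np.allclose(f.M_R[0], np.eye(4), atol=1e-12)
        assert np.allclose(f.M_Delta[0], M, atol=1e-12)

    def test_reconstruction_and_factor_recovery_random_products(self, rng):
        diag = rng.uniform(0.3, 0.9, (40, 3))
        th = rng.uniform(0, 180, 40)
        de = rng.uniform(5, 175, 40)
        d = rng.uniform(-0.45, 0.45, (40, 3))
        MD = make_diattenuator(d)
        MR = make_linear_retarder(th, de)
        MDel = make_depolariser(diag)
        M = MDel @ MR @ MD
        f = decompose(M)
        assert f.valid.all()
        assert np.max(np.abs(f.reconstruct() - M)) < 1e-8
        assert np.max(np.abs(f.M_D - MD)) < 1e-6
        assert np.max(np.abs(f.M_R - MR)) < 1e-6
        assert np.max(np.abs(f.M_Delta - MDel)) < 1e-6

    def test_retarder_block_special_orthogonal(self, rng):
        M = random_physical_mueller(rng, (30,))
        f = decompose(M)
        r3 = f.M_R[f.valid][:, 1:, 1:]
        assert np.max(np.abs(np.linalg.det(r3) - 1.0)) < 1e-8

    def test_nonfinite_pixel_masked_not_thrown(self):
        M = np.tile(np.eye(4), (2, 2, 1, 1))
        M[0, 1, 2, 2] = np.nan
        f = decompose(M)
        assert not f.valid[0, 1]
        assert f.valid[0, 0]

    def test_overunity_diattenuation_masked(self):
        M = np.eye(4)
        M[0, 1] = 1.5
        f = decompose(M[None])
        assert not f.valid[0]


class TestScalarParams:
    def test_identity_factors_give_zero_parameters(self):
        p = scalar_params(decompose(np.eye(4)[None]))
        assert p.D[0] == 0 and p.Delta[0] == pytest.approx(0, abs=1e-12)
        assert p.R[0] == pytest.approx(0, abs=1e-6)
        assert not p.phi_valid[0]  # azimuth undefined at zero retardance

    def test_linear_retarder_recovers_theta_delta(self):
        p = scalar_params(decompose(make_linear_retarder(40.0, 30.0)[None]))
        assert p.R[0] == pytest.approx(30.0, abs=1e-9)
        assert p.phi[0] == pytest.approx(40.0, abs=1e-9)

    def test_retarder_symbolic_identities(self, rng):
        # closed form of the retardance/azimuth coefficients of Eq-style maps:
        # M_R22 + M_R33 = 1 + cos(delta); M_R32 - M_R23 = 0; M_R24/M_R43 = tan(2 theta)
        th, de = 33.0, 71.0
        m = make_linear_retarder(th, de)
        assert m[1, 1] + m[2, 2] == pytest.approx(1 + np.cos(np.radians(de)))
        assert m[2, 1] - m[1, 2] == pytest.approx(0, abs=1e-12)
        assert m[1, 3] / m[3, 2] == pytest.approx(np.tan(np.radians(2 * th)))

    def test_dense_grid_roundtrip(self):
        th = np.arange(0.0, 180.0, 1.0)
        de = np.arange(5.0, 176.0, 5.0)
        TH, DE = np.meshgrid(th, de, indexing="ij")
        p = scalar_params(decompose(make_linear_retarder(TH, DE)))
        dphi = np.abs(p.phi - TH) % 180.0
        dphi = np.minimum(dphi, 180.0 - dphi)
        assert np.max(dphi) < 1e-6
        assert np.max(np.abs(p.R - DE)) < 1e-6

    def test_depolarisation_submatrix_trace(self):
        M = np.diag([1.0, 0.7, 0.6, 0.5])
        p = scalar_params(decompose(M[None]))
        assert p.Delta[0] == pytest.approx(1 - (0.7 + 0.6 + 0.5) / 3)

    def test_depolarisation_literal_4x4_switch(self):
        M = np.diag([1.0, 0.7, 0.6, 0.5])
        p = scalar_params(decompose(M[None]), delta_literal_4x4=True)
        assert p.Delta[0] == pytest.approx(1 - (1 + 0.7 + 0.6 + 0.5) / 3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_parameter_ranges_on_random_valid_inputs(self, seed):
        rng = np.random.default_rng(seed)
        M = random_physical_mueller(rng, (8,))
        p = scalar_params(decompose(M))
        v = p.valid
        assert np.all((p.D[v] >= 0) & (p.D[v] <= 1))
        assert np.all((p.Delta[v] >= -1e-12) & (p.Delta[v] <= 1))
        assert np.all((p.R[v] >= 0) & (p.R[v] <= 180))
        assert np.all((p.phi[v] >= 0) & (p.phi[v] < 180))

    def test_azimuth_equivariant_under_scene_rotation(self, rng):
        th = rng.uniform(0, 180, 16)
        rho = 37.0
        p0 = scalar_params(decompose(make_linear_retarder(th, 30.0)))
        p1 = scalar_params(decompose(make_linear_retarder(th + rho, 30.0)))
        d = (p1.phi - p0.phi - rho) % 180.0
        d = np.minimum(d, 180.0 - d)
        assert np.max(d) < 1e-9

    def test_diattenuation_vector_roundtrip(self, rng):
        d = rng.uniform(-0.45, 0.45, (25, 3))
        M = (make_depolariser(rng.uniform(0.5, 1, (25, 3)))
             @ make_linear_retarder(rng.uniform(0, 180, 25), 40.0)
             @ make_diattenuator(d))
        f = decompose(M)
        assert np.max(np.abs(f.M_D[:, 0, 1:] - d)) < 1e-8
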