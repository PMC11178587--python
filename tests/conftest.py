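import numpy as np
import pytest

from mupol import (PhantomSpec, TrainConfig, make_phantom, train_pddn)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48x48 phantom with all five tissue classes and default noise."""
    return make_phantom(PhantomSpec(H=48, W=48, seed=7))


@pytest.fixture(scope="session")
def smoke_model():
    """A tiny diffusion model trained for seconds, for contract tests."""
    imgs = [make_phantom(PhantomSpec(H=32, W=32, seed=50 + s, n_shots=8,
                                     averages=(8,))).averaged[8].reshape(32, 32, 16)
            for s in range(2)]
    cfg = TrainConfig(patch=16, width=8, T=50, steps=120, batch=4, seed=0)
    return train_pddn(imgs, cfg)


def random_physical_mueller(rng, shape=()):
    """Random physically valid Mueller fields as depolariser*retarder*diattenuator."""
    from mupol import make_depolariser, make_diattenuator, make_linear_retarder
    diag = rng.uniform(0.3, 1.0, shape + (3,))
    theta = rng.uniform(0, 180, shape)
    delta = rng.uniform(0, 180, shape)
    d = rng.uniform(-0.4, 0.4, shape + (3,))
    return (make_depolariser(diag) @ make_linear_retarder(theta, delta)
            @ make_diattenuator(d))
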