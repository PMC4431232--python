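import numpy as np
import pytest

import magsense as ms
from magsense.spin_dynamics import SDParams


@pytest.fixture(scope="session")
def paper_binding():
    """Reference PhoB/DNA rate-constant set."""
    return ms.BindingParams(kd=1.5e-8, KD=21e-3, nA=2.56e-8)


@pytest.fixture(scope="session")
def moment_20nm():
    return ms.moment_magnitude(20e-9, 1.446e6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pair(separation, moment=None, direction=(1.0, 0.0, 0.0),
              orientations=None, seed=0):
    """Two 20 nm particles along ``direction`` at the given separation."""
    m = moment if moment is not None else ms.moment_magnitude(20e-9, 1.446e6)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    center = np.array([200e-9, 200e-9, 200e-9])
    pos = np.array([center - 0.5 * separation * direction,
                    center + 0.5 * separation * direction])
    if orientations is None:
        g = np.random.default_rng(seed)
        v = g.normal(size=(2, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    else:
        v = np.asarray(orientations, dtype=float)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return ms.NanoparticleEnsemble(
        positions=pos, diameters=np.full(2, 20e-9), moments=m * v,
        box=[400e-9, 400e-9, 400e-9], motion_dim=3,
    )


@pytest.fixture
def pair_factory():
    return make_pair


@pytest.fixture(scope="session")
def fast_sd():
    """Strongly damped SD parameters for quick ground-state relaxation."""
    return SDParams(alpha=0.5, dt=2e-13)


@pytest.fixture(scope="session")
def small_ensemble():
    return ms.generate_random_ensemble(10, (300e-9, 300e-9), seed=42)
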