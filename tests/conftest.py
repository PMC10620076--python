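import numpy as np
import pytest

from tidose.phantom import PhantomConfig, build_phantom, electrode_positions


@pytest.fixture(scope="session")
def coarse_phantom():
    """4-mm default-geometry phantom: fast enough for solver-backed tests."""
    return build_phantom(PhantomConfig(spacing_mm=4.0))


@pytest.fixture(scope="session")
def default_phantom():
    """The 2-mm default phantom (shared across the session; it is large)."""
    return build_phantom(PhantomConfig(spacing_mm=2.0))


@pytest.fixture(scope="session")
def coarse_electrodes(coarse_phantom):
    return electrode_positions(["F3", "F4", "TP7", "TP8"], coarse_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231019)


def random_vector_pairs(rng, n, mag_low=1e-3, mag_high=1.0):
    """Seeded random 3-vector pairs with log-uniform magnitudes."""
    mags = 10 ** rng.uniform(np.log10(mag_low), np.log10(mag_high), size=(n, 2))
    v1 = rng.normal(size=(n, 3))
    v2 = rng.normal(size=(n, 3))
    v1 *= (mags[:, 0] / np.linalg.norm(v1, axis=1))[:, None]
    v2 *= (mags[:, 1] / np.linalg.norm(v2, axis=1))[:, None]
    return v1, v2
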