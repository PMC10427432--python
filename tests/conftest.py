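import numpy as np
import pytest

from tripsoct import forward_sim as fs
from tripsoct import polarcore as pc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230626)


@pytest.fixture(scope="session")
def probing():
    return pc.design_probing_states()


def random_axes(rng, n):
    a = rng.normal(size=(n, 3))
    return a / np.linalg.norm(a, axis=1, keepdims=True)


def random_pure_muellers(rng, n):
    J = rng.normal(size=(n, 2, 2)) + 1j * rng.normal(size=(n, 2, 2))
    return pc.jones_to_mueller(J), J


@pytest.fixture(scope="session")
def small_two_layer():
    """A small two-layer sclera phantom simulated once for several tests."""
    ph = fs.make_two_layer_sclera_phantom(nx=20, ny=20, nz=96)
    frames = fs.simulate_stokes_volume(
        ph, acq=fs.AcquisitionSpec(n_bins=3, dtype="float64"))
    return ph, frames


def wrap_orientation(a):
    """Orientation difference wrapped to (-90, 90] degrees."""
    return (np.asarray(a) + 90.0) % 180.0 - 90.0
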