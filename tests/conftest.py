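import warnings

import numpy as np
import pytest

import memprops as mp


@pytest.fixture(scope="session")
def small_bilayer():
    """A small but complete synthetic system shared by fast tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traj, truth = mp.gen_bilayer(
            n_per_leaflet=16, n_frames=120, seed=2024, n_waters=160, n_shell=24
        )
    return traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
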