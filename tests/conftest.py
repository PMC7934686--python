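"""Shared fixtures: schemes, uniform-tensor volumes, tiny cohorts."""

import numpy as np
import pytest

from dtifitlab.io import DWIVolume
from dtifitlab.phantom import make_scheme, predict_signal, tensor_from_eigen


@pytest.fixture(scope="session")
def ge48_scheme():
    return make_scheme(48, 6, 1000.0)


@pytest.fixture(scope="session")
def si30_scheme():
    return make_scheme(30, 1, 1000.0)


def uniform_volume(eigenvalues, direction, scheme, grid=(4, 4, 2), s0=1000.0,
                   subject_id="test"):
    """DWIVolume with the same noiseless tensor signal in every voxel."""
    tensor = tensor_from_eigen(np.asarray(eigenvalues), direction)
    sig = predict_signal(tensor, scheme, s0)
    signal = np.tile(sig, (*grid, 1))
    return DWIVolume(
        signal=signal, voxel_size=(2.0, 2.0, 2.0), scheme=scheme,
        subject_id=subject_id,
    ), tensor


@pytest.fixture()
def prolate_volume(ge48_scheme):
    """Uniform prolate tensor (FA ~ 0.87) on a small grid."""
    return uniform_volume(
        [1.7e-3, 0.2e-3, 0.2e-3], (1.0, 0.0, 0.0), ge48_scheme
    )
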