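"""Shared fixtures: montage and desk-scale spherical leadfields.

Leadfields are session-scoped — the spherical solution and the eLORETA
fixed point are deterministic, so every test can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from eloreta_npv import (
    SphericalModelSpec, build_spherical_leadfield, standard_1020_montage,
)


@pytest.fixture(scope="session")
def montage():
    return standard_1020_montage()


@pytest.fixture(scope="session")
def leadfield_small(montage):
    """27-voxel grid (35 mm spacing) for fast unit tests."""
    return build_spherical_leadfield(
        SphericalModelSpec(grid_spacing_mm=35.0), montage
    )


@pytest.fixture(scope="session")
def leadfield_medium(montage):
    """57-voxel grid (30 mm spacing) for cohort-level tests."""
    return build_spherical_leadfield(
        SphericalModelSpec(grid_spacing_mm=30.0), montage
    )


@pytest.fixture(scope="session")
def eloreta_filter_medium(leadfield_medium):
    from eloreta_npv import compute_filter, compute_weights

    W = compute_weights(leadfield_medium, alpha=0.05)
    return compute_filter(leadfield_medium, W)


def make_recording(data: np.ndarray, fs: float = 500.0, labels=None):
    from eloreta_npv import EEGRecording

    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EEGRecording(data=data, fs=fs, channel_labels=labels)
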