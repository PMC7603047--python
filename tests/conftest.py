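"""Shared fixtures: small synthetic volumes and one expensive NS sweep."""

import numpy as np
import pytest

from trabdvc import (
    BinaryMask,
    add_imaging_noise,
    bone_contour_mask,
    build_grid,
    generate_trabecular_volume,
    segment_bone,
    zero_strain_study,
)
from trabdvc.synthgen import SyntheticSpec


@pytest.fixture(scope="session")
def vol64():
    """64^3 trabecular volume at 39 µm, BV/TV 0.20."""
    spec = SyntheticSpec(dims=(64, 64, 64), target_bvtv=0.20, seed=3)
    return generate_trabecular_volume(spec)


@pytest.fixture(scope="session")
def grid16(vol64):
    return build_grid(vol64.shape, vol64.voxel_size, 16)


@pytest.fixture(scope="session")
def contour64(vol64):
    bone = segment_bone(vol64)
    return bone_contour_mask(bone, 10)


@pytest.fixture(scope="session")
def noisy_pair_104():
    """Repeated 'scans' of one 104^3 volume at 78 µm, differing only in noise."""
    spec = SyntheticSpec(
        dims=(104, 104, 104),
        voxel_size=78.0,
        correlation_length=380.0,
        target_bvtv=0.20,
        seed=11,
    )
    vol = generate_trabecular_volume(spec)
    pre1 = add_imaging_noise(vol, 5.0, seed=111)
    pre2 = add_imaging_noise(vol, 5.0, seed=112)
    return pre1, pre2


@pytest.fixture(scope="session")
def ns_sweep_reports(noisy_pair_104):
    """Zero-strain uncertainty sweep over NS {13, 25, 35, 50} (expensive)."""
    pre1, pre2 = noisy_pair_104
    bone = segment_bone(pre1)
    contour = bone_contour_mask(bone, 10)
    return zero_strain_study(pre1, pre2, mask=contour, ns_list=(13, 25, 35, 50))


@pytest.fixture()
def full_mask_64(vol64):
    return BinaryMask(np.ones(vol64.shape, dtype=bool), vol64.voxel_size)
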