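"""Shared fixtures: a desk-scale phantom/coil/baseline stack.

Everything is generated at test time; session scope keeps the expensive
baseline scan (169 pre-rotated navigator acquisitions) to a single run.
"""

import numpy as np
import pytest

from fidsnav import (
    ProtocolConfig,
    acquire_baselines,
    build_lookup_table,
    make_coil_profiles,
    make_phantom,
    make_snav_trajectory,
)

SMALL_GRID = (24, 24, 16)
SMALL_VOXEL = (5.33, 5.33, 6.0)  # same physical FOV as the 64-scale phantom


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(SMALL_GRID, SMALL_VOXEL)


@pytest.fixture(scope="session")
def small_coils(small_phantom):
    return make_coil_profiles(4, small_phantom, seed=1)


@pytest.fixture(scope="session")
def small_protocol():
    return ProtocolConfig(grid_shape=SMALL_GRID, voxel_size_mm=SMALL_VOXEL)


@pytest.fixture(scope="session")
def nav_trajectory():
    return make_snav_trajectory()


@pytest.fixture(scope="session")
def small_baselines(small_phantom, small_coils, small_protocol, nav_trajectory):
    return acquire_baselines(
        small_phantom, small_coils, small_protocol, nav_trajectory,
        dtype=np.complex64,
    )


@pytest.fixture(scope="session")
def small_lookup(small_baselines):
    return build_lookup_table(small_baselines)
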