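"""Shared fixtures: scaled-down phantoms sized for fast correlation runs."""

import numpy as np
import pytest

from lcstrain import DvcConfig, PhantomSpec, generate_phantom

# 96^3-ish phantom: keeps the anatomy (LC ellipse, CRAV disk, saturated
# ring, dark patches) at reduced absolute size
SMALL = dict(
    grid_shape=(96, 96, 32),
    semi_axes=(80.0, 70.0),
    crav_radius=30.0,
    pps_ring_width=15.0,
    dark_patch_count=2,
    dark_patch_radius=(8.0, 14.0),
)

# minimal phantom for tests that need many correlation runs
TINY = dict(
    grid_shape=(64, 64, 24),
    semi_axes=(55.0, 48.0),
    crav_radius=20.0,
    pps_ring_width=12.0,
    dark_patch_count=1,
    dark_patch_radius=(6.0, 10.0),
)

FAST_DVC = dict(subset_schedule=((32, 32, 16), (16, 16, 8)))


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(**SMALL, seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_small_phantom():
    return generate_phantom(PhantomSpec(**SMALL, seed=42, noise_sigma=0.0))


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(**TINY, seed=7)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture
def fast_cfg():
    return DvcConfig(**FAST_DVC)


def volume_center(vol):
    """Physical center of a volume's grid, micrometers."""
    return tuple((n - 1) * d / 2.0 for n, d in zip(vol.shape, vol.voxel_size))
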