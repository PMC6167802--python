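"""Shared fixtures: small hand-built masks and a session-wide phantom cohort."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import perispace as ps

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_mask(
    grid: ps.VolumeGrid, label: str, occupied: list[tuple[int, int, int]] | np.ndarray
) -> ps.StructureMask:
    """Mask from an explicit voxel-index list (the brute-force-friendly path)."""
    vox = np.zeros(grid.dims, dtype=bool)
    for i, j, k in occupied:
        vox[i, j, k] = True
    return ps.StructureMask(grid, label, vox)


def slab_mask(
    grid: ps.VolumeGrid,
    label: str,
    y_range: tuple[int, int],
    x_range: tuple[int, int] | None = None,
    z_range: tuple[int, int] | None = None,
) -> ps.StructureMask:
    """Axis-aligned slab occupying inclusive index ranges."""
    vox = np.zeros(grid.dims, dtype=bool)
    x0, x1 = x_range if x_range else (0, grid.dims[0] - 1)
    z0, z1 = z_range if z_range else (0, grid.dims[2] - 1)
    vox[x0 : x1 + 1, y_range[0] : y_range[1] + 1, z0 : z1 + 1] = True
    return ps.StructureMask(grid, label, vox)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 20-patient synthetic cohort, measured end to end."""
    return ps.simulate_cohort(ps.CohortSpec())


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (well-placed 10.3 cc gel) with ground truth."""
    return ps.make_phantom(ps.PhantomSpec())


@pytest.fixture(scope="session")
def small_spec():
    """Reduced lattice for fast phantom construction in I/O and CLI tests."""
    return ps.PhantomSpec(dims=(72, 80, 56), ctv_volume_cc=25.0, ctv_center_y_mm=30.0)
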