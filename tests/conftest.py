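"""Shared fixtures: small phantoms reused across test modules.

Everything here is deterministic; heavier artefacts are session-scoped
so the suite stays fast on one CPU.
"""

import numpy as np
import pytest

from marrow3dqm import (
    BinaryMask,
    VoxelGrid,
    esd_transform,
    make_extravascular_domain,
)
from marrow3dqm.phantoms import gen_sphere_phantom, gen_tube_phantom


@pytest.fixture(scope="session")
def unit_grid():
    return VoxelGrid((24, 48, 48), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def aniso_grid():
    return VoxelGrid((16, 40, 40), (2.0, 0.8, 0.8))


@pytest.fixture(scope="session")
def tube_setup():
    """Two-tube vessel phantom with its extravascular distance field."""
    grid = VoxelGrid((48, 120, 120), (1.0, 1.0, 1.0))
    img, truth = gen_tube_phantom(
        grid,
        segments=[((24, 30, -10), (24, 30, 130)), ((24, 90, -10), (24, 90, 130))],
        outer_radius_um=12.0,
        wall_thickness_um=2.0,
    )
    vessels = truth.solid_mask
    tissue = BinaryMask(grid, np.ones(grid.shape, bool), role="tissue")
    domain = make_extravascular_domain(tissue, vessels)
    field = esd_transform(vessels, domain)
    return {
        "grid": grid,
        "image": img,
        "truth": truth,
        "vessels": vessels,
        "tissue": tissue,
        "domain": domain,
        "field": field,
    }


@pytest.fixture(scope="session")
def sphere_setup():
    """Sphere phantom with ground-truth centroids for detection tests."""
    grid = VoxelGrid((32, 96, 96), (1.0, 1.0, 1.0))
    img, truth = gen_sphere_phantom(grid, radius_um=3.75, n_spheres=40, seed=3)
    return {"grid": grid, "image": img, "truth": truth}
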