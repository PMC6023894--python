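"""Phantom generators: determinism, ground-truth bookkeeping, geometry."""

import numpy as np
import pytest

from marrow3dqm import VoxelGrid
from marrow3dqm.phantoms import (
    NoiseModel,
    gen_nuclei_phantom,
    gen_point_pattern,
    gen_sphere_phantom,
    gen_tube_phantom,
)


class TestSpherePhantom:
    def test_seed_determinism(self, unit_grid):
        a, ta = gen_sphere_phantom(unit_grid, n_spheres=10, seed=4)
        b, tb = gen_sphere_phantom(unit_grid, n_spheres=10, seed=4)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(ta.true_points.coords, tb.true_points.coords)

    def test_different_seed_differs(self, unit_grid):
        a, _ = gen_sphere_phantom(unit_grid, n_spheres=10, seed=4)
        b, _ = gen_sphere_phantom(unit_grid, n_spheres=10, seed=5)
        assert not np.array_equal(a.values, b.values)

    def test_intensity_and_germ_count_exclusive(self, unit_grid):
        with pytest.raises(ValueError):
            gen_sphere_phantom(unit_grid, germ_intensity=1e-4, n_spheres=5)

    def test_solid_mask_matches_centers(self):
        grid = VoxelGrid((20, 20, 20), (1, 1, 1))
        _, truth = gen_sphere_phantom(grid, radius_um=3.0, n_spheres=1, margin_um=0.0, seed=0)
        c = truth.true_points.coords[0]
        # the voxel containing the center is solid, a far corner is not
        k = grid.nearest_voxel(c[None, :])[0]
        assert truth.solid_mask.values[k[0], k[1], k[2]]
        assert truth.solid_mask.voxel_count <= 4 / 3 * np.pi * 3.5**3

    def test_zero_spheres_blank(self, unit_grid):
        img, truth = gen_sphere_phantom(unit_grid, n_spheres=0, noise=NoiseModel(), seed=0)
        assert img.values.max() == 0
        assert len(truth.true_points) == 0


class TestTubePhantom:
    def test_analytic_volume_clipped_to_box(self):
        grid = VoxelGrid((32, 64, 64), (1, 1, 1))
        _, truth = gen_tube_phantom(
            grid, segments=[((16, 32, -10), (16, 32, 74))], outer_radius_um=8
        )
        assert truth.analytic_volume_um3 == pytest.approx(np.pi * 64 * 64)

    def test_solid_volume_near_analytic(self):
        grid = VoxelGrid((32, 64, 64), (1, 1, 1))
        _, truth = gen_tube_phantom(
            grid, segments=[((16, 32, -10), (16, 32, 74))], outer_radius_um=8
        )
        assert truth.solid_mask.volume_um3 == pytest.approx(
            truth.analytic_volume_um3, rel=0.05
        )

    def test_wall_only_signal(self):
        grid = VoxelGrid((32, 64, 64), (1, 1, 1))
        img, _ = gen_tube_phantom(
            grid,
            segments=[((16, 32, -10), (16, 32, 74))],
            outer_radius_um=8,
            wall_thickness_um=2,
        )
        # lumen center and far background are dark, wall mid-thickness bright
        assert img.values[16, 32, 32] == 0.0
        assert img.values[16, 5, 5] == 0.0
        assert img.values[16, 32 + 7, 32] > 0.9
        assert img.values.max() == pytest.approx(1.0, abs=1e-6)

    def test_empty_segments_blank(self, unit_grid):
        img, truth = gen_tube_phantom(unit_grid, segments=[])
        assert img.values.max() == 0 and truth.solid_mask.voxel_count == 0


class TestNucleiPhantom:
    def test_truth_tissue_excludes_bone_only(self):
        grid = VoxelGrid((16, 64, 64), (1, 1, 1))
        _, truth = gen_nuclei_phantom(grid, bone_center_yx=(48, 48), bone_radius_um=10, seed=1)
        tis = truth.solid_mask.values
        assert not tis[8, 48, 48]
        assert tis[8, 10, 10]
        assert tis.all(axis=0).any()

    def test_seed_determinism(self):
        grid = VoxelGrid((12, 32, 32), (1, 1, 1))
        a, _ = gen_nuclei_phantom(grid, seed=9)
        b, _ = gen_nuclei_phantom(grid, seed=9)
        assert np.array_equal(a.values, b.values)


class TestPointPattern:
    def test_labels_and_counts(self, tube_setup):
        pts, truth = gen_point_pattern(
            tube_setup["domain"], n=50, field=tube_setup["field"],
            contact_fraction=0.4, contact_band_um=2.0, seed=2,
        )
        assert len(pts) == 50
        assert (pts.labels == "contact").sum() == 20
        assert truth.point_distances_um.shape == (50,)

    def test_contact_points_lie_in_band(self, tube_setup):
        pts, truth = gen_point_pattern(
            tube_setup["domain"], n=40, field=tube_setup["field"],
            contact_fraction=1.0, contact_band_um=2.0, seed=3,
        )
        d = truth.point_distances_um
        assert np.all((d > 0) & (d <= 2.0))

    def test_pure_csr_inside_domain(self, tube_setup):
        pts, _ = gen_point_pattern(
            tube_setup["domain"], n=80, field=tube_setup["field"],
            contact_fraction=0.0, seed=4,
        )
        _, in_dom = tube_setup["field"].sample_at(pts)
        assert in_dom.all()
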