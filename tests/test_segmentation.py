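"""Segmentation operators on phantoms with exact ground truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from marrow3dqm import VolumetricImage, VoxelGrid
from marrow3dqm.phantoms import gen_nuclei_phantom, gen_tube_phantom
from marrow3dqm.segmentation import (
    NetworkParams,
    TissueMaskParams,
    VesselFillParams,
    fill_vessels,
    segment_network,
    segment_tissue_dapi,
    segment_uct,
    sphericity,
)


class TestTissueMask:
    def test_all_zero_image_empty_mask(self, unit_grid):
        img = VolumetricImage(unit_grid, np.zeros(unit_grid.shape))
        with pytest.warns(UserWarning):
            mask = segment_tissue_dapi(img)
        assert mask.voxel_count == 0

    def test_dense_field_covers_box(self):
        grid = VoxelGrid((24, 64, 64), (1, 1, 1))
        img, _ = gen_nuclei_phantom(grid, seed=2)
        mask = segment_tissue_dapi(img)
        assert mask.voxel_count >= 0.99 * np.prod(grid.shape)

    def test_area_classification_idempotent(self):
        # the void-fill / island-removal classification is an exact fixpoint
        grid = VoxelGrid((24, 64, 64), (1, 1, 1))
        img, _ = gen_nuclei_phantom(grid, bone_center_yx=(48, 48), bone_radius_um=12, seed=2)
        mask = segment_tissue_dapi(img)
        params = TissueMaskParams(gaussian_sigma=0.0, intensity_threshold=0.5,
                                  open_close_radius=0.0)
        again = segment_tissue_dapi(VolumetricImage(grid, mask.values.astype(float)), params)
        assert np.array_equal(mask.values, again.values)

    def test_full_operator_near_idempotent(self):
        # open/close is idempotent away from the image border; reflect
        # padding can flip isolated border voxels, nothing more
        grid = VoxelGrid((24, 64, 64), (1, 1, 1))
        img, _ = gen_nuclei_phantom(grid, bone_center_yx=(48, 48), bone_radius_um=12, seed=2)
        mask = segment_tissue_dapi(img)
        again = segment_tissue_dapi(
            VolumetricImage(grid, mask.values.astype(float)),
            TissueMaskParams(gaussian_sigma=0.0, intensity_threshold=0.5),
        )
        changed = np.count_nonzero(mask.values ^ again.values)
        assert changed <= 1e-3 * mask.voxel_count

    def test_intensity_rescale_invariance(self):
        grid = VoxelGrid((16, 48, 48), (1, 1, 1))
        img, _ = gen_nuclei_phantom(grid, seed=3)
        a = segment_tissue_dapi(img)
        b = segment_tissue_dapi(VolumetricImage(grid, img.values * 7.3))
        assert np.array_equal(a.values, b.values)


class TestFillVessels:
    def test_empty_image_empty_mask(self, unit_grid):
        mask = fill_vessels(VolumetricImage(unit_grid, np.zeros(unit_grid.shape)))
        assert mask.voxel_count == 0

    def test_superset_of_wall(self, tube_setup):
        # filled output contains the true wall shell
        wall = tube_setup["image"].values >= 0.999
        fill = fill_vessels(tube_setup["image"])
        assert np.all(fill.values[wall])

    def test_lumen_reconstructed(self, tube_setup):
        fill = fill_vessels(tube_setup["image"])
        truth = tube_setup["truth"]
        assert fill.volume_um3 == pytest.approx(truth.analytic_volume_um3, rel=0.05)

    def test_structuring_element_exceeding_extent_raises(self):
        grid = VoxelGrid((4, 8, 8), (1, 1, 1))
        img = VolumetricImage(grid, np.ones(grid.shape))
        with pytest.raises(ValueError):
            fill_vessels(img, VesselFillParams(closing1_radius=30.0))

    def test_in_plane_tube_filled(self):
        # tube axis parallel to the optical sections: rings only appear in
        # orthogonal sections, exercised by the multi-axis selective fill
        grid = VoxelGrid((48, 64, 96), (1, 1, 1))
        img, truth = gen_tube_phantom(
            grid, segments=[((24, 32, -10), (24, 32, 106))], outer_radius_um=12
        )
        fill = fill_vessels(img)
        assert fill.volume_um3 == pytest.approx(truth.analytic_volume_um3, rel=0.05)


class TestNetwork:
    def test_small_round_noise_removed_elongated_kept(self):
        grid = VoxelGrid((40, 80, 80), (1, 1, 1))
        img = np.zeros(grid.shape)
        img[18:22, 10:70, 38:42] = 1.0  # elongated bar
        zc, yc, xc = np.ogrid[:40, :80, :80]
        ball = (zc - 10) ** 2 + (yc - 60) ** 2 + (xc - 60) ** 2 <= 3**2
        img[ball] = 1.0  # small round blob
        net = segment_network(
            VolumetricImage(grid, img),
            NetworkParams(max_noise_volume=150, max_noise_sphericity=0.8),
        )
        assert net.values[20, 40, 40]
        assert not net.values[10, 60, 60]

    def test_sphericity_of_ball_near_one(self):
        grid = VoxelGrid((40, 40, 40), (1, 1, 1))
        zc, yc, xc = np.ogrid[:40, :40, :40]
        ball = (zc - 20) ** 2 + (yc - 20) ** 2 + (xc - 20) ** 2 <= 10**2
        s = sphericity(ball, grid.spacing)
        assert 0.9 < s <= 1.1

    def test_sphericity_of_bar_low(self):
        grid = VoxelGrid((40, 40, 40), (1, 1, 1))
        bar = np.zeros(grid.shape, bool)
        bar[18:22, 2:38, 18:22] = True
        assert sphericity(bar, grid.spacing) < 0.7


@pytest.fixture(scope="module")
def shell():
    grid = VoxelGrid((40, 80, 80), (1, 1, 1))
    zc, yc, xc = np.ogrid[:40, :80, :80]
    rho = np.sqrt((yc + 0.5 - 40.0) ** 2 + (xc + 0.5 - 40.0) ** 2)
    img = np.clip(0.5 + (22 - rho), 0, 1) * np.clip(0.5 + (rho - 18), 0, 1)
    return grid, VolumetricImage(grid, np.broadcast_to(img, grid.shape).copy())


class TestUct:
    def test_marrow_volume(self, shell):
        grid, img = shell
        bone, marrow = segment_uct(img, bone_threshold=0.5)
        assert marrow.volume_um3 == pytest.approx(np.pi * 18**2 * 40, rel=0.05)

    def test_masks_disjoint_union_is_femur(self, shell):
        grid, img = shell
        bone, marrow = segment_uct(img, bone_threshold=0.5)
        assert not (bone.values & marrow.values).any()
        femur = fill_vessels(img)
        assert (bone.voxel_count + marrow.voxel_count) == femur.voxel_count

    def test_threshold_outside_range_warns(self, shell):
        grid, img = shell
        with pytest.warns(UserWarning):
            segment_uct(img, bone_threshold=99.0)
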