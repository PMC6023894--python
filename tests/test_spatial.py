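"""ESD statistics, CDFs, KS spatial test, perivascular classification."""

import numpy as np
import pytest

from marrow3dqm import (
    BinaryMask,
    EmpiricalCDF,
    IncompatibleGridError,
    PointSet,
    VoxelGrid,
    aggregate_cdfs,
    cdf_at_points,
    classify_by_distance,
    coverage_fraction,
    esd_cdf,
    esd_transform,
    ks_spatial_test,
    make_extravascular_domain,
)
from marrow3dqm.phantoms import gen_point_pattern


class TestDomain:
    def test_vessels_empty_domain_equals_tissue(self, unit_grid):
        tis = np.random.default_rng(0).random(unit_grid.shape) < 0.5
        tissue = BinaryMask(unit_grid, tis, role="tissue")
        vessels = BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool), role="vessel")
        dom = make_extravascular_domain(tissue, vessels)
        assert np.array_equal(dom.values, tis)

    def test_vessels_cover_tissue_warns_empty(self, unit_grid):
        ones = np.ones(unit_grid.shape, bool)
        tissue = BinaryMask(unit_grid, ones, role="tissue")
        vessels = BinaryMask(unit_grid, ones, role="vessel")
        with pytest.warns(UserWarning):
            dom = make_extravascular_domain(tissue, vessels)
        assert dom.voxel_count == 0

    def test_random_masks_boolean_oracle(self, unit_grid):
        rng = np.random.default_rng(1)
        t = rng.random(unit_grid.shape) < 0.6
        v = rng.random(unit_grid.shape) < 0.3
        dom = make_extravascular_domain(
            BinaryMask(unit_grid, t, role="tissue"),
            BinaryMask(unit_grid, v, role="vessel"),
        )
        assert np.array_equal(dom.values, t & ~v)

    def test_grid_mismatch(self, unit_grid, aniso_grid):
        with pytest.raises(IncompatibleGridError):
            make_extravascular_domain(
                BinaryMask(unit_grid, np.ones(unit_grid.shape, bool), role="tissue"),
                BinaryMask(aniso_grid, np.ones(aniso_grid.shape, bool), role="vessel"),
            )


class TestEsdTransform:
    def test_empty_target_raises(self, unit_grid):
        empty = BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool), role="vessel")
        dom = BinaryMask(unit_grid, np.ones(unit_grid.shape, bool), role="domain")
        with pytest.raises(ValueError):
            esd_transform(empty, dom)

    def test_anisotropic_plane_distances(self):
        grid = VoxelGrid((10, 6, 6), (3.0, 1.0, 1.0))
        target = np.zeros(grid.shape, bool)
        target[0] = True  # plane at k=0
        dom = BinaryMask(grid, np.ones(grid.shape, bool), role="domain")
        f = esd_transform(BinaryMask(grid, target, role="vessel"), dom)
        # distance grows by dz=3 per slice
        assert f.values[4, 2, 2] == pytest.approx(12.0)

    def test_on_target_flagged_zero(self, tube_setup):
        f = tube_setup["field"]
        # in this setup the domain excludes the vessel so nothing is on target
        assert not f.on_target.any()
        assert np.nanmin(f.values) > 0


class TestCdf:
    def test_monotone_ends_at_one(self, tube_setup):
        cdf = esd_cdf(tube_setup["field"], bin_width=1.0)
        assert np.all(np.diff(cdf.values) >= 0)
        assert cdf.values[-1] == 1.0

    def test_slab_linear_growth(self):
        # plane target on one face of a unit-spacing box: uniform distance
        # distribution, CDF linear in depth
        grid = VoxelGrid((50, 8, 8), (1.0, 1.0, 1.0))
        target = np.zeros(grid.shape, bool)
        target[0] = True
        dom = BinaryMask(grid, np.ones(grid.shape, bool), role="domain")
        f = esd_transform(BinaryMask(grid, target, role="vessel"), dom)
        cdf = esd_cdf(f, bin_width=1.0, exclude_target_interior=True)
        # after excluding the target plane, 49 slices at distances 1..49
        expected = np.arange(1, 50) / 49.0
        assert np.allclose(cdf.values[:49], expected)

    def test_all_zero_field_cdf_at_zero_one(self, unit_grid):
        ones = np.ones(unit_grid.shape, bool)
        dom = BinaryMask(unit_grid, ones, role="domain")
        f = esd_transform(BinaryMask(unit_grid, ones, role="vessel"), dom)
        cdf = esd_cdf(f, exclude_target_interior=False)
        assert cdf.value_at_zero == 1.0

    def test_guard_zone_restricts_samples(self, tube_setup):
        full = esd_cdf(tube_setup["field"])
        guarded = esd_cdf(tube_setup["field"], guard_zone_um=10.0)
        assert guarded.n_samples < full.n_samples

    def test_invalid_cdf_rejected(self):
        with pytest.raises(ValueError):
            EmpiricalCDF(np.array([0.0, 1.0, 2.0]), np.array([0.5, 0.4]), 10)

    def test_coverage_fraction_lookup(self):
        cdf = EmpiricalCDF(np.array([0.0, 1.0, 2.0]), np.array([0.3, 1.0]), 10,
                           value_at_zero=0.1)
        assert coverage_fraction(cdf, -1.0) == 0.1
        assert coverage_fraction(cdf, 1.0) == pytest.approx(0.3)
        assert coverage_fraction(cdf, 5.0) == 1.0

    def test_cdf_at_points_outside_warns(self, tube_setup):
        pts = PointSet(np.array([[24.0, 30.0, 30.0], [24.0, 60.0, 60.0]]))
        # first point is inside the vessel (outside the domain)
        with pytest.warns(UserWarning):
            cdf = cdf_at_points(tube_setup["field"], pts)
        assert cdf.n_samples == 1


class TestAggregate:
    def test_same_grid_mean_sd(self):
        e = np.array([0.0, 1.0, 2.0])
        a = EmpiricalCDF(e, np.array([0.2, 1.0]), 5)
        b = EmpiricalCDF(e, np.array([0.4, 1.0]), 5)
        env = aggregate_cdfs([a, b])
        assert env.mean[0] == pytest.approx(0.3)
        assert env.sd[0] == pytest.approx(np.std([0.2, 0.4], ddof=1))

    def test_mixed_grids_resampled(self):
        a = EmpiricalCDF(np.array([0.0, 1.0, 2.0]), np.array([0.5, 1.0]), 5)
        b = EmpiricalCDF(np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]),
                         np.array([0.1, 0.2, 0.4, 0.6, 0.8, 1.0]), 5)
        env = aggregate_cdfs([a, b])
        assert env.bin_edges[-1] == pytest.approx(3.0)
        assert np.all(np.diff(env.mean) >= -1e-12)


class TestKs:
    def test_csr_large_p(self, tube_setup):
        pts, _ = gen_point_pattern(
            tube_setup["domain"], n=150, field=tube_setup["field"],
            contact_fraction=0.0, seed=12,
        )
        res = ks_spatial_test(tube_setup["field"], pts, voxel_subsample=20_000, seed=0)
        assert res.p_value > 0.01

    def test_strong_contact_rejected(self, tube_setup):
        pts, _ = gen_point_pattern(
            tube_setup["domain"], n=150, field=tube_setup["field"],
            contact_fraction=0.9, contact_band_um=2.0, seed=13,
        )
        res = ks_spatial_test(tube_setup["field"], pts, voxel_subsample=20_000, seed=0)
        assert res.p_value < 1e-6

    def test_subsample_deterministic(self, tube_setup):
        pts, _ = gen_point_pattern(
            tube_setup["domain"], n=50, field=tube_setup["field"], seed=14
        )
        r1 = ks_spatial_test(tube_setup["field"], pts, voxel_subsample=5_000, seed=3)
        r2 = ks_spatial_test(tube_setup["field"], pts, voxel_subsample=5_000, seed=3)
        assert r1.D == r2.D and r1.p_value == r2.p_value

    def test_too_few_points(self, tube_setup):
        with pytest.raises(ValueError):
            ks_spatial_test(tube_setup["field"], PointSet(np.zeros((1, 3))))


class TestClassify:
    def test_centroid_threshold(self, tube_setup):
        pts, truth = gen_point_pattern(
            tube_setup["domain"], n=100, field=tube_setup["field"], seed=15
        )
        labels, frac = classify_by_distance(pts, tube_setup["field"], threshold=5.0)
        d = truth.point_distances_um
        assert frac == pytest.approx(np.mean(d < 5.0))
        assert np.array_equal(labels == "peri", d < 5.0)

    def test_surface_mode_needs_radius(self, tube_setup):
        pts = PointSet(np.array([[24.0, 60.0, 60.0]]))
        with pytest.raises(ValueError):
            classify_by_distance(pts, tube_setup["field"], mode="surface")

    def test_surface_mode_shifts_threshold(self, tube_setup):
        pts, _ = gen_point_pattern(
            tube_setup["domain"], n=100, field=tube_setup["field"], seed=16
        )
        _, frac_c = classify_by_distance(pts, tube_setup["field"], threshold=5.0)
        _, frac_s = classify_by_distance(
            pts, tube_setup["field"], threshold=5.0, mode="surface", radius=3.0
        )
        assert frac_s >= frac_c
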