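# Methods

This note documents the quantitative model behind `marrow3dqm`, the
parameter choices, and the numerical decisions that affect results. All
distances are µm, volumes µm³ internally and mm³ (= µL) in reports;
arrays are ordered (z, y, x) and point coordinates are physical µm with
the voxel `(k, j, i)` centered at `((k+0.5)·dz, (j+0.5)·dy, (i+0.5)·dx)`.

## 1. Geometric model

A study volume is a `VoxelGrid` (shape + anisotropic spacing). On it
live scalar channels (`VolumetricImage`), role-tagged binary masks
(`BinaryMask`: tissue / vessel / network / bone / marrow / domain),
point patterns (`PointSet`, optional shared soma radius), and distance
fields (`DistanceField`, defined only on a domain mask, NaN elsewhere).
Mask volume is exactly `voxel_count × dz·dy·dx`.

## 2. Segmentation

**Tissue (nuclear stain).** 3D anisotropic Gaussian smoothing
(`gaussian_sigma` 2 µm) → global threshold (default 0.25 of the image
maximum, so results are invariant under positive intensity rescaling) →
per-slice opening then closing with a disk of `open_close_radius` 5 µm →
per-slice connected-component area classification: enclosed background
components below `min_void_area` (200 µm²) are voids between cells and
are included; foreground islands below `min_island_area` (200 µm²)
disconnected from the main body are removed. Slices are reflect-padded
before the morphology; without that the opening erodes a full
structuring-element radius from every slice border (−17.6% volume on the
validation phantom). The area-classification stage is an exact fixpoint;
the open∘close filter is idempotent away from image borders.

**Vessels (wall marker).** The wall signal is a hollow shell, so a solid
lumen mask is reconstructed: reflect-pad → local mean threshold (cubic
window `local_threshold_window` 20 µm, additive offset 0.1 of the image
maximum) → per-slice closing (2 µm), opening (0.5 µm), closing (2 µm) →
selective hole filling — per-slice background components not touching
the slice border with area ≤ `fill_max_hole_area` (2000 µm²) are filled
— applied along all three axes (a tube running parallel to the optical
sections only shows closed rings in orthogonal re-slices) → 3D
anisotropy-aware ball closing (2 µm) → crop. The opening default is
0.5 µm because a 1 µm opening destroys 2 µm walls at the tube mid-plane;
it exists to remove sub-µm noise on finer grids. The filled output is a
superset of the thresholded wall voxels. Resolution limit: the closings
dilate the wall by ≈ 0.3 µm, so relative volume error scales as
2·0.3/r — 3.5% for r = 15 µm sinusoids, 5.7% at r = 10 µm.

**Networks.** Intensity threshold → 26-connected components → remove
components with volume ≤ `max_noise_volume` (100 µm³) **and** Wadell
sphericity ≥ `max_noise_sphericity` (0.8), with sphericity
π^(1/3)(6V)^(2/3)/A and A from a marching-cubes mesh of the component.

**µ-CT.** The bright cortical shell is treated like a vessel wall: the
filling pipeline reconstructs the solid femur, which is then split at
`bone_threshold` into bone (≥) and marrow (<). The two masks are
disjoint and their union is exactly the filled femur.

## 3. Empty-space-distance statistics

`esd_transform` computes the exact anisotropic Euclidean distance
between voxel centers (`scipy.ndimage.distance_transform_edt` with
`sampling=spacing`) from every domain voxel to the target structure;
matching a brute-force nearest-target-voxel search to < 10⁻⁹ µm. Target
voxels inside the domain are distance 0 and flagged so statistics can
exclude structure interiors.

`esd_cdf` bins the distances with exact "fraction ≤ right edge"
semantics (sorted counting, not `np.histogram`, whose left-closed bins
misplace samples that fall exactly on an edge — common on unit grids).
No edge correction is applied by default; for comparisons against
stationary-model predictions at range r, `guard_zone_um ≥ r` restricts
evaluation to voxels at least that far from the domain boundary (the
implementation pads the domain with background so the image border
counts as boundary).

The KS spatial-dependency test (`ks_spatial_test`) is a two-sample
Kolmogorov–Smirnov test between distances at cell centroids and
distances over (up to 10⁵ seeded-subsampled) domain voxels. Calibration
on CSR phantoms: rejection rate 0.04–0.065 at α = 0.05 over 200
replicates; power 1.0 against a 60% perivascular mixture with a 2 µm
contact band. `classify_by_distance` labels cells perivascular below a
threshold (default 5 µm), either on centroid distance or
surface-to-surface (centroid distance minus soma radius, clamped at 0).

## 4. Soma detection

Single-scale Laplacian-of-Gaussian matched to the soma radius
(σ = R/√3, default R = 3.75 µm). The Laplacian is taken in physical
units (per-axis second differences divided by spacing²) — a voxel-unit
Laplacian is wrong on anisotropic grids — scaled by σ² and normalized by
the image maximum times 0.9245, the numerically calibrated response of
an ideal unit-contrast ball, so a full-contrast in-focus soma scores
≈ 1 and `detection_threshold` (0.3) is an interpretable contrast
fraction. Local maxima above threshold undergo greedy non-maximum
suppression at `min_separation` (4 µm). Evaluation follows the standard
counting protocol: greedy one-to-one matching by ascending pair
distance, pairs < 5 µm are TP, precision = TP/(TP+FP),
recall = TP/(TP+FN); undefined ratios are NaN, never silently 0.
Validation: 300-sphere Boolean phantom with noise → precision 1.00,
recall 0.96–0.98.

## 5. Density maps and quantification

`density_map_3d` builds f(u) = (1/n) Σ K_σ(u − xᵢ) with separable
Gaussian kernels supported on ±4σ, σ defaulting to the pattern's mean
nearest-neighbour distance. Each discrete kernel is normalized by its
own voxel sum (unit mass on any grid) and, with a tissue mask, by its
in-mask mass, so the map integrates to exactly 1 over tissue even for
boundary-hugging points; `boundary="none"` gives plain truncation.
`project_density_2d` is the per-(y,x)-column mean over in-mask voxels.

Quantification is deliberately plain algebra kept in one audited place:
density = count / tissue mm³; organ counts = density × µ-CT marrow
volume; imaging/suspension fold and percent-undetected identities
(fold(a,b)·fold(b,a) = 1, pct = 100(1−1/fold)); vessel volume fraction
= |vessels ∩ tissue| / |tissue|.

## 6. Phantoms and their limits

All generators are pure functions of (parameters, seed) with exact
ground truth. Spheres: Boolean model (Poisson germs, fixed radius);
tubes: hollow walls around straight segments; nuclei: dense small blobs
with voids and a signal-free bone pocket. Edges are rendered with a
1-voxel partial-volume ramp whose half-maximum lies exactly on the
object surface, so threshold-at-half recovers the analytic geometry.
Germs can be drawn in a margin-dilated box (balls clipped to the grid)
to emulate stationary processes; the tube truth's analytic volume counts
only the in-box segment portion. Three rasterizations of the analytic
sets are recorded: center-rule (`solid_mask`), cube-touching
(`touch_mask`), and center-rule dilated by 0.3·mean(spacing)
(`distance_target_mask`) — the last makes voxel-center EDT distances to
the continuum surface approximately unbiased (+0.29 µm for solid,
−0.45 µm for touch), calibrated against a continuum nearest-surface
oracle.

Phantoms are idealized: no anisotropic PSF, no depth-dependent
attenuation, no autofluorescence gradients, straight rather than
tortuous vessels. They validate the estimators' correctness, not
robustness to every acquisition artifact.

**Boolean-model validation.** With unbiased rasterization, margin germs
and a 20 µm guard zone, the mean empirical CDF over 16 independent
realizations is within 0.013 sup-norm of the closed form
H(r) = 1 − exp(−λ(4π/3)((r+R)³−R³)) (λ = 5×10⁻⁵ µm⁻³, R = 4 µm,
200×200×64 box). A single realization of that box contains only ~350
balls, and the Poisson count fluctuation alone produces per-realization
sup deviations of 0.014–0.14 (median ≈ 0.045); single-realization
agreement to 0.02 is therefore not statistically attainable at this
window size, and the corresponding strict test in the acceptance suite
documents this as an expected failure of the study conditions, not of
the estimator.

## 7. Problem sizes and runtime

Default phantom scales (≤ 200×200×64 voxels at 1 µm) keep every
validation under a minute on one CPU; the full test suite runs in about
a minute and `scripts/acceptance.py` in ~20 s. These sizes are the
package's own choices for desk-scale validation.
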