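"""Empty-space-distance statistics and spatial-dependency testing.

The empty space distance (ESD) transform assigns every voxel *u* of an
analysis domain *W* (typically the extravascular tissue) its Euclidean
distance *Z(u)* to the nearest voxel containing a fragment of a target
structure (sinusoids, cell somata, ECM). Its cumulative distribution
gives the fraction of tissue volume within any distance of the target;
evaluated at cell centroids instead of all voxels, it describes how a
cell population positions itself relative to the structure.

Under the null hypothesis that cell positions are not influenced by
their distance to the target, the centroid distances are a random sample
of the voxel distances; a two-sample Kolmogorov–Smirnov test compares
the two. Distances are computed with an exact anisotropic Euclidean
distance transform between voxel centers; no edge correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .geometry import (
    BinaryMask,
    DistanceField,
    IncompatibleGridError,
    PointSet,
)

__all__ = [
    "EmpiricalCDF",
    "CDFEnvelope",
    "KSResult",
    "make_extravascular_domain",
    "esd_transform",
    "esd_cdf",
    "cdf_at_points",
    "ks_spatial_test",
    "classify_by_distance",
    "coverage_fraction",
    "aggregate_cdfs",
]


@dataclass
class EmpiricalCDF:
    """Binned cumulative distribution of distances.

    ``bin_edges`` has length ``m + 1`` starting at 0; ``values[i]`` is the
    fraction of samples ≤ ``bin_edges[i + 1]`` (left-open bins), so the
    last value is exactly 1. ``value_at_zero`` is the fraction of exact
    zeros (distance-0 samples on the target surface).
    """

    bin_edges: np.ndarray
    values: np.ndarray
    n_samples: int
    value_at_zero: float = 0.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bin_edges) != len(self.values) + 1:
            raise ValueError("need len(bin_edges) == len(values) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("CDF values must be non-decreasing")
        if self.values.size and not np.isclose(self.values[-1], 1.0):
            raise ValueError("CDF must end at 1")


@dataclass
class CDFEnvelope:
    """Per-bin mean ± sample SD across several empirical CDFs."""

    bin_edges: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    k: int


@dataclass
class KSResult:
    """Two-sample Kolmogorov–Smirnov outcome for the spatial test."""

    D: float
    p_value: float
    n_background: int
    n_points: int

    def __post_init__(self):
        if not 0 <= self.D <= 1:
            raise ValueError("D must be in [0, 1]")


def make_extravascular_domain(tissue: BinaryMask, vessels: BinaryMask) -> BinaryMask:
    """Analysis window W: tissue voxels outside the vessel lumen."""
    if tissue.grid != vessels.grid:
        raise IncompatibleGridError("tissue and vessel masks live on different grids")
    dom = tissue.values & ~vessels.values
    if not dom.any():
        warnings.warn("extravascular domain is empty (vessels cover all tissue)")
    return BinaryMask(tissue.grid, dom, role="domain")


def esd_transform(target: BinaryMask, domain: BinaryMask) -> DistanceField:
    """Exact anisotropic Euclidean distance to the target, on the domain.

    For every domain voxel ``Z(u)`` is the minimum physical distance
    between voxel centers to any target voxel; target voxels themselves
    are at distance 0 and flagged via ``on_target`` so callers can
    exclude structure-interior voxels from statistics.
    """
    if target.grid != domain.grid:
        raise IncompatibleGridError("target and domain masks live on different grids")
    if not target.values.any():
        raise ValueError("empty target: distance field undefined")
    dist = ndi.distance_transform_edt(~target.values, sampling=target.grid.spacing)
    vals = np.where(domain.values, dist, np.nan)
    return DistanceField(
        grid=target.grid,
        domain=domain,
        values=vals,
        target_role=target.role,
        on_target=target.values & domain.values,
    )


def _build_cdf(samples: np.ndarray, bin_width: float) -> EmpiricalCDF:
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples to build a CDF from")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    top = float(samples.max())
    n_bins = max(1, int(np.ceil(top / bin_width - 1e-12)))
    edges = np.arange(n_bins + 1) * bin_width
    # left-open "≤ right edge" semantics: count samples ≤ each edge
    srt = np.sort(samples)
    values = np.searchsorted(srt, edges[1:], side="right") / samples.size
    values[-1] = 1.0
    return EmpiricalCDF(
        bin_edges=edges,
        values=values,
        n_samples=int(samples.size),
        value_at_zero=float(np.mean(samples == 0.0)),
    )


def esd_cdf(
    field: DistanceField,
    bin_width: float = 1.0,
    exclude_target_interior: bool = True,
    guard_zone_um: float = 0.0,
) -> EmpiricalCDF:
    """Cumulative distribution of voxel distances over the domain.

    The result is the empirical fraction of (extravascular) volume within
    each distance of the target. With ``exclude_target_interior`` (the
    default) voxels lying on/inside the target are left out, so the CDF
    describes the genuinely empty space.

    ``guard_zone_um`` optionally restricts the evaluation to domain
    voxels at least that far from the domain boundary. No correction is
    applied by default (for densely occupied structures the boundary
    effect is negligible), but distances near the window border are
    censored — the true nearest structure may lie outside the imaged
    volume — so comparisons against stationary-model predictions at range
    r should use a guard zone of at least r.
    """
    sel = field.domain.values
    if exclude_target_interior:
        sel = sel & ~field.on_target
    if guard_zone_um > 0:
        # pad with background so the image border counts as domain boundary
        padded = np.pad(field.domain.values, 1, constant_values=False)
        core = (
            ndi.distance_transform_edt(padded, sampling=field.grid.spacing)[
                1:-1, 1:-1, 1:-1
            ]
            > guard_zone_um
        )
        sel = sel & core
    vals = field.values[sel]
    if vals.size == 0:
        raise ValueError("empty domain: cannot build a CDF")
    return _build_cdf(vals, bin_width)


def cdf_at_points(
    field: DistanceField, points: PointSet, bin_width: float = 1.0
) -> EmpiricalCDF:
    """CDF of the field sampled at point locations (nearest-voxel lookup).

    Points outside the domain are excluded with a warning; the number of
    retained samples is recorded in ``n_samples``.
    """
    vals, in_domain = field.sample_at(points)
    n_out = int((~in_domain).sum())
    if n_out:
        warnings.warn(f"{n_out} point(s) outside the domain excluded from the CDF")
    vals = vals[in_domain]
    if vals.size == 0:
        raise ValueError("no points inside the domain")
    return _build_cdf(vals, bin_width)


def ks_spatial_test(
    field: DistanceField,
    points: PointSet,
    voxel_subsample: int | str = 100_000,
    seed: int | None = 0,
    exclude_target_interior: bool = True,
) -> KSResult:
    """Two-sample KS test of spatial dependency on the target.

    Compares the distances at the point locations with the distances over
    the (optionally subsampled) domain voxels. A small p-value rejects
    the null hypothesis that the points are positioned independently of
    their distance to the target structure.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points for the spatial test")
    background = field.domain_values(exclude_target_interior=exclude_target_interior)
    if background.size == 0:
        raise ValueError("empty domain")
    if voxel_subsample != "all" and int(voxel_subsample) < background.size:
        rng = np.random.default_rng(seed)
        background = rng.choice(background, size=int(voxel_subsample), replace=False)
    pvals, in_domain = field.sample_at(points)
    pvals = pvals[in_domain]
    if pvals.size < 2:
        raise ValueError("fewer than 2 points inside the domain")
    res = stats.ks_2samp(background, pvals)
    return KSResult(
        D=float(res.statistic),
        p_value=float(res.pvalue),
        n_background=int(background.size),
        n_points=int(pvals.size),
    )


def classify_by_distance(
    points: PointSet,
    field: DistanceField,
    threshold: float = 5.0,
    mode: str = "centroid",
    radius: float | None = None,
) -> tuple[np.ndarray, float]:
    """Label points as perivascular or not by a distance threshold.

    ``mode='centroid'``: a point is ``peri`` iff its centroid distance to
    the target surface is below ``threshold``. ``mode='surface'``: the
    shared soma radius is subtracted first (clamped at 0 for centroids
    inside the target), so the criterion is surface-to-surface distance.
    Returns the label array and the perivascular fraction.
    """
    if mode not in ("centroid", "surface"):
        raise ValueError("mode must be 'centroid' or 'surface'")
    if mode == "surface":
        r = radius if radius is not None else points.radius
        if r is None:
            raise ValueError("surface mode requires a soma radius")
    vals, in_domain = field.sample_at(points)
    if not in_domain.all():
        warnings.warn(
            f"{int((~in_domain).sum())} point(s) outside the domain excluded "
            "from classification"
        )
    vals = vals[in_domain]
    if mode == "surface":
        vals = np.maximum(vals - r, 0.0)
    labels = np.where(vals < threshold, "peri", "non_peri")
    frac = float(np.mean(vals < threshold)) if vals.size else float("nan")
    return labels, frac


def coverage_fraction(cdf: EmpiricalCDF, distance: float) -> float:
    """Fraction of volume within ``distance`` of the target (step lookup).

    Left-open bin convention: the value at a bin's right edge is the
    fraction ≤ that edge; ``distance <= 0`` returns the fraction of exact
    zeros, anything at or beyond the last edge returns 1.
    """
    if distance <= 0:
        return cdf.value_at_zero
    if distance >= cdf.bin_edges[-1]:
        return 1.0
    idx = int(np.searchsorted(cdf.bin_edges, distance, side="left")) - 1
    idx = max(idx, 0)
    return float(cdf.values[idx])


def aggregate_cdfs(cdfs: list[EmpiricalCDF]) -> CDFEnvelope:
    """Per-bin mean and sample SD across several empirical CDFs.

    CDFs on different bin grids are resampled (step-function evaluation)
    onto a common grid: bin width = finest input width, extent = largest
    input extent.
    """
    if not cdfs:
        raise ValueError("need at least one CDF")
    same = all(
        len(c.bin_edges) == len(cdfs[0].bin_edges)
        and np.allclose(c.bin_edges, cdfs[0].bin_edges)
        for c in cdfs
    )
    if same:
        edges = cdfs[0].bin_edges
        stackvals = np.stack([c.values for c in cdfs])
    else:
        width = min(float(np.min(np.diff(c.bin_edges))) for c in cdfs)
        top = max(float(c.bin_edges[-1]) for c in cdfs)
        n_bins = int(np.ceil(top / width - 1e-9))
        edges = np.arange(n_bins + 1) * width
        stackvals = np.stack(
            [[coverage_fraction(c, e) for e in edges[1:]] for c in cdfs]
        )
    mean = stackvals.mean(axis=0)
    sd = stackvals.std(axis=0, ddof=1) if len(cdfs) > 1 else np.zeros(mean.shape)
    return CDFEnvelope(bin_edges=edges, mean=mean, sd=sd, k=len(cdfs))
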