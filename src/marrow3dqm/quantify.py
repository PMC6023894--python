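"""Headline quantification: densities, absolute counts, volume fractions.

These operators turn segmentation masks, detected point sets and µ-CT
organ volumes into the pipeline's summary quantities: cells per mm³ of
tissue, organ-wide absolute cell counts (density × total marrow volume),
the fraction of marrow occupied by vessel lumina, and the fold
discrepancy between imaging-based and cell-suspension (flow cytometry)
counts. Internal volumes are µm³; reported volumes mm³ (1 mm³ = 1 µL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import BinaryMask, IncompatibleGridError

__all__ = [
    "QuantReport",
    "cell_density",
    "weighted_region_average",
    "absolute_count",
    "fold_and_undetected",
    "vessel_volume_fraction",
]


@dataclass
class QuantReport:
    """Summary of one quantification run (densities in cells/mm³)."""

    cell_density: float = float("nan")
    region_volumes_mm3: dict = field(default_factory=dict)
    total_bm_volume_mm3: float = float("nan")
    absolute_count: float = float("nan")
    vessel_volume_fraction_pct: float = float("nan")
    fold: float = float("nan")
    percent_undetected: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "cell_density_per_mm3": self.cell_density,
            "region_volumes_mm3": self.region_volumes_mm3,
            "total_bm_volume_mm3": self.total_bm_volume_mm3,
            "absolute_count": self.absolute_count,
            "vessel_volume_fraction_pct": self.vessel_volume_fraction_pct,
            "fold": self.fold,
            "percent_undetected": self.percent_undetected,
        }


def cell_density(n_cells: float, tissue_volume_mm3: float) -> float:
    """Cells per mm³ of tissue."""
    if tissue_volume_mm3 <= 0:
        raise ValueError("tissue volume must be > 0")
    if n_cells < 0:
        raise ValueError("cell count must be >= 0")
    return n_cells / tissue_volume_mm3


def weighted_region_average(
    values: Sequence[float], weights: Sequence[float]
) -> float:
    """Volume-weighted average of per-region values (e.g. densities).

    Weighting region densities by the imaged tissue volumes makes the
    average the pooled density over the combined volume.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1D and the same length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be >= 0 and not all zero")
    return float((v * w).sum() / w.sum())


def absolute_count(density_per_mm3: float, total_volume_mm3: float) -> float:
    """Organ-wide cell count: mean density × total organ volume."""
    if density_per_mm3 < 0 or total_volume_mm3 < 0:
        raise ValueError("density and volume must be >= 0")
    return density_per_mm3 * total_volume_mm3


def fold_and_undetected(
    imaging_count: float, suspension_count: float
) -> tuple[float, float]:
    """Imaging/suspension fold ratio and % of cells missed in suspension.

    ``fold = imaging / suspension``;
    ``percent_undetected = 100 × (1 − suspension / imaging)``.
    """
    if suspension_count <= 0:
        raise ValueError("suspension count must be > 0 for the fold ratio")
    if imaging_count <= 0:
        raise ValueError("imaging count must be > 0 for the undetected fraction")
    fold = imaging_count / suspension_count
    percent = 100.0 * (1.0 - suspension_count / imaging_count)
    return fold, percent


def vessel_volume_fraction(vessels: BinaryMask, tissue: BinaryMask) -> float:
    """Percent of tissue volume occupied by (intra)vascular space."""
    if vessels.grid != tissue.grid:
        raise IncompatibleGridError("vessel and tissue masks live on different grids")
    n_tissue = tissue.voxel_count
    if n_tissue == 0:
        raise ValueError("empty tissue mask")
    n_inter = int(np.count_nonzero(vessels.values & tissue.values))
    return 100.0 * n_inter / n_tissue
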