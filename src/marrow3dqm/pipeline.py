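"""End-to-end workflow: stacks in, quantification report out.

``run_pipeline`` chains the stages — tissue mask from the nuclear stain,
vessel filling from the wall marker, soma detection, extravascular
domain, ESD/CDF/KS spatial statistics, density map, quantification —
logging every stage's parameters to a JSON sidecar. The run is
deterministic given the config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io
from .density import density_map_3d, nn_sigma, project_density_2d
from .geometry import MM3_PER_UM3, mask_volume
from .quantify import (
    QuantReport,
    absolute_count,
    cell_density,
    fold_and_undetected,
    vessel_volume_fraction,
)
from .segmentation import (
    TissueMaskParams,
    VesselFillParams,
    fill_vessels,
    segment_tissue_dapi,
)
from .spatial import (
    cdf_at_points,
    classify_by_distance,
    coverage_fraction,
    esd_cdf,
    esd_transform,
    ks_spatial_test,
    make_extravascular_domain,
)
from .spots import SpotParams, detect_spots

logger = logging.getLogger("marrow3dqm")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``nuclear_path`` and ``vessel_path`` are single-channel TIFF stacks;
    spacing (dz, dy, dx µm) is required unless present in OME metadata.
    """

    nuclear_path: str
    vessel_path: str
    soma_path: Optional[str] = None  # defaults to the nuclear channel
    spacing: Optional[tuple[float, float, float]] = None
    output_dir: str = "."
    seed: int = 0
    tissue_params: TissueMaskParams = field(default_factory=TissueMaskParams)
    vessel_params: VesselFillParams = field(default_factory=VesselFillParams)
    spot_params: SpotParams = field(default_factory=SpotParams)
    peri_threshold_um: float = 5.0
    coverage_distances_um: tuple[float, ...] = (10.0, 30.0)
    uct_volume_mm3: Optional[float] = None
    fc_count: Optional[float] = None
    voxel_subsample: int = 100_000

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = io.load_config(path)
        for key, klass in (
            ("tissue_params", TissueMaskParams),
            ("vessel_params", VesselFillParams),
            ("spot_params", SpotParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if "spacing" in raw and raw["spacing"] is not None:
            raw["spacing"] = tuple(raw["spacing"])
        return cls(**raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
        return out

    return wrap


def run_pipeline(config: RunConfig) -> QuantReport:
    """Execute the full workflow and write artifacts to the output dir.

    Writes the tissue and vessel masks, the detected soma coordinates,
    the per-bin CDFs and a versioned JSON report; returns the
    :class:`QuantReport`.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed}

    nuclear = _stage("read-nuclear")(io.read_image, config.nuclear_path, config.spacing)
    vessel_img = _stage("read-vessel")(io.read_image, config.vessel_path, config.spacing)
    soma_img = (
        _stage("read-soma")(io.read_image, config.soma_path, config.spacing)
        if config.soma_path
        else nuclear
    )

    tissue = _stage("segment-tissue")(segment_tissue_dapi, nuclear, config.tissue_params)
    io.write_mask(out / "tissue.tif", tissue)
    vessels = _stage("fill-vessels")(fill_vessels, vessel_img, config.vessel_params)
    io.write_mask(out / "vessels.tif", vessels)

    domain = _stage("extravascular-domain")(make_extravascular_domain, tissue, vessels)
    spots = _stage("detect-spots")(detect_spots, soma_img, config.spot_params, domain)
    io.write_points(out / "spots.csv", spots)

    field_v = _stage("esd")(esd_transform, vessels, domain)
    cdf_all = _stage("esd-cdf")(esd_cdf, field_v)
    ks = _stage("ks-test")(
        ks_spatial_test,
        field_v,
        spots,
        voxel_subsample=config.voxel_subsample,
        seed=config.seed,
    ) if len(spots) >= 2 else None
    labels, peri_frac = (
        _stage("classify")(classify_by_distance, spots, field_v, config.peri_threshold_um)
        if len(spots)
        else (np.zeros(0, dtype="<U8"), float("nan"))
    )

    if len(spots) >= 2:
        dmap = _stage("density-map")(
            density_map_3d, spots, nuclear.grid, tissue, nn_sigma(spots)
        )
        map2d = project_density_2d(dmap, tissue)
        np.savetxt(out / "density_2d.csv", map2d, delimiter=",")
        provenance["density_sigma_um"] = dmap.sigma

    tissue_mm3 = mask_volume(tissue, "mm3")
    report = QuantReport()
    report.region_volumes_mm3 = {"imaged": tissue_mm3}
    if tissue_mm3 > 0:
        report.cell_density = cell_density(len(spots), tissue_mm3)
        report.vessel_volume_fraction_pct = vessel_volume_fraction(vessels, tissue)
    if config.uct_volume_mm3 is not None and tissue_mm3 > 0:
        report.total_bm_volume_mm3 = config.uct_volume_mm3
        report.absolute_count = absolute_count(report.cell_density, config.uct_volume_mm3)
        if config.fc_count is not None and report.absolute_count > 0:
            report.fold, report.percent_undetected = fold_and_undetected(
                report.absolute_count, config.fc_count
            )

    result = report.to_dict()
    result["peri_fraction"] = peri_frac
    result["coverage"] = {
        f"within_{d:g}_um": coverage_fraction(cdf_all, d)
        for d in config.coverage_distances_um
    }
    if ks is not None:
        result["ks"] = {
            "D": ks.D,
            "p_value": ks.p_value,
            "n_background": ks.n_background,
            "n_points": ks.n_points,
        }
    result["n_spots"] = len(spots)
    result["provenance"] = provenance
    (out / "report.json").write_text(json.dumps(result, indent=2))
    return report
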