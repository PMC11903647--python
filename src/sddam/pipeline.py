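"""End-to-end orchestration, configuration and heatmap volumes.

``run_pipeline`` chains the stages — region assignment, multi-scale graph
metrics, morphology, and region-wise proportion tests — over a lesion
table and atlas, emitting:

* the lesion table augmented with regions, morphology and trajectory
  summaries plus high-level filter flags;
* a distribution report over all lesions and filtered-set reports for the
  high-clustering and high-importance subsets;
* sphere-overlay heatmap volumes (NIfTI) for all lesions and for the
  lesions whose mean trajectory value exceeds 0.5;
* a run log recording the seed, versions and the SE mode used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    LabelVolume,
    LesionPoint,
    assign_regions_to_lesions,
    lesions_to_frame,
    read_atlas,
    read_lesion_table,
    voxel_proportions,
)
from .graphs import ScaleGrid
from .metrics import (
    SummarySpec,
    TrajectoryRecord,
    filter_high_level,
    multiscale_trajectories,
    summarize,
    trajectories_to_frame,
)
from .morphology import MorphBins, bin_morphology, equivalent_radius
from .stats import region_report, report_to_frame
from .synthetic import rasterize_sphere

logger = logging.getLogger("sddam")

__all__ = ["RunConfig", "HeatmapVolume", "run_pipeline", "build_heatmap", "compute_cohort_trajectories"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run."""

    atlas_path: str
    lesion_table: str
    out_dir: str
    grid: ScaleGrid = field(default_factory=ScaleGrid)
    summary: SummarySpec = field(default_factory=SummarySpec)
    bins: MorphBins = field(default_factory=MorphBins)
    se_mode: str = "observed"
    alpha: float = 0.05
    heatmap_radius_mm: float = 5.0
    heatmap_mean_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a JSON superset
        for key, typ in (("grid", ScaleGrid), ("summary", SummarySpec), ("bins", MorphBins)):
            if key in raw and isinstance(raw[key], dict):
                if key == "bins":
                    raw[key] = MorphBins(
                        radius_edges=tuple(raw[key].get("radius_edges", MorphBins().radius_edges)),
                        volume_edges=tuple(raw[key].get("volume_edges", MorphBins().volume_edges)),
                    )
                else:
                    raw[key] = typ(**raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class HeatmapVolume:
    """Per-voxel count of covering fixed-radius spheres, atlas-aligned."""

    counts: np.ndarray
    spacing: tuple[float, float, float]
    sphere_radius_mm: float = 5.0


def build_heatmap(
    lesions: list[LesionPoint],
    atlas: LabelVolume,
    radius_mm: float = 5.0,
) -> HeatmapVolume:
    """Overlay one sphere per lesion on the atlas grid and count coverage."""
    counts = np.zeros(atlas.shape, dtype=np.int32)
    if not lesions:
        logger.warning("heatmap subset is empty; returning an all-zero volume")
    for les in lesions:
        counts += rasterize_sphere(les.centroid, radius_mm, atlas.shape, atlas.spacing)
    return HeatmapVolume(counts=counts, spacing=atlas.spacing, sphere_radius_mm=radius_mm)


def write_heatmap(hm: HeatmapVolume, path: str | Path) -> None:
    affine = np.diag(list(hm.spacing) + [1.0])
    nib.save(nib.Nifti1Image(hm.counts.astype(np.int32), affine), str(path))


def compute_cohort_trajectories(
    lesions: list[LesionPoint], grid: ScaleGrid
) -> list[TrajectoryRecord]:
    """Per-patient multi-scale trajectories for a pooled lesion list.

    Graphs are built within each patient only — spatial relations across
    different brains are meaningless.
    """
    by_patient: dict[str, list[LesionPoint]] = {}
    for l in lesions:
        by_patient.setdefault(l.patient_id, []).append(l)
    records: list[TrajectoryRecord] = []
    for pid, group in by_patient.items():
        pts = np.array([l.centroid for l in group])
        ids = [l.lesion_id for l in group]
        records.extend(multiscale_trajectories(pts, grid, node_ids=ids, patient_id=pid))
    return records


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage; returns a name -> path map of the written outputs.

    Any stage failure aborts with a stage-named error and removes partial
    outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "load inputs"
    try:
        atlas = read_atlas(config.atlas_path)
        lesions = read_lesion_table(config.lesion_table)
        if not lesions:
            raise ValueError("lesion table is empty")

        stage = "region assignment"
        assign_regions_to_lesions(lesions, atlas)
        expectations = voxel_proportions(atlas)

        stage = "morphology"
        for l in lesions:
            if l.radius is None and l.volume is not None:
                l.radius = equivalent_radius(l.volume)

        stage = "spatial metrics"
        records = compute_cohort_trajectories(lesions, config.grid)
        high_cc, high_ci = filter_high_level(records, config.summary)
        mean_spec = SummarySpec(mode="mean", ci_threshold=config.summary.ci_threshold,
                                cc_threshold=config.summary.cc_threshold)
        summaries = {r.lesion_id: (summarize(r, config.summary), summarize(r, mean_spec))
                     for r in records}

        stage = "write lesion table"
        table = lesions_to_frame(lesions)
        sel, mean_sel = zip(*(summaries[lid] for lid in table["lesion_id"]))
        table["ci_summary"] = [s[0] for s in sel]
        table["cc_summary"] = [s[1] for s in sel]
        table["ci_mean"] = [s[0] for s in mean_sel]
        table["cc_mean"] = [s[1] for s in mean_sel]
        high_cc_ids = {r.lesion_id for r in high_cc}
        high_ci_ids = {r.lesion_id for r in high_ci}
        table["high_clustering"] = table["lesion_id"].isin(high_cc_ids)
        table["high_importance"] = table["lesion_id"].isin(high_ci_ids)
        written["lesion_table"] = out_dir / "lesions_annotated.csv"
        table.to_csv(written["lesion_table"], index=False)

        written["trajectories"] = out_dir / "trajectories.csv"
        trajectories_to_frame(records).to_csv(written["trajectories"], index=False)

        stage = "distribution statistics"
        for name, subset in (
            ("distribution_all", None),
            ("distribution_high_clustering", high_cc_ids),
            ("distribution_high_importance", high_ci_ids),
        ):
            stats = region_report(lesions, expectations, subset_ids=subset,
                                  se_mode=config.se_mode, alpha=config.alpha)
            frame = report_to_frame(stats, atlas.region_names,
                                    lesions=None if subset is not None else lesions,
                                    se_mode=config.se_mode)
            written[name] = out_dir / f"{name}.csv"
            frame.to_csv(written[name], index=False)

        stage = "morphology bins"
        for feat in ("radius", "volume"):
            frame = bin_morphology(lesions, config.bins, feature=feat)
            written[f"bins_{feat}"] = out_dir / f"bins_{feat}.csv"
            frame.to_csv(written[f"bins_{feat}"], index=False)

        stage = "heatmaps"
        thr = config.heatmap_mean_threshold
        subsets = {
            "heatmap_all": lesions,
            "heatmap_mean_ci": [l for l in lesions
                                if summaries[l.lesion_id][1][0] > thr],
            "heatmap_mean_cc": [l for l in lesions
                                if summaries[l.lesion_id][1][1] > thr],
        }
        for name, subset in subsets.items():
            hm = build_heatmap(subset, atlas, config.heatmap_radius_mm)
            written[name] = out_dir / f"{name}.nii.gz"
            write_heatmap(hm, written[name])

        stage = "run log"
        written["run_log"] = out_dir / "run_log.json"
        with open(written["run_log"], "w") as fh:
            json.dump(
                {
                    "sddam_version": __version__,
                    "numpy_version": np.__version__,
                    "pandas_version": pd.__version__,
                    "seed": config.seed,
                    "se_mode": config.se_mode,
                    "scale_grid": dataclasses.asdict(config.grid),
                    "summary_mode": config.summary.mode,
                    "thresholds": {
                        "ci": config.summary.ci_threshold,
                        "cc": config.summary.cc_threshold,
                    },
                    "n_lesions": len(lesions),
                    "n_patients": len({l.patient_id for l in lesions}),
                },
                fh,
                indent=2,
            )
    except Exception as exc:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return written
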