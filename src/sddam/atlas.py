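"""Atlas geometry: lesion localisation and voxel-proportion expected rates.

A labelled atlas volume (integer labels, 0 = background) in a common
template space defines the regions of interest (ROIs).  Lesions are
represented as point centroids in template millimetre coordinates; each is
assigned the ROI whose voxel centre is nearest.  The per-ROI share of
non-background voxels is the "random distribution" expectation: the rate at
which lesions would land in each ROI if every brain voxel were equally at
risk.

Coordinate convention: voxel (i, j, k) has its centre at physical position
(i*sx, j*sy, k*sz); no affine rotation is modelled, inputs are assumed
already registered to the template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("sddam")

__all__ = [
    "LabelVolume",
    "LesionPoint",
    "RegionExpectation",
    "lesion_centroid",
    "assign_region",
    "voxel_proportions",
    "assign_regions_to_lesions",
    "read_atlas",
    "write_atlas",
    "read_lesion_table",
    "write_lesion_table",
    "lesions_to_frame",
]

LESION_COLUMNS = [
    "patient_id",
    "lesion_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "volume_mm3",
    "radius_mm",
    "region",
]


@dataclass(frozen=True)
class LabelVolume:
    """3-D integer atlas with voxel spacing (mm) and region names.

    ``labels`` holds 0 for background and 1..R for the R ROIs.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    region_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be a 3-D array")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        if labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three strictly positive mm values")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def region_labels(self) -> np.ndarray:
        """Sorted non-background labels present in the volume."""
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def name_of(self, label: int) -> str:
        return self.region_names.get(label, f"ROI_{label}")


@dataclass
class LesionPoint:
    """One metastasis: a point of the patient's lesion point cloud.

    Centroid is in template mm; ``region`` is the atlas label (None when the
    centroid rounds to background); volume in mm^3, radius in mm.
    """

    lesion_id: str
    patient_id: str
    centroid: np.ndarray
    region: int | None = None
    volume: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("centroid must be a finite 3-vector (mm)")
        self.centroid = c
        if self.volume is not None and self.volume <= 0:
            raise ValueError("volume must be positive when set")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive when set")


@dataclass(frozen=True)
class RegionExpectation:
    """Expected lesion proportion of one ROI under the voxel-uniform null."""

    region: int
    voxel_count: int
    p_e: float


def lesion_centroid(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Unweighted mean of foreground voxel-centre coordinates, in mm.

    Parameters
    ----------
    mask
        3-D binary segmentation of one lesion.
    spacing
        Voxel edge lengths in mm per axis.
    """
    mask = np.asarray(mask)
    idx = np.argwhere(mask != 0)
    if idx.size == 0:
        raise ValueError("no lesion voxels: mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    return idx.mean(axis=0) * spacing


def assign_region(point: Sequence[float], atlas: LabelVolume) -> int | None:
    """ROI label of the voxel whose centre is nearest to ``point``.

    Rounding is round-half-even per axis.  Background maps to ``None``.
    Raises ``ValueError`` when the point lies outside the atlas bounding
    box (half a voxel beyond the outermost voxel centres).
    """
    p = np.asarray(point, dtype=float)
    spacing = np.asarray(atlas.spacing)
    idx = np.round(p / spacing).astype(int)  # round-half-even (numpy default)
    shape = np.asarray(atlas.shape)
    # bounding box: voxel centres span [0, (n-1)*s]; allow half a voxel slack
    frac = p / spacing
    if np.any(frac < -0.5) or np.any(frac > shape - 0.5):
        raise ValueError(f"point {p.tolist()} outside atlas bounding box")
    idx = np.clip(idx, 0, shape - 1)
    label = int(atlas.labels[tuple(idx)])
    return label if label != 0 else None


def voxel_proportions(atlas: LabelVolume) -> list[RegionExpectation]:
    """Per-ROI voxel counts and expected proportions p_e.

    The denominator is the union of all non-background voxels, so the p_e
    sum to 1 over ROIs.
    """
    labels = atlas.labels
    counts = np.bincount(labels.ravel())
    total = counts[1:].sum()
    if total == 0:
        raise ValueError("atlas contains no non-background voxels")
    out = []
    for lab in range(1, len(counts)):
        if counts[lab] > 0:
            out.append(
                RegionExpectation(
                    region=lab,
                    voxel_count=int(counts[lab]),
                    p_e=counts[lab] / total,
                )
            )
    return out


def assign_regions_to_lesions(
    lesions: Sequence[LesionPoint], atlas: LabelVolume
) -> list[LesionPoint]:
    """Assign each lesion's ROI in place; warn about off-atlas centroids."""
    n_background = 0
    for les in lesions:
        les.region = assign_region(les.centroid, atlas)
        if les.region is None:
            n_background += 1
    if n_background:
        logger.warning(
            "%d lesion centroid(s) fell on background voxels and carry no region",
            n_background,
        )
    return list(lesions)


# ---------------------------------------------------------------------------
# NIfTI / CSV I/O


def read_atlas(path: str | Path, region_names: Mapping[int, str] | None = None) -> LabelVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels=labels, spacing=spacing, region_names=region_names or {})


def write_atlas(atlas: LabelVolume, path: str | Path) -> None:
    affine = np.diag(list(atlas.spacing) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(path))


def lesions_to_frame(lesions: Sequence[LesionPoint]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": l.patient_id,
            "lesion_id": l.lesion_id,
            "x_mm": l.centroid[0],
            "y_mm": l.centroid[1],
            "z_mm": l.centroid[2],
            "volume_mm3": l.volume,
            "radius_mm": l.radius,
            "region": l.region,
        }
        for l in lesions
    ]
    return pd.DataFrame(rows, columns=LESION_COLUMNS)


def write_lesion_table(lesions: Sequence[LesionPoint], path: str | Path) -> None:
    lesions_to_frame(lesions).to_csv(path, index=False)


def read_lesion_table(path: str | Path) -> list[LesionPoint]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        region = row.get("region")
        if pd.isna(region):
            region = None
        else:
            region = int(region)
        volume = row.get("volume_mm3")
        radius = row.get("radius_mm")
        out.append(
            LesionPoint(
                lesion_id=str(row["lesion_id"]),
                patient_id=str(row["patient_id"]),
                centroid=np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float),
                region=region,
                volume=None if pd.isna(volume) else float(volume),
                radius=None if pd.isna(radius) else float(radius),
            )
        )
    return out
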