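"""Synthetic atlases and lesion cohorts with controlled spatial structure.

The patient cohort behind the reference analysis is not publicly
deposited, so every pipeline stage is exercised on synthetic stand-ins
with known ground truth:

* a multi-region label volume — a Voronoi partition of random seed points
  inside an ellipsoidal "brain" mask;
* lesion centroids placed either voxel-uniformly (the complete-spatial-
  randomness counterpart of the voxel-proportion null, optionally with
  per-region intensity multipliers to create detectable enrichment) or by
  a Thomas cluster process (Poisson parents, Gaussian-displaced Poisson
  offspring) to create ground-truth clustered growth;
* log-normal lesion volumes, skewed like real metastasis cohorts.

Defaults emulate the reference cohort's scale: ~20 lesions per patient on
average and a mean volume near 650 mm^3 with a long right tail.  All
randomness flows from a single seed; fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .atlas import LabelVolume, LesionPoint, assign_region
from .morphology import equivalent_radius

__all__ = [
    "CohortSpec",
    "make_label_volume",
    "sample_lesions_uniform",
    "sample_lesions_clustered",
    "sample_cohort",
    "sample_volumes",
    "rasterize_sphere",
]

# log-normal volume parameters: exp(mu + sigma^2/2) ~ 650 mm^3 with the
# heavy right tail (max ~5e4 at cohort size) seen in metastasis cohorts
DEFAULT_LOG_VOLUME_MU = 5.35
DEFAULT_LOG_VOLUME_SIGMA = 1.5


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-patient lesion cohort."""

    n_patients: int = 30
    lesions_per_patient_mean: float = 20.0
    placement: Literal["uniform", "clustered"] = "uniform"
    # Thomas process (clustered placement)
    parents_per_patient_mean: float = 4.0
    offspring_mean: float = 5.0
    sigma_mm: float = 2.0
    # per-ROI enrichment factors for uniform placement
    multipliers: Mapping[int, float] = field(default_factory=dict)
    log_volume_mu: float = DEFAULT_LOG_VOLUME_MU
    log_volume_sigma: float = DEFAULT_LOG_VOLUME_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.lesions_per_patient_mean <= 0:
            raise ValueError("need >= 1 patient and positive lesion rate")
        if self.sigma_mm <= 0 or self.parents_per_patient_mean <= 0 or self.offspring_mean <= 0:
            raise ValueError("Thomas process parameters must be positive")
        if any(m < 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be >= 0")


def make_label_volume(
    n_regions: int,
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
) -> LabelVolume:
    """Voronoi partition of an ellipsoidal mask into contiguous regions.

    ``n_regions`` seed points are drawn inside an ellipsoid inscribed in
    the grid; every in-mask voxel takes the label of its nearest seed, so
    regions are contiguous, non-overlapping and non-empty.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    shape = tuple(int(s) for s in shape)
    if min(shape) < 16:
        raise ValueError("grid must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed)
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    centre = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) / 2.0 - 1.0
    inside = (((idx - centre) / semi) ** 2).sum(axis=1) <= 1.0
    mask_idx = idx[inside]
    if len(mask_idx) < n_regions:
        raise ValueError("mask too small to hold the requested regions")
    # rejection-free: pick distinct in-mask voxels as Voronoi seeds
    for _ in range(100):
        seeds = mask_idx[rng.choice(len(mask_idx), size=n_regions, replace=False)]
        nearest = cKDTree(seeds).query(mask_idx)[1]
        if len(np.unique(nearest)) == n_regions:  # every region non-empty
            break
    else:  # pragma: no cover - seeds are distinct voxels, so this is unreachable
        raise RuntimeError("could not build a partition with all regions non-empty")
    labels = np.zeros(shape, dtype=np.int32)
    flat = mask_idx.astype(int)
    labels[flat[:, 0], flat[:, 1], flat[:, 2]] = nearest + 1
    names = {lab: f"Region_{lab}" for lab in range(1, n_regions + 1)}
    return LabelVolume(labels=labels, spacing=spacing, region_names=names)


def _mask_voxels(atlas: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
    """(voxel index array, voxel label array) for non-background voxels."""
    vox = np.argwhere(atlas.labels > 0)
    labs = atlas.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
    return vox, labs


def sample_lesions_uniform(
    atlas: LabelVolume,
    n: int,
    multipliers: Mapping[int, float] | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Centroids drawn voxel-uniformly over the brain mask (mm).

    Per-region ``multipliers`` reweight the sampling intensity (a factor of
    2 doubles a voxel's chance relative to unit-weight voxels); points are
    jittered uniformly within the voxel.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    vox, labs = _mask_voxels(atlas)
    w = np.ones(len(vox))
    for region, m in (multipliers or {}).items():
        w[labs == region] = m
    total = w.sum()
    if total <= 0:
        raise ValueError("all sampling weights are zero")
    pick = rng.choice(len(vox), size=n, p=w / total)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
    return (vox[pick] + jitter) * np.asarray(atlas.spacing)


def sample_lesions_clustered(
    atlas: LabelVolume,
    n_parents_mean: float,
    offspring_mean: float,
    sigma_mm: float,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Thomas cluster process over the brain mask (mm).

    Poisson(n_parents_mean) parents uniform over the mask; each parent
    spawns Poisson(offspring_mean) offspring displaced by an isotropic
    Gaussian of standard deviation ``sigma_mm`` and clipped back to the
    mask (off-mask offspring snap to the nearest in-mask voxel centre).
    Guaranteed non-empty: at least one parent and one offspring are drawn.
    """
    if min(n_parents_mean, offspring_mean, sigma_mm) <= 0:
        raise ValueError("Thomas process parameters must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    vox, _ = _mask_voxels(atlas)
    spacing = np.asarray(atlas.spacing)
    n_parents = max(1, rng.poisson(n_parents_mean))
    parents = (vox[rng.choice(len(vox), size=n_parents)] + rng.uniform(-0.5, 0.5, (n_parents, 3))) * spacing
    points = []
    for par in parents:
        k = rng.poisson(offspring_mean)
        if k == 0:
            continue
        points.append(par + rng.normal(0.0, sigma_mm, size=(k, 3)))
    if not points:  # degenerate draw: keep the first parent itself
        points.append(parents[:1])
    pts = np.concatenate(points, axis=0)
    # clip to mask: snap any off-mask point to its nearest in-mask voxel centre
    tree = cKDTree(vox * spacing)
    for i, p in enumerate(pts):
        idx = np.round(p / spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(atlas.shape)))
        if not inside or atlas.labels[tuple(np.clip(idx, 0, np.asarray(atlas.shape) - 1))] == 0:
            pts[i] = vox[tree.query(p)[1]] * spacing
    return pts


def sample_volumes(n: int, mu: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal lesion volumes in mm^3."""
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def sample_cohort(atlas: LabelVolume, spec: CohortSpec) -> list[LesionPoint]:
    """A full multi-patient cohort of region-assigned lesions with volumes."""
    rng = np.random.default_rng(spec.seed)
    lesions: list[LesionPoint] = []
    for p in range(spec.n_patients):
        pid = f"P{p:04d}"
        if spec.placement == "uniform":
            n = max(1, rng.poisson(spec.lesions_per_patient_mean))
            pts = sample_lesions_uniform(atlas, n, spec.multipliers, rng=rng)
        else:
            pts = sample_lesions_clustered(
                atlas,
                spec.parents_per_patient_mean,
                spec.offspring_mean,
                spec.sigma_mm,
                rng=rng,
            )
        vols = sample_volumes(len(pts), spec.log_volume_mu, spec.log_volume_sigma, rng)
        for j, (xyz, vol) in enumerate(zip(pts, vols)):
            lesions.append(
                LesionPoint(
                    lesion_id=f"{pid}_L{j:03d}",
                    patient_id=pid,
                    centroid=xyz,
                    region=assign_region(xyz, atlas),
                    volume=float(vol),
                    radius=equivalent_radius(float(vol)),
                )
            )
    return lesions


def rasterize_sphere(
    center: Sequence[float],
    radius: float,
    shape: tuple[int, int, int],
    spacing: Sequence[float],
) -> np.ndarray:
    """Binary mask of voxels whose centres lie within ``radius`` of ``center``.

    ``center`` is in mm on the same grid convention as the atlas (voxel
    (i,j,k) centred at (i,j,k)*spacing).  Raises if the sphere misses the
    grid entirely.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(int(s) for s in shape)
    lo = np.maximum(np.floor((center - radius) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + radius) / spacing).astype(int) + 1, np.asarray(shape))
    if np.any(lo >= hi):
        raise ValueError("sphere lies entirely outside the grid")
    mask = np.zeros(shape, dtype=np.uint8)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    coords = np.stack(grids, axis=-1) * spacing
    inside = ((coords - center) ** 2).sum(axis=-1) <= radius**2
    mask[grids[0], grids[1], grids[2]] = inside.astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("sphere lies entirely outside the grid")
    return mask
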