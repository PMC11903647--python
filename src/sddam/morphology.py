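"""Lesion morphology: volume, equivalent-sphere radius, and bin systems.

Volume is the foreground voxel count times the voxel volume (mm^3).  The
radius is the equivalent-sphere radius r = (3V / 4 pi)^(1/3): the radius of
the sphere with the lesion's volume.  Radii and volumes are grouped into
half-open bins for the demographic analysis; because most lesions have
radii under 10 mm or volumes under 200 mm^3, those low ranges are
subdivided more finely by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sddam")

__all__ = ["MorphBins", "lesion_volume", "equivalent_radius", "sphere_volume", "bin_morphology"]

DEFAULT_RADIUS_EDGES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, math.inf)
DEFAULT_VOLUME_EDGES = (0.0, 50.0, 100.0, 200.0, 700.0, 15000.0, math.inf)


@dataclass(frozen=True)
class MorphBins:
    """Half-open [lo, hi) bin edges for radius (mm) and volume (mm^3)."""

    radius_edges: tuple[float, ...] = DEFAULT_RADIUS_EDGES
    volume_edges: tuple[float, ...] = DEFAULT_VOLUME_EDGES

    def __post_init__(self) -> None:
        for edges in (self.radius_edges, self.volume_edges):
            if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError("bin edges must be strictly increasing")

    @staticmethod
    def labels(edges: Sequence[float]) -> list[str]:
        return [
            f"[{lo:g}, {hi:g})" if math.isfinite(hi) else f">= {lo:g}"
            for lo, hi in zip(edges, edges[1:])
        ]


def lesion_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Foreground voxel count times voxel volume, in mm^3."""
    mask = np.asarray(mask)
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("no lesion voxels: mask is empty")
    return n * float(np.prod(np.asarray(spacing, dtype=float)))


def equivalent_radius(volume: float) -> float:
    """Radius of the sphere with the given volume: (3V / 4 pi)^(1/3)."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def sphere_volume(radius: float) -> float:
    """Inverse of :func:`equivalent_radius`."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 4.0 / 3.0 * math.pi * radius**3


def bin_morphology(
    lesions,
    bins: MorphBins | None = None,
    feature: str = "radius",
) -> pd.DataFrame:
    """Region-by-bin contingency of lesions on radius or volume.

    Returns a tidy frame with counts and, per bin, the proportion each
    region holds of that bin's total.  Lesions missing the binned feature
    or a region are excluded (with a logged count).
    """
    bins = bins or MorphBins()
    if feature == "radius":
        edges = np.asarray(bins.radius_edges)
        values = [l.radius for l in lesions]
    elif feature == "volume":
        edges = np.asarray(bins.volume_edges)
        values = [l.volume for l in lesions]
    else:
        raise ValueError("feature must be 'radius' or 'volume'")

    kept_regions, kept_values = [], []
    n_skipped = 0
    for les, v in zip(lesions, values):
        if v is None or les.region is None:
            n_skipped += 1
            continue
        kept_regions.append(les.region)
        kept_values.append(v)
    if n_skipped:
        logger.warning("%d lesion(s) missing %s or region excluded from binning", n_skipped, feature)

    labels = MorphBins.labels(edges)
    idx = np.digitize(kept_values, edges) - 1  # [lo, hi) half-open
    rows = []
    regions = sorted(set(kept_regions))
    counts = {}
    for r, b in zip(kept_regions, idx):
        counts[(r, b)] = counts.get((r, b), 0) + 1
    bin_totals = {b: sum(c for (r2, b2), c in counts.items() if b2 == b) for b in range(len(labels))}
    for r in regions:
        for b, lab in enumerate(labels):
            c = counts.get((r, b), 0)
            total = bin_totals[b]
            rows.append(
                {
                    "region": r,
                    "bin": lab,
                    "count": c,
                    "proportion_of_bin": c / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["region", "bin", "count", "proportion_of_bin"])
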