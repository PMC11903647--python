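"""Region-wise proportion tests against the voxel-uniform null.

Each ROI's observed lesion rate p-hat = count / n is compared with its
expected rate p_e (the ROI's share of brain voxels) by a two-tailed normal
z-test:

    z = (p_hat - p_e) / SE,    p = 2 (1 - Phi(|z|))

Two standard-error conventions are kept.  ``se_mode="observed"`` evaluates
SE = sqrt(p_hat (1 - p_hat) / n) at the observed proportion — the default,
which reproduces the reference distribution tables — and sends z to +/-inf
(p = 0) when p_hat is exactly 0 or 1.  ``se_mode="expected"`` uses
SE = sqrt(p_e (1 - p_e) / n), the textbook one-sample form.  The two can
differ materially when p_hat is far from p_e, so reports always name the
mode used.  Multiplicity across ROIs is handled by Bonferroni.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from .atlas import LesionPoint, RegionExpectation

__all__ = ["RegionStats", "proportion_ztest", "bonferroni_alpha", "region_report", "report_to_frame"]

SeMode = Literal["observed", "expected"]


@dataclass(frozen=True)
class RegionStats:
    """Observed vs expected lesion rate of one ROI, with test results."""

    region: int
    observed_count: int
    n_total: int
    p_hat: float
    p_e: float
    z: float
    p_value: float
    significant: bool


def proportion_ztest(
    observed_count: int,
    n_total: int,
    p_e: float,
    se_mode: SeMode = "observed",
) -> tuple[float, float]:
    """Two-tailed one-sample proportion z-test.

    Returns ``(z, p)``.  In observed mode a degenerate p_hat of exactly 0
    or 1 yields z = -inf / +inf with p = 0.
    """
    if not 0 < p_e < 1:
        raise ValueError("p_e must lie strictly between 0 and 1")
    if not 0 <= observed_count <= n_total or n_total < 1:
        raise ValueError("require 0 <= observed_count <= n_total, n_total >= 1")
    p_hat = observed_count / n_total
    if se_mode == "observed":
        if p_hat == 0.0:
            return -math.inf, 0.0
        if p_hat == 1.0:
            return math.inf, 0.0
        se = math.sqrt(p_hat * (1.0 - p_hat) / n_total)
    elif se_mode == "expected":
        se = math.sqrt(p_e * (1.0 - p_e) / n_total)
    else:
        raise ValueError("se_mode must be 'observed' or 'expected'")
    z = (p_hat - p_e) / se
    p = 2.0 * norm.sf(abs(z))
    return z, p


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise adjusted significance level alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def region_report(
    lesions: Sequence[LesionPoint],
    expectations: Sequence[RegionExpectation],
    subset_ids: set[str] | None = None,
    se_mode: SeMode = "observed",
    alpha: float = 0.05,
) -> list[RegionStats]:
    """One RegionStats per ROI over the (optionally filtered) lesion set.

    ``subset_ids`` restricts to a lesion subset, e.g. the high-clustering
    lesions; ``n_total`` is then the subset size, so rates are shares of
    the filtered set, not of the whole cohort.  Regions with zero lesions
    in the set are still reported.  Lesions without a region are ignored.
    """
    exp_by_region: Mapping[int, RegionExpectation] = {e.region: e for e in expectations}
    counted = [
        l
        for l in lesions
        if l.region is not None and (subset_ids is None or l.lesion_id in subset_ids)
    ]
    for l in counted:
        if l.region not in exp_by_region:
            raise ValueError(f"lesion {l.lesion_id}: region {l.region} has no expectation")
    n_total = len(counted)
    counts: dict[int, int] = {e.region: 0 for e in expectations}
    for l in counted:
        counts[l.region] += 1

    level = bonferroni_alpha(alpha, len(expectations))
    out = []
    for e in sorted(expectations, key=lambda e: e.region):
        c = counts[e.region]
        if n_total == 0:
            z, p = math.nan, math.nan
            p_hat = math.nan
        else:
            z, p = proportion_ztest(c, n_total, e.p_e, se_mode=se_mode)
            p_hat = c / n_total
        out.append(
            RegionStats(
                region=e.region,
                observed_count=c,
                n_total=n_total,
                p_hat=p_hat,
                p_e=e.p_e,
                z=z,
                p_value=p,
                significant=bool(p <= level) if not math.isnan(z) else False,
            )
        )
    return out


def report_to_frame(
    stats: Sequence[RegionStats],
    region_names: Mapping[int, str] | None = None,
    lesions: Sequence[LesionPoint] | None = None,
    se_mode: str = "observed",
) -> pd.DataFrame:
    """Distribution-table layout: counts, rates, morphology ranges, z, p.

    With ``lesions`` given, per-region radius/volume min/mean/max columns
    are included.
    """
    names = region_names or {}
    rows = []
    morph: dict[int, dict[str, list[float]]] = {}
    if lesions is not None:
        for l in lesions:
            if l.region is None:
                continue
            d = morph.setdefault(l.region, {"radius": [], "volume": []})
            if l.radius is not None:
                d["radius"].append(l.radius)
            if l.volume is not None:
                d["volume"].append(l.volume)
    for s in stats:
        row = {
            "region": s.region,
            "region_name": names.get(s.region, f"ROI_{s.region}"),
            "observed_count": s.observed_count,
            "n_total": s.n_total,
            "observed_rate_pct": 100.0 * s.p_hat,
            "expected_rate_pct": 100.0 * s.p_e,
            "z": s.z,
            "p_value": s.p_value,
            "significant": s.significant,
            "se_mode": se_mode,
        }
        if lesions is not None:
            d = morph.get(s.region, {"radius": [], "volume": []})
            for feat in ("radius", "volume"):
                vals = d[feat]
                row[f"{feat}_min"] = min(vals) if vals else math.nan
                row[f"{feat}_mean"] = sum(vals) / len(vals) if vals else math.nan
                row[f"{feat}_max"] = max(vals) if vals else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
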