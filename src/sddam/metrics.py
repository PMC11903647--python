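"""Per-lesion spatial-relation metrics across the scale grid.

At each filtration scale a lesion (node) receives:

* degree centrality ``dc`` — degree normalised by (n - 1), in [0, 1];
* eigenvector centrality ``ec`` — entry of the principal eigenvector of the
  adjacency matrix, computed by power iteration and scaled to unit
  Euclidean norm over all nodes, in [0, 1];
* centrality importance ``ci = (dc + ec) / 2``;
* clustering coefficient ``cc = 2 T / (deg (deg - 1))`` with T the number
  of triangles through the node; nodes of degree < 2 score 0.

The per-lesion trajectory is the ordered sequence of (ci, cc) pairs over
the grid.  Trajectories are summarised by the mean or the maximum over
scales; the high-level filter selects lesions whose summary strictly
exceeds the configured threshold (defaults: cc > 0.9, ci > 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .graphs import Filtration, ScaleGraph, ScaleGrid, build_filtration

__all__ = [
    "NodeMetrics",
    "TrajectoryRecord",
    "SummarySpec",
    "degree_centrality",
    "eigenvector_centrality",
    "centrality_importance",
    "clustering_coefficient",
    "raw_degree",
    "multiscale_trajectories",
    "summarize",
    "filter_high_level",
    "bin_ten_ranges",
    "trajectories_to_frame",
]


@dataclass(frozen=True)
class NodeMetrics:
    """All four per-node scores of one scale graph, aligned to its node ids."""

    scale: float
    node_ids: tuple[str, ...]
    dc: np.ndarray
    ec: np.ndarray
    ci: np.ndarray
    cc: np.ndarray


@dataclass(frozen=True)
class TrajectoryRecord:
    """One lesion's (scale, ci, cc) sequence over the whole grid."""

    lesion_id: str
    patient_id: str
    scales: np.ndarray
    ci: np.ndarray
    cc: np.ndarray


@dataclass(frozen=True)
class SummarySpec:
    """How trajectories collapse to one number and which thresholds filter.

    ``mode``: "max" takes the best value a lesion ever attains across
    scales; "mean" averages over scales.  Filtering is a strict exceedance
    of the threshold.
    """

    mode: Literal["mean", "max"] = "max"
    ci_threshold: float = 0.8
    cc_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "max"):
            raise ValueError("mode must be 'mean' or 'max'")
        for t in (self.ci_threshold, self.cc_threshold):
            if not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")


def raw_degree(g: ScaleGraph) -> np.ndarray:
    """Unnormalised node degree (diagnostic)."""
    return g.adjacency.sum(axis=1).astype(float)


def degree_centrality(g: ScaleGraph) -> np.ndarray:
    """Degree / (n - 1); a single-node graph scores 0."""
    n = g.n_nodes
    if n < 2:
        return np.zeros(n)
    return raw_degree(g) / (n - 1)


def eigenvector_centrality(
    g: ScaleGraph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    context: str = "",
) -> np.ndarray:
    """Principal eigenvector of the adjacency by power iteration.

    Non-negative, unit Euclidean norm over all nodes.  An edgeless graph
    (including a single node) scores all zeros: the leading eigenvalue is 0
    and the recursive definition has no informative solution.  On a
    disconnected graph the vector concentrates on the component with the
    largest leading eigenvalue, the common library convention.
    """
    a = g.adjacency.astype(float)
    n = g.n_nodes
    if n == 0 or a.sum() == 0:
        return np.zeros(n)
    # iterate with A + I: same eigenvectors, spectrum shifted positive, which
    # kills the sign oscillation of bipartite components
    a = a + np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = a @ v
        norm = np.linalg.norm(w)
        if norm == 0:  # cannot happen for a nonzero symmetric a with v > 0
            return np.zeros(n)
        w /= norm
        if np.linalg.norm(w - v) < tol:
            return w
        v = w
    where = f" ({context})" if context else ""
    raise RuntimeError(
        f"eigenvector centrality did not converge at scale {g.scale}{where}"
    )


def centrality_importance(dc: np.ndarray, ec: np.ndarray) -> np.ndarray:
    """Elementwise average of degree and eigenvector centrality."""
    dc = np.asarray(dc, dtype=float)
    ec = np.asarray(ec, dtype=float)
    if dc.shape != ec.shape:
        raise ValueError("dc and ec must be aligned over the same node set")
    return (dc + ec) / 2.0


def clustering_coefficient(g: ScaleGraph) -> np.ndarray:
    """2T / (deg (deg - 1)) per node; deg < 2 scores 0."""
    a = g.adjacency.astype(float)
    deg = a.sum(axis=1)
    # triangles through node u = (A^3)_uu / 2
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    cc = np.zeros_like(deg)
    ok = denom > 0
    cc[ok] = 2.0 * tri[ok] / denom[ok]
    return cc


def node_metrics(g: ScaleGraph, context: str = "") -> NodeMetrics:
    dc = degree_centrality(g)
    ec = eigenvector_centrality(g, context=context)
    return NodeMetrics(
        scale=g.scale,
        node_ids=g.node_ids,
        dc=dc,
        ec=ec,
        ci=centrality_importance(dc, ec),
        cc=clustering_coefficient(g),
    )


def multiscale_trajectories(
    points: Sequence[Sequence[float]],
    grid: ScaleGrid | None = None,
    node_ids: Sequence[str] | None = None,
    patient_id: str = "",
) -> list[TrajectoryRecord]:
    """(ci, cc) at every grid scale for each lesion of one patient."""
    grid = grid or ScaleGrid()
    filt = build_filtration(points, grid, node_ids=node_ids)
    per_scale = [node_metrics(g, context=f"patient {patient_id}") for g in filt]
    scales = np.array([m.scale for m in per_scale])
    ids = per_scale[0].node_ids
    ci = np.stack([m.ci for m in per_scale], axis=1)  # (node, scale)
    cc = np.stack([m.cc for m in per_scale], axis=1)
    return [
        TrajectoryRecord(
            lesion_id=ids[u],
            patient_id=patient_id,
            scales=scales,
            ci=ci[u],
            cc=cc[u],
        )
        for u in range(len(ids))
    ]


def summarize(record: TrajectoryRecord, spec: SummarySpec) -> tuple[float, float]:
    """Collapse a trajectory to (ci_summary, cc_summary) per the spec mode."""
    if record.ci.size == 0:
        raise ValueError("empty trajectory")
    op = np.mean if spec.mode == "mean" else np.max
    return float(op(record.ci)), float(op(record.cc))


def filter_high_level(
    records: Sequence[TrajectoryRecord], spec: SummarySpec | None = None
) -> tuple[list[TrajectoryRecord], list[TrajectoryRecord]]:
    """Split out the high-clustering and high-importance lesion subsets.

    A lesion enters a subset when its summarised value strictly exceeds the
    threshold.  Returns ``(high_cc, high_ci)``.
    """
    if not records:
        raise ValueError("no trajectory records to filter")
    spec = spec or SummarySpec()
    high_cc, high_ci = [], []
    for rec in records:
        ci_s, cc_s = summarize(rec, spec)
        if cc_s > spec.cc_threshold:
            high_cc.append(rec)
        if ci_s > spec.ci_threshold:
            high_ci.append(rec)
    return high_cc, high_ci


def bin_ten_ranges(values: Sequence[float]) -> np.ndarray:
    """Histogram over [0, 1] in ten equal ranges.

    Bins are [0, 0.1), ..., [0.9, 1.0]; the last bin is right-closed so the
    value 1.0 is counted.
    """
    v = np.asarray(values, dtype=float)
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("values must lie in [0, 1]")
    counts, _ = np.histogram(v, bins=np.linspace(0.0, 1.0, 11))
    return counts


def trajectories_to_frame(records: Sequence[TrajectoryRecord]) -> pd.DataFrame:
    """Long-format table: patient_id, lesion_id, scale, ci, cc."""
    rows = []
    for rec in records:
        for s, ci, cc in zip(rec.scales, rec.ci, rec.cc):
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "lesion_id": rec.lesion_id,
                    "scale": s,
                    "ci": ci,
                    "cc": cc,
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "lesion_id", "scale", "ci", "cc"])
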