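"""Multi-scale Rips graphs over lesion centroids.

The lesion point cloud of one patient is turned into a nested family of
undirected graphs (the 1-skeleton of a Vietoris-Rips filtration): at scale
``s`` two lesions are joined by an edge when their Euclidean distance is
strictly below ``s``.  The default scale grid runs from 10 mm to 90 mm in
5 mm steps.  Only the graph skeleton is used; no higher simplices or
persistence diagrams are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["ScaleGrid", "ScaleGraph", "Filtration", "build_scale_graph", "build_filtration"]


@dataclass(frozen=True)
class ScaleGrid:
    """Arithmetic grid of filtration scales in mm: start, start+step, ... <= stop."""

    start: float = 10.0
    step: float = 5.0
    stop: float = 90.0

    def __post_init__(self) -> None:
        if self.start <= 0 or self.step <= 0 or self.stop < self.start:
            raise ValueError("require start > 0, step > 0, stop >= start")

    @property
    def scales(self) -> np.ndarray:
        n = int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1
        return self.start + self.step * np.arange(n)

    def __iter__(self) -> Iterator[float]:
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)

    @classmethod
    def parse(cls, text: str) -> "ScaleGrid":
        """Parse 'start:stop:step' (e.g. '10:90:5')."""
        start, stop, step = (float(x) for x in text.split(":"))
        return cls(start=start, step=step, stop=stop)


@dataclass(frozen=True)
class ScaleGraph:
    """Undirected simple graph over one patient's lesions at one scale."""

    scale: float
    node_ids: tuple[str, ...]
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.node_ids)
        if a.shape != (n, n):
            raise ValueError("adjacency shape must match node count")
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def edges(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        sel = self.adjacency[iu, ju] > 0
        return [(self.node_ids[i], self.node_ids[j]) for i, j in zip(iu[sel], ju[sel])]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class Filtration:
    """Ordered family of scale graphs with nested edge sets."""

    graphs: tuple[ScaleGraph, ...] = field(default=())

    def __iter__(self) -> Iterator[ScaleGraph]:
        return iter(self.graphs)

    def __len__(self) -> int:
        return len(self.graphs)

    @property
    def scales(self) -> list[float]:
        return [g.scale for g in self.graphs]


def _check_points(points: Sequence[Sequence[float]]) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.shape[0] < 1 or pts.shape[1] != 3:
        raise ValueError("need at least one 3-D point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in point cloud")
    return pts


def build_scale_graph(
    points: Sequence[Sequence[float]],
    scale: float,
    node_ids: Sequence[str] | None = None,
) -> ScaleGraph:
    """Connect every pair of points with Euclidean distance strictly < scale."""
    pts = _check_points(points)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if node_ids is None:
        node_ids = [str(i) for i in range(len(pts))]
    if len(pts) == 1:
        adj = np.zeros((1, 1), dtype=np.int8)
    else:
        dist = squareform(pdist(pts))
        adj = (dist < scale).astype(np.int8)
        np.fill_diagonal(adj, 0)
    return ScaleGraph(scale=float(scale), node_ids=tuple(node_ids), adjacency=adj)


def build_filtration(
    points: Sequence[Sequence[float]],
    grid: ScaleGrid | None = None,
    node_ids: Sequence[str] | None = None,
) -> Filtration:
    """One scale graph per grid value, ascending; edge sets are nested."""
    grid = grid or ScaleGrid()
    pts = _check_points(points)
    if node_ids is None:
        node_ids = [str(i) for i in range(len(pts))]
    # compute the distance matrix once; thresholding at each scale preserves
    # nestedness by construction
    if len(pts) == 1:
        dist = np.zeros((1, 1))
    else:
        dist = squareform(pdist(pts))
    graphs = []
    for s in grid:
        adj = (dist < s).astype(np.int8)
        np.fill_diagonal(adj, 0)
        graphs.append(ScaleGraph(scale=float(s), node_ids=tuple(node_ids), adjacency=adj))
    return Filtration(graphs=tuple(graphs))


def write_edge_lists(filtration: Filtration, path) -> None:
    """Serialise a filtration as text lines ``scale<TAB>u<TAB>v``."""
    with open(path, "w") as fh:
        fh.write("scale\tu\tv\n")
        for g in filtration:
            for u, v in g.edges:
                fh.write(f"{g.scale:g}\t{u}\t{v}\n")
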