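"""Typed intercellular graphs and spatial statistics of the tumor
microenvironment.

Graphs connect pairs of cell types (tumor-tumor, tumor-stroma,
tumor-inflammatory) through a Delaunay triangulation of the involved
centroids, pruned to edges whose endpoints match the pair class and whose
length does not exceed a cap (default 50 um).  The per-cell MeanEdgeLength
is the average length (in microns) of a tumor cell's incident edges; tumor
cell density (TcD) is neoplastic cells per square millimeter.  Group
differences are assessed with the two-sided Mann-Whitney U rank test (exact
enumeration for tiny samples, normal approximation with tie and continuity
correction otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial import Delaunay, QhullError

from .data import CellMap

__all__ = [
    "PAIR_CLASSES",
    "CellGraph",
    "build_typed_graph",
    "mean_edge_length",
    "tumor_cell_density",
    "compare_groups",
]

# pair class -> (focus type, partner type); field names map to HoverNet
# classes: tumor = neoplastic, stroma = connective.
PAIR_CLASSES = {
    "tumor-tumor": ("neoplastic", "neoplastic"),
    "tumor-stroma": ("neoplastic", "connective"),
    "tumor-inflammatory": ("neoplastic", "inflammatory"),
}


@dataclass
class CellGraph:
    pair_class: str
    indices: np.ndarray  # indices into the source CellMap
    types: np.ndarray  # cell type per node
    coords: np.ndarray  # node centroids, px
    edges: list  # (i, j, length_px, length_um) with i < j, node indices
    microns_per_px: float
    degenerate: bool = False  # fallback construction was used

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _delaunay_edges(points: np.ndarray) -> tuple[set[tuple[int, int]], bool]:
    """Unique undirected edges of the Delaunay triangulation.

    Fewer than 3 points, or degenerate (e.g. collinear) inputs, fall back
    to a nearest-neighbor chain along lexicographic order; the second
    return value flags that fallback.
    """
    m = len(points)
    if m < 2:
        return set(), True
    try:
        if m < 3:
            raise QhullError("too few points")
        tri = Delaunay(points)
        edges: set[tuple[int, int]] = set()
        for simplex in tri.simplices:
            for a, b in combinations(sorted(int(v) for v in simplex), 2):
                edges.add((a, b))
        return edges, False
    except QhullError:
        order = np.lexsort((points[:, 1], points[:, 0]))
        chain = {tuple(sorted((int(a), int(b))))
                 for a, b in zip(order[:-1], order[1:])}
        return chain, True


def build_typed_graph(
    cellmap: CellMap, pair_class: str, max_edge_um: float = 50.0
) -> CellGraph:
    """Delaunay graph over the two involved cell types, pruned by type pair
    and edge-length cap."""
    if pair_class not in PAIR_CLASSES:
        raise ValueError(
            f"unknown pair class {pair_class!r}; choose from {sorted(PAIR_CLASSES)}"
        )
    if max_edge_um <= 0:
        raise ValueError("max_edge_um must be positive")
    type_a, type_b = PAIR_CLASSES[pair_class]
    wanted = {type_a, type_b}
    sel = np.flatnonzero(np.isin(cellmap.cell_types, list(wanted)))
    pts = cellmap.centroids[sel]
    types = cellmap.cell_types[sel]
    mpp = cellmap.microns_per_px

    raw_edges, degenerate = _delaunay_edges(pts)
    edges = []
    for a, b in sorted(raw_edges):
        ta, tb = types[a], types[b]
        if type_a != type_b and {ta, tb} != wanted:
            continue  # mixed pair class keeps only cross-type edges
        length_px = float(np.linalg.norm(pts[a] - pts[b]))
        length_um = length_px * mpp
        if length_px <= 0 or length_um > max_edge_um:
            continue
        edges.append((a, b, length_px, length_um))
    return CellGraph(
        pair_class=pair_class,
        indices=sel,
        types=types,
        coords=pts,
        edges=edges,
        microns_per_px=mpp,
        degenerate=degenerate,
    )


def mean_edge_length(
    graph: CellGraph, cell_type_focus: str = "neoplastic"
) -> tuple[np.ndarray, int]:
    """Per-cell mean incident edge length (um) for focus-type cells.

    Degree-0 focus cells are excluded (their count is returned alongside)
    rather than scored 0, which would distort the distribution's tail.
    """
    if cell_type_focus not in set(PAIR_CLASSES[graph.pair_class]):
        raise ValueError(
            f"focus type {cell_type_focus!r} not part of pair class "
            f"{graph.pair_class!r}"
        )
    incident: dict[int, list[float]] = {}
    for a, b, _, length_um in graph.edges:
        incident.setdefault(a, []).append(length_um)
        incident.setdefault(b, []).append(length_um)
    focus_nodes = np.flatnonzero(graph.types == cell_type_focus)
    values = [float(np.mean(incident[i])) for i in focus_nodes if i in incident]
    n_excluded = int(sum(1 for i in focus_nodes if i not in incident))
    return np.asarray(values), n_excluded


def tumor_cell_density(cellmap: CellMap, area_mm2: float | None = None) -> float:
    """Neoplastic cells per square millimeter (TcD)."""
    if area_mm2 is None:
        area_mm2 = cellmap.area_mm2
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    return float((cellmap.cell_types == "neoplastic").sum()) / area_mm2


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two samples.

    Exact enumeration when min(n_a, n_b) <= 8 and n_a + n_b <= 12 with no
    ties; the normal approximation with tie and continuity correction
    otherwise.  Returns (U statistic of the first sample, p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    small = min(len(a), len(b)) <= 8 and len(a) + len(b) <= 12
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if small and not has_ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
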