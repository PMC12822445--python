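"""Tile-phenotype discovery from high-attention tile embeddings.

Per slide, the ``k`` tiles with the highest attention scores are collected;
each is re-embedded as a singleton bag (the post-transformer cls state) and
scored for tile-level risk.  The pooled embeddings are clustered by Leiden
community detection on a cosine kNN graph.  A cluster is retained in a risk
group when that group contributes strictly more than 25% of the cluster's
tiles; retained in exactly one group it is high- or low-specific, in both it
is colocalized (the strict majority guarantees every cluster gets exactly
one of the three labels).  Subcluster cellular compositions (mean cells per
tile by type) are min-max scaled per type and organized by Ward hierarchical
clustering on Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.neighbors import NearestNeighbors

from .data import CELL_TYPES, CellMap, TileBag
from .heatmap import tile_attention_scores, top_k_tiles
from .model import ModelConfig, embed_tile, forward_bag
from .training import assign_risk_group

__all__ = [
    "TileEmbeddingTable",
    "SubclusterReport",
    "collect_top_tiles",
    "cluster_embeddings",
    "classify_subclusters",
    "composition_dendrogram",
]


@dataclass
class TileEmbeddingTable:
    """Embeddings of collected high-attention tiles with aligned metadata."""

    embeddings: np.ndarray  # T x embed_dim
    meta: pd.DataFrame  # slide_id, col, row, risk_group, slide_score, tile_score

    def __post_init__(self) -> None:
        if len(self.embeddings) != len(self.meta):
            raise ValueError("embeddings and metadata row counts differ")


@dataclass
class SubclusterReport:
    """Per-cluster counts, specificity labels and optional compositions."""

    clusters: dict[int, dict] = field(default_factory=dict)

    def specificity(self, cluster_id: int) -> str:
        return self.clusters[cluster_id]["specificity"]


def collect_top_tiles(
    bags: Sequence[TileBag],
    params,
    config: ModelConfig,
    k: int = 100,
) -> TileEmbeddingTable:
    """Embed the top-k attention tiles of every slide into one table."""
    rows = []
    embeddings = []
    for bag in bags:
        if bag.label_normalized is None:
            raise ValueError(f"bag {bag.slide_id} has no label")
        pred = forward_bag(bag, params, config)
        scores = tile_attention_scores(bag, params, config, prediction=pred)
        group = assign_risk_group(bag.label_normalized, "normalized")
        coord_index = {(int(c), int(r)): i for i, (c, r) in enumerate(bag.coords)}
        for (col, row), score in top_k_tiles(scores, bag.coords, k):
            i = coord_index[(col, row)]
            emb = embed_tile(bag.features[i], bag.coords[i], params, config)
            tile_bag = TileBag(
                slide_id=f"{bag.slide_id}_t{i}",
                patient_id=bag.patient_id,
                features=bag.features[i : i + 1],
                coords=bag.coords[i : i + 1],
            )
            tile_score = forward_bag(tile_bag, params, config).risk_probability
            embeddings.append(emb)
            rows.append(
                {
                    "slide_id": bag.slide_id,
                    "col": col,
                    "row": row,
                    "attention": score,
                    "risk_group": group,
                    "slide_score": pred.risk_probability,
                    "tile_score": tile_score,
                }
            )
    return TileEmbeddingTable(
        embeddings=np.asarray(embeddings), meta=pd.DataFrame(rows)
    )


def cluster_embeddings(
    embeddings: np.ndarray,
    n_neighbors: int = 50,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden communities on a cosine kNN graph of embeddings.

    The directed kNN sets are symmetrized by union; edge weights are cosine
    similarities (1 - cosine distance, clipped at a small positive floor).
    Labels are renumbered densely by decreasing cluster size.
    """
    X = np.asarray(embeddings, dtype=float)
    T = len(X)
    if T <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} points, got {T}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric="cosine").fit(X)
    dist, idx = nn.kneighbors(X)
    edges: dict[tuple[int, int], float] = {}
    for i in range(T):
        for d, j in zip(dist[i, 1:], idx[i, 1:]):  # drop self
            a, b = (i, int(j)) if i < j else (int(j), i)
            w = max(1.0 - float(d), 1e-6)
            prev = edges.get((a, b))
            edges[(a, b)] = w if prev is None else max(prev, w)
    g = igraph.Graph(n=T, edges=list(edges.keys()))
    partition = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=list(edges.values()),
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = np.asarray(partition.membership)
    # dense renumbering by decreasing size (ties by original id for determinism)
    ids, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    remap = {int(ids[i]): rank for rank, i in enumerate(order)}
    return np.array([remap[int(l)] for l in labels])


def classify_subclusters(
    labels: Sequence[int],
    risk_groups: Sequence[str],
    min_fraction: float = 0.25,
) -> SubclusterReport:
    """Label clusters high-specific / low-specific / colocalized.

    A cluster is retained in group g iff its tile count from g strictly
    exceeds ``min_fraction`` of the cluster total.
    """
    labels = np.asarray(labels)
    groups = np.asarray(risk_groups, dtype=object)
    if labels.shape != groups.shape:
        raise ValueError("labels and risk_groups must align")
    unknown = set(groups) - {"high", "low"}
    if unknown:
        raise ValueError(f"unknown risk groups: {sorted(unknown)}")
    report = SubclusterReport()
    for cid in np.unique(labels):
        sel = labels == cid
        n_total = int(sel.sum())
        n_high = int((groups[sel] == "high").sum())
        n_low = n_total - n_high
        keep_high = n_high > min_fraction * n_total
        keep_low = n_low > min_fraction * n_total
        if keep_high and keep_low:
            spec = "colocalized"
        elif keep_high:
            spec = "high-specific"
        else:
            spec = "low-specific"
        report.clusters[int(cid)] = {
            "n_total": n_total,
            "n_high": n_high,
            "n_low": n_low,
            "specificity": spec,
        }
    return report


def composition_dendrogram(
    labels: Sequence[int],
    tile_cellmaps: Mapping[int, CellMap],
    report: Optional[SubclusterReport] = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Ward dendrogram over min-max scaled subcluster cell compositions.

    ``tile_cellmaps`` maps each tile index (position in ``labels``) to its
    cell map.  Returns (scaled C x 5 composition matrix, scipy linkage
    matrix, cluster ids in row order).  Compositions are mean cells per tile
    by type; each type column is min-max scaled across clusters (constant
    columns become zero).
    """
    labels = np.asarray(labels)
    for i in range(len(labels)):
        if i not in tile_cellmaps:
            raise ValueError(f"missing cell map for tile {i}")
    cluster_ids = [int(c) for c in np.unique(labels)]
    comp = np.zeros((len(cluster_ids), len(CELL_TYPES)))
    for r, cid in enumerate(cluster_ids):
        members = np.flatnonzero(labels == cid)
        counts = np.array(
            [
                [tile_cellmaps[i].counts_by_type()[t] for t in CELL_TYPES]
                for i in members
            ],
            dtype=float,
        )
        comp[r] = counts.mean(axis=0)
    lo, hi = comp.min(axis=0), comp.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (comp - lo) / np.where(span > 0, span, 1.0), 0.0)
    if report is not None:
        for r, cid in enumerate(cluster_ids):
            if cid in report.clusters:
                report.clusters[cid]["composition"] = scaled[r].tolist()
    if len(cluster_ids) < 2:
        return scaled, np.zeros((0, 4)), cluster_ids
    Z = linkage(scaled, method="ward", metric="euclidean")
    return scaled, Z, cluster_ids
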