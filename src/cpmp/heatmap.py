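"""Whole-slide attention visualization and its quantitative evaluation.

Tile importance is the cls row of the head-averaged attention-rollout
matrix, min-max normalized to [0, 1] per slide.  Scores are painted onto a
pixel canvas at each tile's footprint; when visualization tiling overlaps
(the default visualization overlap rate is 0.1), pixels covered by
several tiles receive the arithmetic mean of the contributing scores, and
uncovered pixels carry NaN as the sentinel.  Concordance against a binary
region mask is reported as pixelwise ROC AUC plus recall / Dice /
overlap-ratio of the attention map binarized at a threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .data import TileBag
from .model import BagPrediction, ModelConfig, forward_bag

__all__ = [
    "AttentionRaster",
    "normalize_scores",
    "tile_attention_scores",
    "assemble_raster",
    "top_k_tiles",
    "concordance",
]


@dataclass
class AttentionRaster:
    """Per-tile scores painted on a pixel canvas (NaN = uncovered)."""

    canvas: np.ndarray  # 2-D float, values in [0,1] where covered
    tile_size_px: int
    stride_px: int
    overlap: float

    @property
    def covered(self) -> np.ndarray:
        return ~np.isnan(self.canvas)


def normalize_scores(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant vector maps to all 0.5.

    The constant case means "no salient region": rendering it mid-scale
    keeps the heatmap well-defined instead of dividing by zero.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-300:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def tile_attention_scores(
    bag: TileBag,
    params,
    config: ModelConfig,
    prediction: BagPrediction | None = None,
) -> np.ndarray:
    """Normalized per-tile attention scores in [0, 1] for one bag.

    Pass ``prediction`` to reuse an existing forward pass.
    """
    if prediction is None:
        prediction = forward_bag(bag, params, config)
    return normalize_scores(prediction.tile_scores_raw)


def assemble_raster(
    scores: np.ndarray,
    coords: np.ndarray,
    tile_size_px: int = 256,
    overlap: float = 0.0,
) -> AttentionRaster:
    """Paint per-tile scores onto a canvas at stride ``tile_size*(1-overlap)``.

    Overlapping footprints blend by arithmetic mean (linear in the scores);
    pixels no tile covers are NaN.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    coords = np.asarray(coords, dtype=int).reshape(-1, 2)
    if len(scores) != len(coords):
        raise ValueError("scores and coords must align")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap {overlap} outside [0, 1)")
    if (coords < 0).any():
        raise ValueError("negative tile coordinates")
    stride = max(1, int(round(tile_size_px * (1.0 - overlap))))
    width = coords[:, 0].max() * stride + tile_size_px
    height = coords[:, 1].max() * stride + tile_size_px
    acc = np.zeros((height, width))
    cnt = np.zeros((height, width), dtype=int)
    for s, (c, r) in zip(scores, coords):
        x0, y0 = c * stride, r * stride
        acc[y0 : y0 + tile_size_px, x0 : x0 + tile_size_px] += s
        cnt[y0 : y0 + tile_size_px, x0 : x0 + tile_size_px] += 1
    with np.errstate(invalid="ignore"):
        canvas = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return AttentionRaster(
        canvas=canvas, tile_size_px=tile_size_px, stride_px=stride, overlap=overlap
    )


def top_k_tiles(
    scores: np.ndarray, coords: np.ndarray, k: int
) -> list[tuple[tuple[int, int], float]]:
    """Top-k ((col, row), score) pairs, descending by score.

    Ties break by row-major coordinate order (row, then column); ``k`` above
    the tile count returns everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = np.asarray(scores, dtype=float).ravel()
    coords = np.asarray(coords, dtype=int).reshape(-1, 2)
    order = sorted(
        range(len(scores)),
        key=lambda i: (-scores[i], coords[i, 1], coords[i, 0]),
    )
    return [
        ((int(coords[i, 0]), int(coords[i, 1])), float(scores[i]))
        for i in order[: min(k, len(scores))]
    ]


def concordance(
    raster: AttentionRaster, mask: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Pixelwise agreement between the attention map and a binary mask.

    Over covered pixels: ``auc`` ranks raw attention values against the
    mask; the map binarized at ``threshold`` (>= high-attention) yields
    ``recall`` = TP/(TP+FN), ``dice`` = 2TP/(2TP+FP+FN) and
    ``overlap_ratio`` = TP/(TP+FP).  A single-class mask makes AUC NaN.
    """
    mask = np.asarray(mask)
    if mask.shape != raster.canvas.shape:
        raise ValueError(
            f"mask shape {mask.shape} != raster shape {raster.canvas.shape}"
        )
    cov = raster.covered
    values = raster.canvas[cov]
    truth = (mask[cov] > 0).astype(int)
    if truth.min() == truth.max():
        auc = float("nan")
    else:
        auc = float(roc_auc_score(truth, values))
    hot = values >= threshold
    tp = int((hot & (truth == 1)).sum())
    fp = int((hot & (truth == 0)).sum())
    fn = int((~hot & (truth == 1)).sum())
    recall = tp / (tp + fn) if tp + fn else float("nan")
    dice = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    overlap_ratio = tp / (tp + fp) if tp + fp else float("nan")
    return {"auc": auc, "recall": recall, "dice": dice,
            "overlap_ratio": overlap_ratio}
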