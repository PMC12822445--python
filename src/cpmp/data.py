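"""Core data containers and on-disk formats.

A slide is represented as a *bag* of per-tile feature vectors plus the
integer tile-grid coordinate of each tile.  Bags are stored one-per-file in
HDF5 with a fixed layout::

    /features           float32, n x c
    /coords             int32,   n x 2   (column, row)
    attrs: slide_id, patient_id, tile_size_px, magnification,
           label_normalized (optional)

Cell maps (nucleus centroids with one of five HoverNet-style classes) travel
as three-column CSV ``x_px,y_px,cell_type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

CELL_TYPES = (
    "neoplastic",
    "inflammatory",
    "necrotic",
    "connective",
    "non-neoplastic-epithelial",
)


class BagFormatError(ValueError):
    """Raised when an HDF5 bag file does not conform to the expected layout."""


@dataclass
class TileBag:
    """One slide's instances: features, tile-grid coordinates and metadata.

    ``coords`` are (column, row) indices on the tiling grid, not pixels.
    ``label_normalized`` is the continuous risk score on the [0, 1] scale
    (0.5 is the high/low decision boundary); it is absent for unlabeled
    slides.
    """

    slide_id: str
    patient_id: str
    features: np.ndarray
    coords: np.ndarray
    tile_size_px: int = 256
    magnification: str = "20x"
    label_normalized: Optional[float] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int32)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (n x c) matrix")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a 2-D (n x 2) matrix")
        if self.features.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"features rows ({self.features.shape[0]}) != coords rows "
                f"({self.coords.shape[0]})"
            )
        if self.features.shape[0] < 1:
            raise ValueError("a bag must contain at least one tile")
        if (self.coords < 0).any():
            raise ValueError("coords must be non-negative grid indices")
        if len({tuple(rc) for rc in self.coords.tolist()}) != len(self.coords):
            raise ValueError("duplicate tile coordinates within a bag")
        if self.tile_size_px <= 0:
            raise ValueError("tile_size_px must be positive")
        if self.label_normalized is not None:
            lab = float(self.label_normalized)
            if not 0.0 <= lab <= 1.0:
                raise ValueError(f"label_normalized {lab} outside [0, 1]")
            self.label_normalized = lab

    @property
    def n_tiles(self) -> int:
        return self.features.shape[0]

    @property
    def n_channels(self) -> int:
        return self.features.shape[1]


@dataclass
class CellMap:
    """Typed nucleus centroids within a rectangular tissue region."""

    centroids: np.ndarray  # m x 2, pixels
    cell_types: np.ndarray  # m labels from CELL_TYPES
    region_width_px: int
    region_height_px: int
    microns_per_px: float = 0.5

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if len(self.centroids) != len(self.cell_types):
            raise ValueError("centroids and cell_types length mismatch")
        if self.region_width_px <= 0 or self.region_height_px <= 0:
            raise ValueError("region dimensions must be positive")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")
        bad = set(self.cell_types) - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell types: {sorted(bad)}")
        x, y = self.centroids[:, 0], self.centroids[:, 1]
        if len(x) and (
            (x < 0).any()
            or (y < 0).any()
            or (x >= self.region_width_px).any()
            or (y >= self.region_height_px).any()
        ):
            raise ValueError("centroids must lie inside the region")

    @property
    def n_cells(self) -> int:
        return len(self.centroids)

    def counts_by_type(self) -> dict[str, int]:
        return {t: int((self.cell_types == t).sum()) for t in CELL_TYPES}

    @property
    def area_mm2(self) -> float:
        w_mm = self.region_width_px * self.microns_per_px / 1000.0
        h_mm = self.region_height_px * self.microns_per_px / 1000.0
        return w_mm * h_mm


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated bag."""

    signal_tile_mask: np.ndarray  # n booleans
    signal_direction: np.ndarray  # unit vector, c channels
    signal_strength: float
    blob_centers: list = field(default_factory=list)
    seed: int = 0


# ---------------------------------------------------------------------------
# HDF5 bag I/O
# ---------------------------------------------------------------------------

def write_bag(bag: TileBag, path) -> None:
    """Write a bag to ``path`` in the canonical HDF5 layout."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords.astype(np.int32))
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patient_id"] = bag.patient_id
        f.attrs["tile_size_px"] = int(bag.tile_size_px)
        f.attrs["magnification"] = bag.magnification
        if bag.label_normalized is not None:
            f.attrs["label_normalized"] = float(bag.label_normalized)


def read_bag(path) -> TileBag:
    """Read a bag written by :func:`write_bag`.

    Raises :class:`BagFormatError` naming the offending dataset when the
    file does not conform to the layout.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("features", "coords"):
            if name not in f:
                raise BagFormatError(f"{path}: missing dataset '{name}'")
        features = np.asarray(f["features"])
        coords = np.asarray(f["coords"])
        if features.ndim != 2:
            raise BagFormatError(f"{path}: dataset 'features' is not 2-D")
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise BagFormatError(f"{path}: dataset 'coords' is not n x 2")
        if features.shape[0] != coords.shape[0]:
            raise BagFormatError(
                f"{path}: dataset 'coords' row count {coords.shape[0]} does "
                f"not match 'features' ({features.shape[0]})"
            )
        label = f.attrs.get("label_normalized", None)
        return TileBag(
            slide_id=str(f.attrs.get("slide_id", path.stem)),
            patient_id=str(f.attrs.get("patient_id", path.stem)),
            features=features,
            coords=coords,
            tile_size_px=int(f.attrs.get("tile_size_px", 256)),
            magnification=str(f.attrs.get("magnification", "20x")),
            label_normalized=None if label is None else float(label),
        )


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id",
    "slide_id",
    "mp_score_raw",
    "mp_score_normalized",
    "risk_group",
]


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_cellmap(cellmap: CellMap, path) -> None:
    pd.DataFrame(
        {
            "x_px": cellmap.centroids[:, 0],
            "y_px": cellmap.centroids[:, 1],
            "cell_type": cellmap.cell_types,
        }
    ).to_csv(path, index=False)


def read_cellmap(
    path,
    region_width_px: Optional[int] = None,
    region_height_px: Optional[int] = None,
    microns_per_px: float = 0.5,
) -> CellMap:
    """Read a ``x_px,y_px,cell_type`` CSV.

    Region dimensions default to the smallest integer box containing all
    centroids when not given explicitly.
    """
    df = pd.read_csv(path)
    for col in ("x_px", "y_px", "cell_type"):
        if col not in df.columns:
            raise ValueError(f"cell map CSV missing column '{col}'")
    xy = df[["x_px", "y_px"]].to_numpy(dtype=float)
    if region_width_px is None:
        region_width_px = int(np.floor(xy[:, 0].max())) + 1 if len(xy) else 1
    if region_height_px is None:
        region_height_px = int(np.floor(xy[:, 1].max())) + 1 if len(xy) else 1
    return CellMap(
        centroids=xy,
        cell_types=df["cell_type"].to_numpy(dtype=object),
        region_width_px=region_width_px,
        region_height_px=region_height_px,
        microns_per_px=microns_per_px,
    )
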