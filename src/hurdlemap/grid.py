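"""Raster grid and predictor-stack containers.

Conventions
-----------
* Planar, equal-area coordinate reference system whose units are kilometres,
  so cell areas in km² are exact products of the cell size.
* Row 0 is the northernmost row (raster convention); the affine transform is
  axis-aligned with square cells.
* Pixel extents are half-open: a point lies in cell ``(i, j)`` iff
  ``x0 + j*cs <= x < x0 + (j+1)*cs`` and ``y0 - (i+1)*cs < y <= y0 - i*cs``.
* Internally rows/cols are 0-based; user-facing tables carry pixel-centroid
  coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridTransform:
    """Affine metadata of an axis-aligned raster: origin is the top-left corner."""

    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.x_origin, self.y_origin, self.cell_size]).all():
            raise ValueError("grid transform must be finite")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")


class RasterGrid:
    """A single 2-D raster layer with a missing-data mask.

    Parameters
    ----------
    values : array-like
        2-D array; may be a masked array. Unmasked values must be finite.
    transform : GridTransform
        Origin (top-left corner) and cell size, in CRS units (km).
    crs : str
        Identifier of the (synthetic, equal-area) CRS.
    nodata : float
        Sentinel written to files for masked cells.
    """

    def __init__(self, values, transform: GridTransform, crs: str = "synthetic-laea-km",
                 nodata: float = -9999.0):
        arr = np.ma.masked_invalid(np.ma.asarray(values, dtype=float))
        if arr.ndim != 2:
            raise ValueError("raster values must be 2-D")
        self.values = arr
        self.transform = transform
        self.crs = crs
        self.nodata = float(nodata)

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    @property
    def cell_area_km2(self) -> float:
        return self.transform.cell_size ** 2

    @property
    def mask(self) -> np.ndarray:
        return np.ma.getmaskarray(self.values)

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        t = self.transform
        nrow, ncol = self.shape
        return (t.x_origin, t.y_origin - nrow * t.cell_size,
                t.x_origin + ncol * t.cell_size, t.y_origin)

    def index_to_center(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        t = self.transform
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = t.x_origin + (cols + 0.5) * t.cell_size
        y = t.y_origin - (rows + 0.5) * t.cell_size
        return x, y

    def coords_to_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); points outside the grid get -1."""
        t = self.transform
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - t.x_origin) / t.cell_size).astype(int)
        row = np.floor((t.y_origin - y) / t.cell_size).astype(int)
        nrow, ncol = self.shape
        bad = (col < 0) | (col >= ncol) | (row < 0) | (row >= nrow)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of every cell, as two arrays shaped like the grid."""
        nrow, ncol = self.shape
        rows, cols = np.mgrid[0:nrow, 0:ncol]
        return self.index_to_center(rows, cols)

    # -- derivation ------------------------------------------------------
    def like(self, values, copy_mask: bool = False) -> "RasterGrid":
        """New raster on the same grid; optionally inherit this raster's mask."""
        out = RasterGrid(values, self.transform, crs=self.crs, nodata=self.nodata)
        if copy_mask:
            out.values = np.ma.masked_where(self.mask, out.values)
        return out

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.transform, crs=self.crs,
                          nodata=self.nodata)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def sample(self, x, y):
        """Values at coordinates; masked where outside grid or nodata."""
        row, col = self.coords_to_index(x, y)
        out = np.ma.masked_all(np.shape(row), dtype=float)
        ok = row >= 0
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (f"RasterGrid(shape={self.shape}, cell={self.cell_size} km, "
                f"crs={self.crs!r}, unmasked={self.n_unmasked})")


# the 7 predictor categories used throughout
PREDICTOR_TYPES = ("water", "human", "topography", "precipitation",
                   "temperature", "dhi", "soil")


@dataclass
class PredictorStack:
    """Aligned raster layers, each tagged with a predictor category."""

    layers: dict[str, RasterGrid]
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        names = list(self.layers)
        ref = self.layers[names[0]]
        for name in names[1:]:
            if not self.layers[name].aligned_with(ref):
                raise ValueError(f"layer {name!r} is not aligned with {names[0]!r}")
        for name, t in self.types.items():
            if name not in self.layers:
                raise ValueError(f"type given for unknown layer {name!r}")
            if t not in PREDICTOR_TYPES:
                raise ValueError(f"unknown predictor type {t!r} for layer {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def joint_mask(self) -> np.ndarray:
        """True where ANY layer is masked."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for lyr in self.layers.values():
            m |= lyr.mask
        return m

    def subset(self, names) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack is missing layer(s): {missing}")
        return PredictorStack({n: self.layers[n] for n in names},
                              {n: self.types[n] for n in names if n in self.types})

    def by_type(self) -> dict[str, list[str]]:
        """Layer names grouped by predictor category, category order fixed."""
        groups: dict[str, list[str]] = {}
        for t in PREDICTOR_TYPES:
            members = [n for n in self.names if self.types.get(n) == t]
            if members:
                groups[t] = members
        return groups

    def values_matrix(self, names=None) -> tuple[np.ndarray, np.ndarray]:
        """(cells × layers) matrix over jointly unmasked cells.

        Returns
        -------
        X : ndarray, shape (n_cells, n_layers)
        flat_index : ndarray
            Flat indices of the retained cells in the 2-D grid.
        """
        names = list(names) if names is not None else self.names
        ok = ~self.joint_mask()
        idx = np.flatnonzero(ok.ravel())
        X = np.column_stack([np.ma.getdata(self.layers[n].values).ravel()[idx]
                             for n in names])
        return X, idx

    def extract(self, x, y, names=None) -> np.ndarray:
        """Predictor values at point coordinates (cells × layers), masked outside."""
        names = list(names) if names is not None else self.names
        cols = [self.layers[n].sample(x, y) for n in names]
        return np.ma.column_stack(cols)
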