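"""Readers and writers for the plain-text formats the pipeline touches.

Rasters are stored as ESRI ASCII grids (``.asc``) with a small JSON sidecar
(``<name>.asc.json``) holding the CRS id and the value dtype, polygons as
GeoJSON, and tables as CSV. Integer rasters round-trip bit-exactly; float
rasters round-trip within repr precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridTransform, PredictorStack, RasterGrid


# ---------------------------------------------------------------------------
# rasters (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path, dtype: str | None = None) -> Path:
    """Write a raster as an ESRI ASCII grid plus a JSON sidecar.

    ``dtype='int'`` writes integers (exact round-trip); default infers it
    from the data (integral unmasked values → int).
    """
    path = Path(path)
    nrow, ncol = grid.shape
    t = grid.transform
    data = np.ma.getdata(grid.values).copy()
    mask = grid.mask
    if dtype is None:
        unmasked = data[~mask]
        is_int = unmasked.size > 0 and np.all(unmasked == np.round(unmasked))
        dtype = "int" if is_int else "float"
    data[mask] = grid.nodata
    header = (f"ncols {ncol}\n"
              f"nrows {nrow}\n"
              f"xllcorner {t.x_origin!r}\n"
              f"yllcorner {t.y_origin - nrow * t.cell_size!r}\n"
              f"cellsize {t.cell_size!r}\n"
              f"NODATA_value {grid.nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        if dtype == "int":
            np.savetxt(fh, data.astype(np.int64), fmt="%d")
        else:
            np.savetxt(fh, data, fmt="%.17g")
    sidecar = {"crs": grid.crs, "dtype": dtype}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))
    return path


def read_raster(path) -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrow, ncol = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrow, ncol)
    cs = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    transform = GridTransform(header["xllcorner"], header["yllcorner"] + nrow * cs, cs)
    crs = "synthetic-laea-km"
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        crs = json.loads(sidecar_path.read_text()).get("crs", crs)
    values = np.ma.masked_equal(data, nodata)
    return RasterGrid(values, transform, crs=crs, nodata=nodata)


def read_stack(paths: dict[str, str | Path], type_map: dict[str, str] | None = None
               ) -> PredictorStack:
    """Read named raster files into an aligned stack.

    Raises a ``ValueError`` naming the first layer whose grid does not match;
    no implicit resampling is performed.
    """
    layers: dict[str, RasterGrid] = {}
    ref_name = None
    for name, p in paths.items():
        grid = read_raster(p)
        if ref_name is None:
            ref_name = name
        elif not grid.aligned_with(layers[ref_name]):
            raise ValueError(
                f"layer {name!r} grid (shape {grid.shape}, cell {grid.cell_size}) "
                f"does not match {ref_name!r}; resampling is not supported")
        layers[name] = grid
    return PredictorStack(layers, dict(type_map or {}))


# ---------------------------------------------------------------------------
# polygons (GeoJSON)
# ---------------------------------------------------------------------------

def write_geojson(geoms, path, properties=None) -> Path:
    """Write one geometry or a list of geometries as a GeoJSON FeatureCollection."""
    path = Path(path)
    if isinstance(geoms, BaseGeometry):
        geoms = [geoms]
    properties = properties or [{} for _ in geoms]
    features = [{"type": "Feature", "geometry": mapping(g), "properties": p}
                for g, p in zip(geoms, properties)]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_geojson(path) -> tuple[list[BaseGeometry], list[dict]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        feats = doc["features"]
    elif doc.get("type") == "Feature":
        feats = [doc]
    else:  # bare geometry
        return [shape(doc)], [{}]
    return ([shape(f["geometry"]) for f in feats],
            [f.get("properties") or {} for f in feats])


# ---------------------------------------------------------------------------
# tables (CSV)
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
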