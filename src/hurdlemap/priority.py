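"""Consensus conservation prioritization.

Combines, per species, the binarized presence map and the median-binarized
abundance map, sums the four binary layers cell-wise into priority categories
1 (low) … 4 (very high), delineates critical conservation areas (very-high
patches plus high patches inside the convex hull connecting them), and
accounts areas in km² against zone and protected-area polygons. All area
algebra happens on the planar equal-area grid, so km² are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid import RasterGrid

log = logging.getLogger(__name__)

CATEGORY_LABELS = {0: "none", 1: "low", 2: "medium", 3: "high", 4: "very_high"}


def rescale01(amap: RasterGrid) -> RasterGrid:
    """Min–max rescale unmasked values to [0, 1] (order preserving)."""
    v = amap.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ValueError("rescale is undefined for a constant map")
    return amap.like((v - vmin) / (vmax - vmin))


@dataclass
class RelationshipResult:
    """Abundance–suitability spatial correlation on sampled presence cells."""

    r: float
    p_value: float
    ci95: tuple[float, float]
    n_cells: int
    method: str = "same_set"      # "same_set" | "best_models"
    policy: str = "raw"


def spatial_correlation(suitability: RasterGrid, abundance: RasterGrid,
                        sample_frac: float = 0.10, seed=None,
                        method: str = "best_models", policy: str = "raw"
                        ) -> RelationshipResult:
    """Pearson r over a random ~``sample_frac`` of jointly unmasked cells.

    The confidence interval is the Fisher-z 95% interval; the p-value is
    two-sided.
    """
    if not suitability.aligned_with(abundance):
        raise ValueError("maps are not aligned")
    ok = ~(suitability.mask | abundance.mask)
    idx = np.flatnonzero(ok.ravel())
    if idx.size < 3:
        raise ValueError("fewer than 3 jointly unmasked cells")
    n = max(3, int(round(sample_frac * idx.size)))
    n = min(n, idx.size)
    rng = np.random.default_rng(seed)
    take = rng.choice(idx, size=n, replace=False)
    s = np.ma.getdata(suitability.values).ravel()[take]
    a = np.ma.getdata(abundance.values).ravel()[take]
    res = stats.pearsonr(s, a)
    r = float(res.statistic)
    # Fisher z interval
    if abs(r) < 1 and n > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959963984540054 * se)),
              float(np.tanh(z + 1.959963984540054 * se)))
    else:
        ci = (r, r)
    return RelationshipResult(r, float(res.pvalue), ci, n, method, policy)


def binarize_abundance_median(amap: RasterGrid) -> RasterGrid:
    """1 where strictly above the median of unmasked cells ("highly abundant").

    Ties at the median go to 0, so at most half the cells are flagged.
    """
    v = amap.values
    if v.count() < 1:
        raise ValueError("abundance map is fully masked")
    med = float(np.ma.median(v))
    out = (np.ma.getdata(v) > med).astype(float)
    return amap.like(np.ma.masked_where(amap.mask, out))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass
class PriorityMap:
    """Integer consensus raster: category = Σ of four binary layers (0–4)."""

    raster: RasterGrid
    provenance: dict[str, RasterGrid] = field(default_factory=dict)

    def category_areas_km2(self) -> dict[str, float]:
        cell = self.raster.cell_area_km2
        v = self.raster.values
        return {CATEGORY_LABELS[c]: float((v == c).sum() * cell)
                for c in range(5)}


def consensus(presence_a: RasterGrid, abundant_a: RasterGrid,
              presence_b: RasterGrid, abundant_b: RasterGrid) -> PriorityMap:
    """Cell-wise sum of the four binary layers.

    1 = one species present (low); 2 = one present and abundant, or both
    present (medium); 3 = both present, one abundant (high); 4 = both present
    and abundant (very high). Requires hurdle containment per species
    (abundant ⇒ present), otherwise the category legend would be ambiguous.
    """
    layers = {"presence_a": presence_a, "abundant_a": abundant_a,
              "presence_b": presence_b, "abundant_b": abundant_b}
    ref = presence_a
    for name, lyr in layers.items():
        if not lyr.aligned_with(ref):
            raise ValueError(f"layer {name!r} is not aligned")
    for sp, (p, a) in {"a": (presence_a, abundant_a),
                       "b": (presence_b, abundant_b)}.items():
        pv = np.ma.getdata(p.values) > 0
        av = (np.ma.getdata(a.values) > 0) & ~a.mask
        if np.any(av & ~pv):
            raise ValueError(
                f"species {sp}: abundant cells outside the presence mask break "
                "the hurdle containment required by the category legend")
    # a cell masked in a binary layer contributes 0 (absence)
    total = np.zeros(ref.shape)
    for lyr in layers.values():
        total += np.where(lyr.mask, 0.0, np.ma.getdata(lyr.values))
    return PriorityMap(ref.like(total), layers)


# ---------------------------------------------------------------------------
# vectorization and critical areas
# ---------------------------------------------------------------------------

def cells_to_polygons(binary: RasterGrid) -> list[BaseGeometry]:
    """Dissolve 8-connected patches of 1-cells into polygons."""
    arr = (np.ma.getdata(binary.values) > 0) & ~binary.mask
    labels, n = ndimage.label(arr, structure=np.ones((3, 3), dtype=int))
    t = binary.transform
    nrow, _ = binary.shape
    polys = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        boxes = [box(t.x_origin + c * t.cell_size,
                     t.y_origin - (r + 1) * t.cell_size,
                     t.x_origin + (c + 1) * t.cell_size,
                     t.y_origin - r * t.cell_size)
                 for r, c in zip(rows, cols)]
        polys.append(unary_union(boxes))
    return polys


@dataclass
class CriticalArea:
    """Very-high patches ∪ (high patches ∩ hull of very-high patches)."""

    polygon: BaseGeometry
    hull: BaseGeometry | None
    area_km2: float

    def __post_init__(self) -> None:
        if not self.polygon.is_empty and self.area_km2 <= 0:
            raise ValueError("non-empty critical area with zero area")


def critical_areas(priority: PriorityMap, per_cluster: bool = False) -> CriticalArea:
    """Delineate where conservation must be critically prioritized.

    The connecting hull is the convex hull of the union of all very-high
    patches (the minimal convex set containing them); ``per_cluster=True``
    instead hulls each connected cluster of very-high patches separately.
    High patches are kept only where they intersect the hull.
    """
    r = priority.raster
    very_high = r.like((np.ma.getdata(r.values) == 4).astype(float))
    high = r.like((np.ma.getdata(r.values) == 3).astype(float))
    vh_polys = cells_to_polygons(very_high)
    if not vh_polys:
        log.warning("no very-high cells: critical area is empty")
        from shapely.geometry import Polygon
        return CriticalArea(Polygon(), None, 0.0)
    if per_cluster:
        hull = unary_union([p.convex_hull for p in vh_polys])
    else:
        hull = unary_union(vh_polys).convex_hull
    high_polys = cells_to_polygons(high)
    kept_high = [p.intersection(hull) for p in high_polys if p.intersects(hull)]
    combined = unary_union(vh_polys + [g for g in kept_high if not g.is_empty])
    return CriticalArea(combined, hull, float(combined.area))


# ---------------------------------------------------------------------------
# area accounting
# ---------------------------------------------------------------------------

def area_accounting(priority: PriorityMap, zones: dict[str, BaseGeometry],
                    overlap: str = "all") -> pd.DataFrame:
    """km² per priority category × zone, by exact cell-box ∩ zone geometry.

    Overlapping zones double-count by default (``overlap="all"``, warned);
    ``overlap="first"`` assigns each cell's area to the first containing zone
    in the given order. The ``TOTAL`` row sums the categories per zone.
    """
    r = priority.raster
    t = r.transform
    vals = np.ma.getdata(r.values).astype(int)
    nrow, ncol = r.shape
    cats = range(1, 5)
    # precompute cell boxes only for prioritized cells
    occupied = np.argwhere((vals >= 1) & ~r.mask)
    boxes = {}
    for rr, cc in occupied:
        boxes[(rr, cc)] = box(t.x_origin + cc * t.cell_size,
                              t.y_origin - (rr + 1) * t.cell_size,
                              t.x_origin + (cc + 1) * t.cell_size,
                              t.y_origin - rr * t.cell_size)
    zone_names = list(zones)
    if overlap == "all":
        for i, za in enumerate(zone_names):
            for zb in zone_names[i + 1:]:
                if zones[za].intersection(zones[zb]).area > 1e-9:
                    log.warning("zones %r and %r overlap: their areas are "
                                "double-counted", za, zb)
    areas = {z: {CATEGORY_LABELS[c]: 0.0 for c in cats} for z in zone_names}
    for (rr, cc), b in boxes.items():
        cat = CATEGORY_LABELS[vals[rr, cc]]
        for z in zone_names:
            inter = b.intersection(zones[z]).area
            if inter > 0:
                areas[z][cat] += inter
                if overlap == "first":
                    break
    df = pd.DataFrame(areas)
    df.loc["TOTAL"] = df.sum(axis=0)
    df["ALL_ZONES"] = df.sum(axis=1)
    return df


def protected_overlap(critical: CriticalArea, pa_polygons: list[BaseGeometry]
                      ) -> tuple[float, float, float]:
    """(protected km², unprotected km², protected fraction) of the critical area."""
    geom = critical.polygon
    if geom.is_empty:
        return 0.0, 0.0, 0.0
    pa = unary_union([g if g.is_valid else g.buffer(0) for g in pa_polygons]) \
        if pa_polygons else None
    if pa is None or pa.is_empty:
        return 0.0, float(geom.area), 0.0
    if not geom.is_valid:
        geom = geom.buffer(0)
        if not geom.is_valid:
            raise ValueError("critical-area geometry could not be repaired")
    protected = float(geom.intersection(pa).area)
    total = float(geom.area)
    return protected, total - protected, protected / total
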