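"""Occurrence and transect preparation.

Cleans raw point records, collapses them to pixel centroids, spatially
rarefies them with distances tied to local environmental heterogeneity,
builds the calibration area used for background sampling ("background
thickening"), draws pseudo-absences, and rasterizes survey transects to
per-pixel count records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from shapely import contains_xy
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grid import PredictorStack, RasterGrid

log = logging.getLogger(__name__)

#: fixed rule order: each removed record is attributed to its first failing rule
CLEANING_RULES = ("erroneous", "out_of_range", "old_year", "high_uncertainty",
                  "duplicate")


@dataclass
class CleaningReport:
    """Bookkeeping of a cleaning pass: input = output + Σ removals, always."""

    input_count: int
    removals: dict[str, int]
    output_count: int

    def __post_init__(self) -> None:
        if self.input_count != self.output_count + sum(self.removals.values()):
            raise ValueError("cleaning report does not reconcile")


def clean_occurrences(records: pd.DataFrame, min_year: int = 1979,
                      max_uncertainty_km: float = 10.0,
                      range_polygon: BaseGeometry | None = None,
                      ) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop unusable records; attribute each removal to exactly one rule.

    Rules, in order: non-finite coordinates ("erroneous"); outside the
    range polygon ("out_of_range"); ``year < min_year``; coordinate
    uncertainty strictly above ``max_uncertainty_km``; duplicated
    (species, x, y, year) keeping the first.
    """
    df = records.copy()
    n_in = len(df)
    removals = {rule: 0 for rule in CLEANING_RULES}
    failed = np.zeros(n_in, dtype=bool)

    xy_ok = np.isfinite(df["x"].to_numpy(float)) & np.isfinite(df["y"].to_numpy(float))
    _attribute(~xy_ok, failed, removals, "erroneous")

    if range_polygon is not None:
        inside = np.zeros(n_in, dtype=bool)
        inside[xy_ok] = contains_xy(range_polygon, df["x"].to_numpy(float)[xy_ok],
                                    df["y"].to_numpy(float)[xy_ok])
        _attribute(xy_ok & ~inside, failed, removals, "out_of_range")

    year = pd.to_numeric(df.get("year"), errors="coerce").to_numpy(float)
    _attribute(year < min_year, failed, removals, "old_year")

    unc = pd.to_numeric(df.get("uncertainty_km"), errors="coerce").to_numpy(float)
    _attribute(unc > max_uncertainty_km, failed, removals, "high_uncertainty")

    survivors = df.loc[~failed]
    dup = survivors.duplicated(subset=[c for c in ("species", "x", "y", "year")
                                       if c in survivors.columns], keep="first")
    removals["duplicate"] = int(dup.sum())
    out = survivors.loc[~dup.to_numpy()].reset_index(drop=True)
    report = CleaningReport(n_in, removals, len(out))
    log.info("cleaning: %d -> %d records (%s)", n_in, len(out), removals)
    return out, report


def _attribute(mask: np.ndarray, failed: np.ndarray, removals: dict[str, int],
               rule: str) -> None:
    fresh = np.asarray(mask, dtype=bool) & ~failed
    removals[rule] = int(fresh.sum())
    failed |= fresh


def thin_to_pixel_centroids(records: pd.DataFrame, grid: RasterGrid) -> pd.DataFrame:
    """At most one record per pixel, snapped to the pixel centroid.

    Records falling outside the grid are dropped (logged). The first record
    in each occupied pixel is kept; its coordinates are replaced by the
    centroid of that pixel.
    """
    row, col = grid.coords_to_index(records["x"].to_numpy(float),
                                    records["y"].to_numpy(float))
    inside = row >= 0
    n_out = int((~inside).sum())
    if n_out:
        log.warning("thinning: dropped %d record(s) outside the grid", n_out)
    df = records.loc[inside].copy()
    r, c = row[inside], col[inside]
    df["_pix"] = r * grid.shape[1] + c
    df = df.drop_duplicates(subset="_pix", keep="first")
    rr = (df.pop("_pix")).to_numpy()
    x, y = grid.index_to_center(rr // grid.shape[1], rr % grid.shape[1])
    df["x"], df["y"] = x, y
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# heterogeneity-stratified rarefaction
# ---------------------------------------------------------------------------

def heterogeneity_raster(stack: PredictorStack) -> RasterGrid:
    """Per-cell environmental heterogeneity.

    Defined as the mean, over layers, of the absolute spatial gradient
    magnitude of each standardized layer — a multivariate roughness statistic
    with no units.
    """
    acc = np.zeros(stack.grid.shape)
    for name in stack.names:
        v = np.ma.getdata(stack[name].values).astype(float)
        z = (v - v.mean()) / (v.std() or 1.0)
        gy, gx = np.gradient(z)
        acc += np.hypot(gx, gy)
    het = acc / len(stack)
    return stack.grid.like(het, copy_mask=True)


def classify_heterogeneity(het: RasterGrid) -> tuple[RasterGrid, np.ndarray]:
    """Tercile split into strata 0 (high), 1 (medium), 2 (low heterogeneity)."""
    vals = het.values.compressed()
    t1, t2 = np.quantile(vals, [1 / 3, 2 / 3])
    data = np.ma.getdata(het.values)
    strata = np.where(data >= t2, 0, np.where(data >= t1, 1, 2)).astype(float)
    return het.like(strata, copy_mask=True), np.array([t1, t2])


def rarefy_by_heterogeneity(records: pd.DataFrame, het: RasterGrid,
                            distances_km: tuple[float, float, float] = (1.0, 3.0, 5.0),
                            seed=None) -> pd.DataFrame:
    """Greedy spatial thinning, stricter where the environment is smoother.

    Records in the high-heterogeneity stratum are thinned at
    ``distances_km[0]``, medium at ``[1]``, low at ``[2]``. Within each
    stratum the greedy pass visits records in a seed-shuffled order (ties
    broken by record order) and keeps a record iff no already-kept record of
    the same stratum lies strictly closer than the stratum distance.
    Idempotent: a second pass removes nothing.
    """
    if len(records) == 0:
        return records.copy()
    strata_grid, _ = classify_heterogeneity(het)
    x = records["x"].to_numpy(float)
    y = records["y"].to_numpy(float)
    s = np.ma.getdata(strata_grid.sample(x, y)).astype(int)
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(records), dtype=bool)
    for stratum, dist in zip((0, 1, 2), distances_km):
        idx = np.flatnonzero(s == stratum)
        if idx.size == 0:
            continue
        order = idx[np.lexsort((idx, rng.permutation(idx.size)))]
        kept: list[int] = []
        for i in order:
            pt = np.array([x[i], y[i]])
            if all(np.hypot(*(pt - np.array([x[j], y[j]]))) >= dist for j in kept):
                kept.append(i)
        keep[kept] = True
    return records.loc[keep].sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# calibration area and pseudo-absences
# ---------------------------------------------------------------------------

@dataclass
class CalibrationArea:
    """Background-sampling extent: buffered local hulls ∪ the range polygon."""

    polygon: BaseGeometry
    hull_km: float
    buffer_km: float
    n_clusters: int = 1
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.polygon.is_empty:
            raise ValueError("calibration area is empty")
        if not self.polygon.is_valid:
            raise ValueError("calibration area geometry is invalid")


def build_calibration_area(records: pd.DataFrame, hull_km: float, buffer_km: float,
                           range_polygon: BaseGeometry | None = None
                           ) -> CalibrationArea:
    """Union of buffered convex hulls of occurrence clusters with the range.

    "Hulls of peripheral occurrences within a distance D" is realized as:
    single-linkage clustering of occurrences at threshold ``hull_km``, a
    convex hull per cluster, each hull buffered by ``buffer_km``, all unioned
    with the published range polygon. Keeps background sampling local to the
    occurrences (background thickening) without a global hull.
    """
    pts = records[["x", "y"]].to_numpy(float)
    notes: list[str] = []
    if len(pts) < 3:
        notes.append(f"degenerate: only {len(pts)} record(s); buffering points")
        pieces = [Point(*p).buffer(buffer_km) for p in pts]
        n_clusters = len(pts)
    else:
        if len(pts) == 0:
            raise ValueError("cannot build a calibration area from zero records")
        d = pdist(pts)
        labels = (fcluster(linkage(d, method="single"), t=hull_km,
                           criterion="distance")
                  if d.size else np.ones(len(pts), dtype=int))
        n_clusters = int(labels.max())
        pieces = []
        for lab in range(1, n_clusters + 1):
            cluster = pts[labels == lab]
            hull = MultiPoint([tuple(p) for p in cluster]).convex_hull
            pieces.append(hull.buffer(buffer_km))
    area = unary_union(pieces) if pieces else None
    if range_polygon is not None:
        area = range_polygon if area is None else unary_union([area, range_polygon])
    if area is None:
        raise ValueError("no records and no range polygon")
    if not area.is_valid:
        area = area.buffer(0)
    return CalibrationArea(area, hull_km, buffer_km, n_clusters, notes)


def sample_pseudo_absences(area: CalibrationArea, grid: RasterGrid,
                           occupied: pd.DataFrame | np.ndarray,
                           n: int = 10_000, seed=None) -> pd.DataFrame:
    """Exactly ``n`` distinct background cells, uniform over eligible cells.

    Eligible cells are unmasked, have centroids inside the calibration area,
    and are not occupied by any occurrence record. Sampling is without
    replacement; a deficit of eligible cells is an error stating the gap.
    """
    if n <= 0:
        raise ValueError("pseudo-absence count must be positive")
    nrow, ncol = grid.shape
    if isinstance(occupied, pd.DataFrame):
        r, c = grid.coords_to_index(occupied["x"].to_numpy(float),
                                    occupied["y"].to_numpy(float))
        occ_flat = (r[r >= 0] * ncol + c[r >= 0])
    else:
        occ_flat = np.asarray(occupied).ravel()
    xs, ys = grid.cell_centers()
    inside = contains_xy(area.polygon, xs.ravel(), ys.ravel())
    eligible = inside & ~grid.mask.ravel()
    eligible[np.asarray(occ_flat, dtype=int)] = False
    pool = np.flatnonzero(eligible)
    if pool.size < n:
        raise ValueError(
            f"only {pool.size} eligible cells for {n} pseudo-absences "
            f"(deficit {n - pool.size})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, (nrow, ncol))
    x, y = grid.index_to_center(rows, cols)
    return pd.DataFrame({"x": x, "y": y, "row": rows, "col": cols})


# ---------------------------------------------------------------------------
# transect rasterization
# ---------------------------------------------------------------------------

def rasterize_transects(geometries: list[LineString], counts, grid: RasterGrid
                        ) -> pd.DataFrame:
    """Overlay survey polylines on the grid: one record per intersected pixel.

    Pixel length is the exact geometric intersection length (pixels with
    zero-length intersections are skipped), so per transect the pixel lengths
    sum to the transect length. The transect's total count is apportioned to
    pixels proportionally to length with a largest-remainder rounding, so
    per-pixel counts are integers summing to the total.
    """
    records = []
    counts = np.asarray(counts)
    for tidx, (line, total) in enumerate(zip(geometries, counts)):
        xmin, ymin, xmax, ymax = line.bounds
        r0, c0 = grid.coords_to_index(xmin, ymax)
        r1, c1 = grid.coords_to_index(xmax, ymin)
        nrow, ncol = grid.shape
        gxmin, gymin, gxmax, gymax = grid.bounds()
        cs = grid.cell_size
        cmin = max(0, int(np.floor((xmin - gxmin) / cs)))
        cmax = min(ncol - 1, int(np.floor((xmax - gxmin) / cs)))
        rmin = max(0, int(np.floor((gymax - ymax) / cs)))
        rmax = min(nrow - 1, int(np.floor((gymax - ymin) / cs)))
        cells, lengths = [], []
        for r in range(rmin, rmax + 1):
            for c in range(cmin, cmax + 1):
                cell = box(gxmin + c * cs, gymax - (r + 1) * cs,
                           gxmin + (c + 1) * cs, gymax - r * cs)
                seg = line.intersection(cell)
                if seg.is_empty or seg.length <= 1e-12:
                    continue
                cells.append((r, c))
                lengths.append(seg.length)
        if not cells:
            continue
        lengths = np.asarray(lengths)
        # largest-remainder apportionment of the integer total count
        quota = total * lengths / lengths.sum()
        base = np.floor(quota).astype(int)
        short = int(total - base.sum())
        order = np.argsort(-(quota - base))
        base[order[:short]] += 1
        for (r, c), seg_len, cnt in zip(cells, lengths, base):
            x, y = grid.index_to_center(r, c)
            records.append((f"T{tidx:03d}", float(x), float(y), int(cnt),
                            float(seg_len)))
    return pd.DataFrame(records,
                        columns=["transect_id", "x", "y", "count", "length_km"])
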