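"""Occurrence cleaning, thinning, rarefaction, calibration areas,
pseudo-absences, and transect rasterization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare
from shapely.geometry import LineString, box

from hurdlemap.grid import GridTransform, RasterGrid
from hurdlemap.occurrences import (build_calibration_area, clean_occurrences,
                                   heterogeneity_raster,
                                   rarefy_by_heterogeneity,
                                   rasterize_transects, sample_pseudo_absences,
                                   thin_to_pixel_centroids)
from tests.conftest import make_stack


def records(rows):
    return pd.DataFrame(rows, columns=["species", "x", "y", "year",
                                       "uncertainty_km"])


GOOD = ("sp", 2.5, 2.5, 2000, 1.0)


class TestCleaning:
    def test_high_uncertainty_removed(self):
        df = records([GOOD, ("sp", 3.5, 3.5, 2000, 15.0)])
        out, rep = clean_occurrences(df)
        assert len(out) == 1
        assert rep.removals["high_uncertainty"] == 1

    def test_pre_cutoff_year_removed(self):
        df = records([GOOD, ("sp", 3.5, 3.5, 1975, 1.0)])
        out, rep = clean_occurrences(df)
        assert len(out) == 1
        assert rep.removals["old_year"] == 1

    def test_cutoff_year_kept(self):
        df = records([("sp", 2.5, 2.5, 1979, 1.0)])
        out, _ = clean_occurrences(df)
        assert len(out) == 1

    def test_missing_coordinates_attributed_to_erroneous(self):
        df = records([GOOD, ("sp", np.nan, 2.5, 2000, 1.0)])
        out, rep = clean_occurrences(df)
        assert rep.removals["erroneous"] == 1

    def test_out_of_range_removed(self):
        df = records([GOOD, ("sp", 50.0, 50.0, 2000, 1.0)])
        out, rep = clean_occurrences(df, range_polygon=box(0, 0, 10, 10))
        assert rep.removals["out_of_range"] == 1

    def test_duplicates_keep_first(self):
        df = records([GOOD, GOOD, GOOD])
        out, rep = clean_occurrences(df)
        assert len(out) == 1
        assert rep.removals["duplicate"] == 2

    def test_empty_input(self):
        out, rep = clean_occurrences(records([]))
        assert len(out) == 0
        assert rep.input_count == 0
        assert all(v == 0 for v in rep.removals.values())

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(
        st.sampled_from(["a", "b"]),
        st.one_of(st.floats(-5, 15), st.just(float("nan"))),
        st.floats(-5, 15),
        st.integers(1950, 2023),
        st.floats(0, 30)), max_size=40))
    def test_report_conservation_fuzz(self, rows):
        """input = output + Σ removals on arbitrary inputs."""
        df = records(rows)
        out, rep = clean_occurrences(df, range_polygon=box(0, 0, 10, 10))
        assert rep.input_count == rep.output_count + sum(rep.removals.values())
        assert rep.output_count == len(out)


class TestThinning:
    def test_three_records_one_pixel_collapse(self, small_grid):
        df = records([("sp", 2.1, 2.1, 2000, 1), ("sp", 2.6, 2.2, 2001, 1),
                      ("sp", 2.9, 2.9, 2002, 1)])
        out = thin_to_pixel_centroids(df, small_grid)
        assert len(out) == 1
        assert (out.loc[0, "x"], out.loc[0, "y"]) == (2.5, 2.5)

    def test_distinct_pixels_snapped_not_dropped(self, small_grid):
        df = records([("sp", 1.2, 1.2, 2000, 1), ("sp", 5.7, 5.3, 2000, 1)])
        out = thin_to_pixel_centroids(df, small_grid)
        assert len(out) == 2
        assert set(out["x"] % 1) == {0.5}

    def test_matches_brute_force_bin_count(self, small_grid):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 10, size=(100, 2))
        df = records([("sp", x, y, 2000, 1) for x, y in xy])
        out = thin_to_pixel_centroids(df, small_grid)
        occupied = {(int(x), int(9 - np.floor(y - 1e-12)))
                    for x, y in zip(np.floor(xy[:, 0]), xy[:, 1])}
        # brute-force bin count: distinct (col, row) pairs
        brute = {(int(np.floor(x)), int(np.floor((10 - y))))
                 for x, y in xy}
        assert len(out) == len(brute)

    def test_outside_grid_dropped(self, small_grid):
        df = records([GOOD, ("sp", -3.0, 2.0, 2000, 1)])
        out = thin_to_pixel_centroids(df, small_grid)
        assert len(out) == 1


class TestRarefaction:
    def make_het(self, value, shape=(20, 20)):
        """Uniform heterogeneity raster forcing a single stratum everywhere."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=shape) * 1e-9 + value
        return RasterGrid(base, GridTransform(0.0, shape[0] * 1.0, 1.0))

    def test_close_pair_high_heterogeneity_one_survives(self):
        stack = make_stack(3, shape=(20, 20), seed=5)
        het = heterogeneity_raster(stack)
        # force both records into the same (high) stratum via identical location area
        df = records([("sp", 5.2, 5.2, 2000, 1), ("sp", 5.6, 5.5, 2000, 1)])
        out = rarefy_by_heterogeneity(df, het, distances_km=(1, 3, 5), seed=0)
        assert len(out) == 1  # 0.5 km apart: closer than every stratum distance

    def test_all_far_apart_unchanged(self):
        stack = make_stack(3, shape=(40, 40), seed=6)
        het = heterogeneity_raster(stack)
        df = records([("sp", 2.5, 2.5, 2000, 1), ("sp", 22.5, 2.5, 2000, 1),
                      ("sp", 2.5, 32.5, 2000, 1)])
        out = rarefy_by_heterogeneity(df, het, seed=1)
        assert len(out) == 3

    def test_min_distance_enforced_exhaustively(self):
        """Cluster in a uniform stratum: retained pairwise distances respect
        the stratum rule (verified against the full distance matrix)."""
        stack = make_stack(2, shape=(30, 30), seed=8)
        het = heterogeneity_raster(stack)
        from hurdlemap.occurrences import classify_heterogeneity
        strata, _ = classify_heterogeneity(het)
        rng = np.random.default_rng(2)
        xy = rng.uniform(1, 29, size=(60, 2))
        df = records([("sp", x, y, 2000, 1) for x, y in xy])
        out = rarefy_by_heterogeneity(df, het, distances_km=(1, 3, 5), seed=3)
        s = np.ma.getdata(strata.sample(out["x"], out["y"])).astype(int)
        dists = {0: 1.0, 1: 3.0, 2: 5.0}
        pts = out[["x", "y"]].to_numpy()
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                if s[i] == s[j]:
                    d = np.hypot(*(pts[i] - pts[j]))
                    assert d >= dists[s[i]] - 1e-9

    def test_idempotent(self):
        stack = make_stack(2, shape=(30, 30), seed=9)
        het = heterogeneity_raster(stack)
        rng = np.random.default_rng(4)
        xy = rng.uniform(1, 29, size=(40, 2))
        df = records([("sp", x, y, 2000, 1) for x, y in xy])
        once = rarefy_by_heterogeneity(df, het, seed=7)
        twice = rarefy_by_heterogeneity(once, het, seed=99)
        assert once[["x", "y"]].reset_index(drop=True).equals(
            twice[["x", "y"]].reset_index(drop=True))


class TestCalibrationArea:
    def test_single_cluster_one_hull(self):
        df = records([("sp", 1, 1, 2000, 1), ("sp", 2, 1, 2000, 1),
                      ("sp", 1.5, 2, 2000, 1)])
        area = build_calibration_area(df, hull_km=100.0, buffer_km=1.0)
        assert area.n_clusters == 1
        assert area.polygon.contains(box(1.2, 1.2, 1.4, 1.4))

    def test_two_distant_clusters_disjoint_hulls(self):
        """Single-linkage at the hull distance separates far clusters."""
        near = [("sp", x, y, 2000, 1) for x in (0, 1, 2) for y in (0, 1)]
        far = [("sp", x + 100, y + 100, 2000, 1) for x in (0, 1, 2) for y in (0, 1)]
        area = build_calibration_area(records(near + far), hull_km=10.0,
                                      buffer_km=1.0)
        assert area.n_clusters == 2
        assert area.polygon.geom_type == "MultiPolygon"

    def test_range_polygon_superset_absorbs_hulls(self):
        df = records([("sp", 4, 4, 2000, 1), ("sp", 5, 4, 2000, 1),
                      ("sp", 4, 5, 2000, 1)])
        big = box(-100, -100, 100, 100)
        area = build_calibration_area(df, hull_km=10.0, buffer_km=1.0,
                                      range_polygon=big)
        assert area.polygon.equals(big)

    def test_degenerate_few_points_buffered(self):
        df = records([("sp", 3, 3, 2000, 1)])
        area = build_calibration_area(df, hull_km=10.0, buffer_km=2.0)
        assert area.polygon.contains(box(2.5, 2.5, 3.5, 3.5))
        assert area.notes

    def test_buffer_monotonicity(self):
        rng = np.random.default_rng(5)
        df = records([("sp", x, y, 2000, 1)
                      for x, y in rng.uniform(0, 20, size=(15, 2))])
        a_small = build_calibration_area(df, 50.0, 1.0).polygon.area
        a_big = build_calibration_area(df, 50.0, 5.0).polygon.area
        assert a_big >= a_small


class TestPseudoAbsences:
    def grid9(self):
        return RasterGrid(np.zeros((3, 3)), GridTransform(0.0, 3.0, 1.0))

    def test_small_grid_distinct_cells(self):
        area = build_calibration_area(
            records([("sp", 0.5, 0.5, 2000, 1)]), 10, 5.0)
        pas = sample_pseudo_absences(area, self.grid9(), np.array([0]), n=5,
                                     seed=0)
        assert len(pas) == 5
        assert len(pas[["row", "col"]].drop_duplicates()) == 5

    def test_everything_occupied_errors(self):
        area = build_calibration_area(
            records([("sp", 0.5, 0.5, 2000, 1)]), 10, 5.0)
        with pytest.raises(ValueError, match="deficit"):
            sample_pseudo_absences(area, self.grid9(), np.arange(9), n=1, seed=0)

    def test_never_on_occurrence_cells(self):
        grid = RasterGrid(np.zeros((20, 20)), GridTransform(0.0, 20.0, 1.0))
        occ = records([("sp", x + 0.5, y + 0.5, 2000, 1)
                       for x in range(0, 20, 3) for y in range(0, 20, 3)])
        area = build_calibration_area(occ, 100.0, 30.0)
        pas = sample_pseudo_absences(area, grid, occ, n=300, seed=1)
        occ_cells = set(zip(*grid.coords_to_index(occ["x"], occ["y"])))
        pa_cells = set(zip(pas["row"], pas["col"]))
        assert not (pa_cells & occ_cells)

    def test_uniform_over_eligible_cells(self):
        """Chi-square uniformity not rejected at α=0.01 in ≥95% of seeds."""
        grid = RasterGrid(np.zeros((10, 10)), GridTransform(0.0, 10.0, 1.0))
        area = build_calibration_area(
            records([("sp", 5, 5, 2000, 1)]), 10, 50.0)
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            counts = np.zeros(100)
            for rep in range(25):
                pas = sample_pseudo_absences(area, grid, np.array([], int),
                                             n=40, seed=seed * 1000 + rep)
                counts[pas["row"] * 10 + pas["col"]] += 1
            p = chisquare(counts).pvalue
            ok += p > 0.01
        assert ok >= 0.95 * n_seeds - 1


class TestRasterizeTransects:
    def test_straight_transect_even_pixels(self, small_grid):
        line = LineString([(2.0, 4.5), (5.0, 4.5)])
        out = rasterize_transects([line], [6], small_grid)
        assert len(out) == 3
        assert np.allclose(out["length_km"], 1.0)
        assert out["count"].sum() == 6

    def test_diagonal_lengths_sum_to_total(self, small_grid):
        line = LineString([(0.3, 0.7), (7.9, 8.1)])
        out = rasterize_transects([line], [11], small_grid)
        assert out["length_km"].sum() == pytest.approx(line.length, rel=1e-9)
        assert out["count"].sum() == 11

    def test_outside_grid_empty(self, small_grid):
        line = LineString([(50, 50), (60, 60)])
        out = rasterize_transects([line], [5], small_grid)
        assert len(out) == 0
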