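"""Abundance models: bootstrap averaging, offsets, consistency, fences,
projection policies, and hurdle containment."""

import numpy as np
import pytest
import statsmodels.api as sm

from hurdlemap.abundance import (AbundanceMap, Fences, apply_policy,
                                 consistency, deviance_importance,
                                 fit_abundance, inner_fences,
                                 project_abundance)
from hurdlemap.grid import GridTransform, RasterGrid
from tests.conftest import make_stack


def poisson_data(n=400, beta=(0.5, 1.0, -0.7), seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta) - 1))
    lengths = rng.uniform(0.5, 3.0, size=n)
    mu = np.exp(beta[0] + X @ np.asarray(beta[1:]) + np.log(lengths))
    y = rng.poisson(mu).astype(float)
    return X, y, lengths


class TestFitAbundance:
    def test_poisson_recovers_truth(self):
        X, y, lengths = poisson_data(n=500, seed=1)
        m = fit_abundance(X, y, lengths, ["a", "b"], n_boot=100, seed=0)
        assert m.boot_coef.shape == (100, 3)
        assert np.allclose(m.avg_coef, m.boot_coef.mean(axis=0))
        assert abs(m.avg_coef[0] - 0.5) < 0.15
        assert abs(m.avg_coef[1] - 1.0) < 0.1
        assert abs(m.avg_coef[2] + 0.7) < 0.1

    def test_degenerate_bootstrap_equals_single_fit(self):
        X, y, lengths = poisson_data(seed=2)
        m = fit_abundance(X, y, lengths, ["a", "b"], n_boot=1, seed=0,
                          resample=False)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson(),
                     offset=np.log(lengths)).fit()
        assert np.allclose(m.avg_coef, ref.params, atol=1e-10)

    def test_offset_invariance_under_doubled_lengths(self):
        """Doubling effort (and redrawing counts accordingly) leaves the
        coefficient estimates unchanged in expectation."""
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 1))
            for mult in (1.0, 2.0):
                lengths = np.full(500, mult)
                mu = np.exp(0.4 + 0.8 * X[:, 0] + np.log(lengths))
                y = rng.poisson(mu).astype(float)
                m = fit_abundance(X, y, lengths, ["a"], n_boot=1, seed=0,
                                  resample=False)
                if mult == 1.0:
                    b1 = m.avg_coef.copy()
                else:
                    deltas.append(np.abs(m.avg_coef - b1))
        assert np.mean(deltas) < 0.05

    def test_negbin_theta_estimated(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(600, 1))
        lengths = np.ones(600)
        mu = np.exp(1.0 + 0.6 * X[:, 0])
        theta = 2.0
        y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        m = fit_abundance(X, y, lengths, ["a"], family="negbin", n_boot=20,
                          seed=0)
        assert m.theta == pytest.approx(theta, rel=0.5)
        assert abs(m.avg_coef[1] - 0.6) < 0.15

    def test_gamma_rejects_zeros_with_instruction(self):
        X, y, lengths = poisson_data(seed=4)
        y[0] = 0.0
        with pytest.raises(ValueError, match="drop_zeros"):
            fit_abundance(X, y, lengths, ["a", "b"], family="gamma")

    def test_gamma_drop_zeros_logs_exclusions(self):
        X, y, lengths = poisson_data(seed=5)
        y[y == 0] = 0.0
        n_zero = int((y == 0).sum())
        m = fit_abundance(X, y, lengths, ["a", "b"], family="gamma",
                          n_boot=5, seed=0, drop_zeros=True)
        if n_zero:
            assert any(str(n_zero) in note for note in m.notes)

    def test_all_zero_counts_error(self):
        X = np.zeros((10, 1))
        with pytest.raises(ValueError, match="zero"):
            fit_abundance(X, np.zeros(10), np.ones(10), ["a"])

    def test_gam_bootstrap_coefficients_commensurable(self):
        X, y, lengths = poisson_data(n=300, seed=6)
        m = fit_abundance(X, y, lengths, ["a", "b"], method="GAM", n_boot=10,
                          seed=0)
        assert m.boot_coef.shape[0] == 10
        # averaged-coefficient predictions behave like a real model
        pred = m.predict(X, lengths)
        assert np.corrcoef(pred, y)[0, 1] > 0.5


class TestConsistency:
    def test_identity(self):
        rep = consistency([1, 2, 3, 4], [1, 2, 3, 4])
        assert (rep.r, rep.slope, rep.intercept) == (1.0, 1.0, 0.0)
        assert rep.passes

    def test_scale_bias_visible_in_slope(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        rep = consistency(obs, 2 * obs)
        assert rep.r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(0.5)
        assert rep.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        rep = consistency(y, x)
        slope_o, intercept_o = np.polyfit(x, y, 1)
        assert rep.slope == pytest.approx(slope_o, abs=1e-10)
        assert rep.intercept == pytest.approx(intercept_o, abs=1e-10)
        assert rep.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_constant_predictions_error(self):
        with pytest.raises(ValueError, match="constant"):
            consistency([1, 2, 3], [2, 2, 2])


class TestDevianceImportance:
    def test_single_predictor_equals_full_explained_deviance(self):
        X, y, lengths = poisson_data(n=300, beta=(0.5, 1.0), seed=8)
        imp = deviance_importance(X, y, lengths, ["a"], n_boot=10, seed=0)
        m = fit_abundance(X, y, lengths, ["a"], n_boot=10, seed=0)
        assert imp["a"] == pytest.approx(m.explained_deviance, abs=1e-9)

    def test_signal_beats_noise(self):
        hits, near_zero = 0, 0
        n_seeds = 6
        for seed in range(n_seeds):
            X, y, lengths = poisson_data(n=300, beta=(0.5, 1.0, 0.0),
                                         seed=100 + seed)
            imp = deviance_importance(X, y, lengths, ["sig", "noise"],
                                      n_boot=10, seed=seed)
            hits += imp["sig"] > imp["noise"]
            near_zero += abs(imp["noise"]) < 2.0
        assert hits == n_seeds
        assert near_zero >= n_seeds - 1


class TestProjection:
    def make_stack_and_mask(self, all_zero=False):
        stack = make_stack(2, shape=(20, 20), seed=4)
        vals = np.zeros((20, 20)) if all_zero else \
            (np.ma.getdata(stack["p0"].values) > 0).astype(float)
        mask = RasterGrid(vals, stack.grid.transform)
        return stack, mask

    def intercept_model(self, b0):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 1))
        y = rng.poisson(np.exp(b0), size=50).astype(float)
        return fit_abundance(X, y, np.ones(50), ["p0"], n_boot=1, seed=0,
                             resample=False)

    def test_intercept_only_closed_form(self):
        stack, mask = self.make_stack_and_mask()
        m = self.intercept_model(np.log(2.0))
        m.avg_coef = np.array([np.log(2.0), 0.0])
        amap = project_abundance(m, stack, mask)
        assert np.allclose(amap.raster.values.compressed(), 2.0)

    def test_all_zero_mask_fully_masked(self):
        stack, mask = self.make_stack_and_mask(all_zero=True)
        m = self.intercept_model(0.0)
        amap = project_abundance(m, stack, mask)
        assert amap.raster.values.count() == 0

    def test_hurdle_containment_exhaustive(self):
        stack, mask = self.make_stack_and_mask()
        m = self.intercept_model(0.0)
        amap = project_abundance(m, stack, mask)
        pres = np.ma.getdata(mask.values) > 0
        assert not np.any(~amap.raster.mask & ~pres)


class TestFences:
    def test_constant_values_collapse(self):
        f = inner_fences([3.0] * 10, n_boot=50, seed=0)
        assert f.lower == f.upper == 3.0

    def test_direct_quantile_oracle_on_1_to_9(self):
        """No bootstrap: classic fences from linear-interpolation quartiles."""
        v = np.arange(1.0, 10.0)
        f = inner_fences(v, n_boot=0)
        q1, q3 = np.percentile(v, [25, 75])  # 3.0, 7.0 under linear rule
        assert f.lower == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert f.upper == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        v = rng.lognormal(size=200)
        f1 = inner_fences(v, n_boot=100, seed=4)
        f2 = inner_fences(v, n_boot=100, seed=4)
        assert (f1.lower, f1.upper) == (f2.lower, f2.upper)

    def test_medcouple_variant_widens_upper_on_right_skew(self):
        rng = np.random.default_rng(10)
        v = rng.lognormal(sigma=1.2, size=500)
        classic = inner_fences(v, n_boot=0)
        adjusted = inner_fences(v, n_boot=0, variant="medcouple")
        assert adjusted.upper > classic.upper
        assert adjusted.lower <= adjusted.upper

    def test_too_few_values_error(self):
        with pytest.raises(ValueError):
            inner_fences([1.0, 2.0, 3.0])


class TestPolicies:
    def make_map(self, values):
        vals = np.ma.masked_invalid(np.asarray(values, dtype=float))
        grid = RasterGrid(vals, GridTransform(0.0, vals.shape[0] * 1.0, 1.0))
        return AbundanceMap(grid, "raw")

    def test_clamping_definition(self):
        amap = self.make_map([[1.0, 5.0, 20.0]])
        out = apply_policy(amap, Fences(2.0, 10.0), "extrapolation_and_clamping")
        assert list(np.ma.getdata(out.raster.values)[0]) == [2.0, 5.0, 10.0]

    def test_no_extrapolation_masks(self):
        amap = self.make_map([[1.0, 5.0, 20.0]])
        out = apply_policy(amap, Fences(2.0, 10.0), "no_extrapolation")
        assert list(out.raster.mask[0]) == [True, False, True]
        assert out.raster.values[0, 1] == 5.0

    def test_within_fences_untouched_by_both(self):
        amap = self.make_map([[3.0, 5.0, 9.0]])
        for policy in ("no_extrapolation", "extrapolation_and_clamping"):
            out = apply_policy(amap, Fences(2.0, 10.0), policy)
            assert np.allclose(np.ma.getdata(out.raster.values),
                               np.ma.getdata(amap.raster.values))

    def test_bookkeeping_identity(self):
        """no-extrapolation cell count = input count − out-of-fence count;
        clamped output always passes the fence check."""
        rng = np.random.default_rng(11)
        vals = rng.lognormal(size=(15, 15))
        amap = self.make_map(vals)
        fences = Fences(0.5, 3.0)
        out_of = int(((vals < 0.5) | (vals > 3.0)).sum())
        masked = apply_policy(amap, fences, "no_extrapolation")
        assert masked.raster.values.count() == vals.size - out_of
        clamped = apply_policy(amap, fences, "extrapolation_and_clamping")
        cv = clamped.raster.values.compressed()
        assert cv.min() >= 0.5 and cv.max() <= 3.0
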