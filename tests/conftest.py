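"""Shared fixtures: small synthetic grids, stacks, and datasets."""

import numpy as np
import pytest

from hurdlemap.grid import GridTransform, PredictorStack, RasterGrid
from hurdlemap.synth import (PredictorSpec, ScenarioConfig, default_scenario,
                             generate_dataset, generate_predictor_stack)


@pytest.fixture
def small_grid() -> RasterGrid:
    """10×10 grid, 1-km cells, no masked cells."""
    rng = np.random.default_rng(7)
    return RasterGrid(rng.normal(size=(10, 10)), GridTransform(0.0, 10.0, 1.0))


@pytest.fixture
def masked_grid() -> RasterGrid:
    vals = np.ma.masked_array(np.arange(25, dtype=float).reshape(5, 5))
    vals[1, 2] = np.ma.masked
    vals[4, 4] = np.ma.masked
    return RasterGrid(vals, GridTransform(0.0, 5.0, 1.0))


def make_stack(n_layers=4, shape=(60, 60), seed=0, correlations=None,
               types=None) -> PredictorStack:
    from hurdlemap.grid import PREDICTOR_TYPES
    types = types or [PREDICTOR_TYPES[i % 7] for i in range(n_layers)]
    cfg = ScenarioConfig(
        shape=shape,
        predictors=[PredictorSpec(f"p{i}", types[i]) for i in range(n_layers)],
        correlations=correlations or {},
        seed=seed)
    return generate_predictor_stack(cfg)


@pytest.fixture
def stack4() -> PredictorStack:
    return make_stack(4)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 60×60 two-species scenario shared across tests (read-only)."""
    cfg = default_scenario(seed=11, shape=(60, 60), n_occurrences=80,
                          n_transects=12)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by pipeline-level tests."""
    from hurdlemap.config import RunConfig
    from hurdlemap.pipeline import run_pipeline
    cfg = RunConfig(grid_shape=(60, 60), n_occurrences=90, n_transects=12,
                    n_pseudo_absences=800, n_boot_fit=10, n_boot_fence=10,
                    seed=5)
    outdir = tmp_path_factory.mktemp("run")
    report = run_pipeline(cfg, outdir)
    return cfg, outdir, report
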