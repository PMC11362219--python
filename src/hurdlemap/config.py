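"""Run configuration: every analysis knob in one validated, serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters of a full two-species hurdle-modeling run.

    Defaults are the protocol's standard values: cleaning at 1979 / 10 km,
    800-km hulls buffered 40 km, 10,000 pseudo-absences, |r| > 0.7 pruning,
    5-fold 80/20 Monte-Carlo CV gated at AUC > 0.7 and TSS > 0.4, 1000 fit
    bootstraps and 100 fence bootstraps, ~10% raster sampling for the
    abundance–suitability correlation.
    """

    # scenario / inputs
    input_dir: str | None = None            # read a simulated dataset; None = simulate
    grid_shape: tuple[int, int] = (200, 200)
    n_occurrences: int = 400
    n_transects: int = 44

    # cleaning & thinning
    min_year: int = 1979
    max_uncertainty_km: float = 10.0
    rarefy_distances_km: tuple[float, float, float] = (1.0, 3.0, 5.0)

    # calibration area & background
    hull_km: float = 800.0
    buffer_km: float = 40.0
    n_pseudo_absences: int = 10_000

    # predictor sets
    r_threshold: float = 0.7
    correlation_sample_cells: int = 1_000_000

    # suitability models
    cv_folds: int = 5
    calib_frac: float = 0.8
    auc_min: float = 0.7
    tss_min: float = 0.4
    gam_k: int = 4

    # abundance models
    abundance_family: str = "poisson"
    n_boot_fit: int = 1000
    n_boot_fence: int = 100
    consistency_r_min: float = 0.7
    fence_variant: str = "classic"
    extrapolation_policy: str = "extrapolation_and_clamping"

    # relationship
    correlation_sample_frac: float = 0.10

    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_pseudo_absences > 0, "pseudo-absence count must be positive"),
            (0 < self.r_threshold <= 1, "correlation threshold must be in (0, 1]"),
            (0 < self.calib_frac < 1, "calibration fraction must be in (0, 1)"),
            (self.cv_folds >= 2, "need at least 2 CV splits"),
            (0 <= self.auc_min <= 1, "AUC minimum must be in [0, 1]"),
            (-1 <= self.tss_min <= 1, "TSS minimum must be in [-1, 1]"),
            (self.n_boot_fit >= 1 and self.n_boot_fence >= 0,
             "bootstrap counts must be non-negative (fit >= 1)"),
            (self.max_uncertainty_km >= 0, "uncertainty threshold must be >= 0"),
            (self.hull_km > 0 and self.buffer_km >= 0,
             "hull distance must be positive, buffer non-negative"),
            (0 < self.correlation_sample_frac <= 1,
             "correlation sample fraction must be in (0, 1]"),
            (self.extrapolation_policy in ("no_extrapolation",
                                           "extrapolation_and_clamping"),
             "unknown extrapolation policy"),
            (self.abundance_family in ("poisson", "negbin", "gamma"),
             "unknown abundance family"),
            (self.fence_variant in ("classic", "medcouple"),
             "unknown fence variant"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["rarefy_distances_km"] = list(self.rarefy_distances_km)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "rarefy_distances_km" in d:
            d["rarefy_distances_km"] = tuple(d["rarefy_distances_km"])
        return cls(**d)
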