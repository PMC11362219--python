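"""Abundance-stage (hurdle) models on per-pixel transect counts.

Counts per pixel are modeled with a log link and ``log(transect length)`` as
an offset, so coefficients describe individuals per km of survey effort.
Coefficients are estimated by bootstrapping the records and averaging the
per-resample coefficient vectors. Projections are confined to the presence
mask of the distribution stage (the hurdle), then controlled against
extrapolation with bootstrap "inner fences" — Q1 − 1.5·IQR, Q3 + 1.5·IQR by
default, or the medcouple-adjusted skew variant — by either masking
("no extrapolation") or clamping out-of-fence cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.stattools import medcouple

from .gam import GamModel, estimate_nb_theta, fit_gam, make_family, null_deviance
from .grid import PredictorStack, RasterGrid

log = logging.getLogger(__name__)

FAMILIES = ("poisson", "negbin", "gamma")


@dataclass
class FittedAbundanceModel:
    """Bootstrap-averaged count model with an offset contract of log(km)."""

    method: str                    # "GLM" | "GAM"
    family: str
    predictors: list[str]
    boot_coef: pd.DataFrame        # n_boot × p coefficient matrix
    avg_coef: np.ndarray           # column means of boot_coef
    theta: float | None            # averaged dispersion (negbin)
    explained_deviance: float      # % on the original data, averaged coefficients
    n_records: int
    n_boot: int
    n_redraws: int = 0
    gam: GamModel | None = None    # frozen basis/smoothing for GAM predictions
    notes: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray, length_km=1.0) -> np.ndarray:
        """Expected individuals per ``length_km`` of survey effort."""
        X = np.asarray(X, dtype=float)
        offset = np.log(np.broadcast_to(np.asarray(length_km, dtype=float),
                                        (X.shape[0],)))
        if self.method == "GLM":
            eta = self.avg_coef[0] + X @ self.avg_coef[1:] + offset
            return np.exp(np.clip(eta, -35, 35))
        return self.gam.predict(X, offset=offset, coef=self.avg_coef)


def _fit_glm_once(X, y, offset, family, theta):
    if family == "negbin":
        th = 10.0 if theta is None else theta
        for _ in range(3):
            fam = sm.families.NegativeBinomial(alpha=1.0 / th)
            res = sm.GLM(y, sm.add_constant(X, has_constant="add"), family=fam,
                         offset=offset).fit()
            th = estimate_nb_theta(y, res.fittedvalues)
        return np.asarray(res.params), th
    fam = make_family(family)
    res = sm.GLM(y, sm.add_constant(X, has_constant="add"), family=fam,
                 offset=offset).fit()
    return np.asarray(res.params), None


def fit_abundance(X: np.ndarray, counts: np.ndarray, lengths_km: np.ndarray,
                  names: list[str], family: str = "poisson", method: str = "GLM",
                  n_boot: int = 1000, seed=None, theta: float | None = None,
                  resample: bool = True, k: int = 4, select: bool = False,
                  drop_zeros: bool = False) -> FittedAbundanceModel:
    """Bootstrap the records, fit each resample, average the coefficients.

    Resamples that fail to converge (or produce non-finite coefficients) are
    redrawn and counted. ``resample=False`` fits every replicate on the full
    sample, so ``n_boot=1`` reduces exactly to a single ordinary fit. The
    Gamma family refuses zero counts unless ``drop_zeros=True``, which fits
    the strictly positive records and logs the exclusions.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    if method not in ("GLM", "GAM"):
        raise ValueError("method must be GLM or GAM")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_km, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("transect lengths must be positive")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    notes = []
    if family == "gamma":
        zeros = y == 0
        if zeros.any() and not drop_zeros:
            raise ValueError(
                f"gamma family is undefined for {int(zeros.sum())} zero count(s); "
                "pass drop_zeros=True to fit the strictly positive records only")
        if zeros.any():
            notes.append(f"gamma: excluded {int(zeros.sum())} zero-count record(s)")
            X, y, lengths = X[~zeros], y[~zeros], lengths[~zeros]
    if np.all(y == 0):
        raise ValueError("all counts are zero; no abundance signal to fit")
    offset = np.log(lengths)
    n = len(y)
    names = list(names)
    rng = np.random.default_rng(seed)

    # GAM: freeze basis and smoothing parameters on the full data, then pin
    # them across resamples so bootstrap coefficient vectors are commensurable
    gam_ref = None
    theta_ref = theta
    if method == "GAM":
        if family == "negbin" and theta_ref is None:
            pilot = fit_gam(X, y, "poisson", names=names, k=k, select=select,
                            offset=offset)
            theta_ref = estimate_nb_theta(y, pilot.predict(X, offset=offset))
        gam_ref = fit_gam(X, y, family, names=names, k=k, select=select,
                          offset=offset, theta=theta_ref)
    elif family == "negbin" and theta_ref is None:
        _, theta_ref = _fit_glm_once(X, y, offset, "negbin", None)

    coefs, thetas = [], []
    n_redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        try:
            if method == "GLM":
                beta, th = _fit_glm_once(X[idx], y[idx], offset[idx], family,
                                         theta)
                if family == "negbin":
                    thetas.append(th)
            else:
                if family == "negbin":
                    th = (theta if theta is not None else
                          estimate_nb_theta(y[idx], gam_ref.predict(
                              X[idx], offset=offset[idx])))
                    thetas.append(th)
                else:
                    th = theta_ref
                m = fit_gam(X[idx], y[idx], family, names=names, k=k,
                            select=select, offset=offset[idx],
                            alphas=gam_ref.alphas, theta=th)
                beta = m.coef
            if not np.all(np.isfinite(beta)):
                raise RuntimeError("non-finite coefficients")
        except Exception:
            n_redraws += 1
            if n_redraws > 10 * n_boot:
                raise RuntimeError("bootstrap failed to converge repeatedly")
            continue
        coefs.append(beta)
        b += 1
    if n_redraws:
        log.info("bootstrap: %d resample(s) redrawn", n_redraws)
    if method == "GLM":
        columns = ["intercept"] + names
    else:
        columns = [f"c{j}" for j in range(len(coefs[0]))]
    boot = pd.DataFrame(np.vstack(coefs), columns=columns)
    avg = boot.to_numpy().mean(axis=0)
    theta_avg = float(np.mean(thetas)) if thetas else theta_ref

    # explained deviance on the original data with the averaged coefficients
    fam_name = family
    if method == "GLM":
        eta = avg[0] + X @ avg[1:] + offset
        mu = np.exp(np.clip(eta, -35, 35))
    else:
        mu = gam_ref.predict(X, offset=offset, coef=avg)
    fam = make_family(fam_name, theta_avg)
    dev = float(fam.deviance(y, mu))
    ndev = null_deviance(y, fam_name, offset=offset, theta=theta_avg)
    expl = 100.0 * (1.0 - dev / ndev) if ndev > 0 else 0.0
    return FittedAbundanceModel(method, family, names, boot, avg, theta_avg,
                                float(np.clip(expl, 0.0, 100.0)), n, n_boot,
                                n_redraws, gam=gam_ref, notes=notes)


# ---------------------------------------------------------------------------
# observed–predicted consistency
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Agreement between observed (y-axis) and predicted (x-axis) counts."""

    r: float
    slope: float
    intercept: float
    n: int
    passes: bool                  # r > 0.7

    @property
    def reason(self) -> str:
        return "" if self.passes else f"r = {self.r:.3f} <= 0.7"


def consistency(observed, predicted, r_min: float = 0.7) -> ConsistencyReport:
    """Pearson r plus the observed-on-predicted least-squares line."""
    y = np.asarray(observed, dtype=float)
    x = np.asarray(predicted, dtype=float)
    if len(y) < 3:
        raise ValueError("consistency needs at least 3 pairs")
    if np.std(x) == 0:
        raise ValueError("constant predictions: consistency undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
    intercept = float(y.mean() - slope * x.mean())
    return ConsistencyReport(r, slope, intercept, len(y), bool(r > r_min))


def deviance_importance(X: np.ndarray, counts, lengths_km, names: list[str],
                        family: str = "poisson", method: str = "GLM",
                        n_boot: int = 50, seed=None, **fit_kw) -> dict[str, float]:
    """Leave-one-predictor-out loss of mean explained deviance (% points)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    names = list(names)
    full = fit_abundance(X, counts, lengths_km, names, family, method,
                         n_boot=n_boot, seed=seed, **fit_kw)
    out = {}
    for j, name in enumerate(names):
        keep = [i for i in range(len(names)) if i != j]
        if not keep:
            out[name] = full.explained_deviance
            continue
        try:
            red = fit_abundance(X[:, keep], counts, lengths_km,
                                [names[i] for i in keep], family, method,
                                n_boot=n_boot, seed=seed, **fit_kw)
            out[name] = full.explained_deviance - red.explained_deviance
        except Exception:
            out[name] = float("nan")
            log.warning("deviance importance: refit without %r failed", name)
    return out


# ---------------------------------------------------------------------------
# projection, fences, policies
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMap:
    """Predicted individuals per reference km, confined to the presence mask."""

    raster: RasterGrid
    policy: str                   # "raw" | "no_extrapolation" | "extrapolation_and_clamping"
    reference_length_km: float = 1.0


def project_abundance(model: FittedAbundanceModel, stack: PredictorStack,
                      presence_mask: RasterGrid,
                      reference_length_km: float = 1.0) -> AbundanceMap:
    """Project expected abundance into the cells classified as presence.

    All cells outside the presence mask (or masked in the stack) are masked:
    the hurdle containment ``support(abundance) ⊆ presence`` holds by
    construction.
    """
    missing = [p for p in model.predictors if p not in stack.names]
    if missing:
        raise ValueError(f"stack is missing model predictor(s): {missing}")
    if not presence_mask.aligned_with(stack.grid):
        raise ValueError("presence mask is not aligned with the stack")
    pres = (np.ma.getdata(presence_mask.values) > 0) & ~presence_mask.mask
    if not pres.any():
        log.warning("empty presence mask: abundance map is fully masked")
    X, idx = stack.values_matrix(model.predictors)
    mu = model.predict(X, length_km=reference_length_km)
    flat = np.full(pres.size, np.nan)
    flat[idx] = mu
    arr = np.ma.masked_invalid(flat.reshape(pres.shape))
    arr = np.ma.masked_where(~pres, arr)
    return AbundanceMap(stack.grid.like(arr), "raw", reference_length_km)


@dataclass
class Fences:
    """Extrapolation-control bounds from bootstrap quartile fences."""

    lower: float
    upper: float
    variant: str = "classic"
    n_boot: int = 100

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower fence exceeds upper fence")


def inner_fences(values, n_boot: int = 100, seed=None,
                 variant: str = "classic") -> Fences:
    """Mean of per-replicate quartile fences over bootstrap resamples.

    Classic: ``[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`` with linear-interpolation
    quantiles. ``medcouple``: the skew-adjusted boxplot fences
    ``[Q1 − 1.5·e^{aM}·IQR, Q3 + 1.5·e^{bM}·IQR]`` with (a, b) = (−4, 3) for
    medcouple M ≥ 0 and (−3, 4) otherwise. ``n_boot=0`` computes the fences
    directly on the values.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("inner fences need at least 4 finite values")
    if np.all(v == v[0]):
        return Fences(float(v[0]), float(v[0]), variant, n_boot)
    rng = np.random.default_rng(seed)
    reps = max(n_boot, 1)
    lowers = np.empty(reps)
    uppers = np.empty(reps)
    for b in range(reps):
        s = v if n_boot == 0 else rng.choice(v, size=v.size, replace=True)
        q1, q3 = np.percentile(s, [25, 75])
        iqr = q3 - q1
        if variant == "classic":
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        elif variant == "medcouple":
            sub = s if s.size <= 5000 else rng.choice(s, 5000, replace=False)
            mc = float(medcouple(sub))
            a, c = (-4.0, 3.0) if mc >= 0 else (-3.0, 4.0)
            lo = q1 - 1.5 * np.exp(a * mc) * iqr
            hi = q3 + 1.5 * np.exp(c * mc) * iqr
        else:
            raise ValueError(f"unknown fence variant {variant!r}")
        lowers[b], uppers[b] = lo, hi
    return Fences(float(lowers.mean()), float(uppers.mean()), variant, n_boot)


def apply_policy(amap: AbundanceMap, fences: Fences, policy: str) -> AbundanceMap:
    """Constrain projected abundances to the fences.

    ``no_extrapolation`` masks out-of-fence cells; ``extrapolation_and_clamping``
    replaces them with the nearest fence. Within-fence cells are untouched.
    """
    r = amap.raster
    vals = np.ma.getdata(r.values)
    mask = r.mask
    if policy == "no_extrapolation":
        out_of = (~mask) & ((vals < fences.lower) | (vals > fences.upper))
        arr = np.ma.masked_where(mask | out_of, vals)
    elif policy == "extrapolation_and_clamping":
        arr = np.ma.masked_where(mask, np.clip(vals, fences.lower, fences.upper))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    return AbundanceMap(r.like(arr), policy, amap.reference_length_km)
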