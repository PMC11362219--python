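"""Binomial suitability models (SDMs): fitting, evaluation, projection.

Presences and pseudo-absences are pooled (background points unweighted) and
modeled on the logit scale, with GLM (optionally backward-stepwise on AIC) or
GAM (optionally with shrinkage selection). Evaluation uses Monte-Carlo
cross-validation (independent random 80/20 splits), AUC as the rank
statistic, and the TSS-maximizing threshold for binarization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import rankdata

from .gam import GamModel, fit_gam
from .grid import PredictorStack, RasterGrid

log = logging.getLogger(__name__)


@dataclass
class FittedSuitabilityModel:
    """A fitted binomial SDM (GLM or GAM) on a fixed predictor list."""

    method: str                   # "GLM" | "GAM"
    selected: bool                # stepwise (GLM) / shrinkage (GAM) variant
    input_predictors: list[str]
    predictors: list[str]         # retained after selection
    aic: float
    coef: dict[str, float] | None = None        # GLM only
    gam: GamModel | None = None                 # GAM only
    separation_flag: bool = False
    n_train: int = 0
    notes: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray, input_names: list[str]) -> np.ndarray:
        """Occurrence probability for rows of ``X`` (columns = input_names)."""
        cols = [input_names.index(p) for p in self.predictors]
        Xs = np.asarray(X, dtype=float)[:, cols]
        if self.method == "GLM":
            eta = self.coef["intercept"] + Xs @ np.array(
                [self.coef[p] for p in self.predictors])
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return self.gam.predict(Xs)


def _glm_fit_aic(X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, sm.add_constant(X, has_constant="add"),
                     family=sm.families.Binomial()).fit()
    sep = any("separation" in str(w.message).lower() or
              "overflow" in str(w.message).lower() for w in caught)
    return res, sep


def fit_glm_binomial(X: np.ndarray, y: np.ndarray, names: list[str],
                     stepwise: bool = False) -> FittedSuitabilityModel:
    """Logit-link binomial GLM, optionally backward-eliminated on AIC.

    The stepwise variant repeatedly drops the predictor whose removal lowers
    AIC the most, stopping at a local minimum, so AIC(final) ≤ AIC(full).
    Complete separation is flagged, not fatal: the ranking of predictions
    stays usable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both presence and absence classes are required")
    names = list(names)
    current = list(names)
    res, sep = _glm_fit_aic(X, y)
    aic = res.aic
    if stepwise:
        while len(current) > 0:
            best_drop, best_aic = None, aic
            for p in current:
                trial = [q for q in current if q != p]
                cols = [names.index(q) for q in trial]
                r, _ = _glm_fit_aic(X[:, cols] if cols else X[:, :0], y)
                if r.aic < best_aic - 1e-9:
                    best_drop, best_aic, best_res = p, r.aic, r
            if best_drop is None:
                break
            current.remove(best_drop)
            res, aic = best_res, best_aic
    params = np.asarray(res.params)
    coef = {"intercept": float(params[0])}
    coef.update({p: float(b) for p, b in zip(current, params[1:])})
    if sep:
        log.warning("binomial GLM: possible complete separation; "
                    "coefficients unreliable but rankings usable")
    return FittedSuitabilityModel("GLM", stepwise, names, current, float(res.aic),
                                  coef=coef, separation_flag=sep, n_train=len(y))


def fit_gam_binomial(X: np.ndarray, y: np.ndarray, names: list[str],
                     k: int = 4, shrinkage: bool = False,
                     alphas=None) -> FittedSuitabilityModel:
    """Binomial GAM with per-predictor cubic smooths of basis size ``k``.

    With ``shrinkage=True`` the null space of each smooth is penalized too,
    so uninformative smooths shrink toward zero effective degrees of freedom
    (the shrinkage/double-penalty selection approach).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both presence and absence classes are required")
    m = fit_gam(X, y, "binomial", names=list(names), k=k, select=shrinkage,
                alphas=alphas)
    return FittedSuitabilityModel("GAM", shrinkage, list(names), list(names),
                                  m.aic, gam=m, n_train=len(y), notes=m.notes)


@dataclass
class SDMSpec:
    """Recipe for fitting one SDM variant; used by cross-validation."""

    method: str = "GLM"           # "GLM" | "GAM"
    select: bool = False
    k: int = 4

    @property
    def label(self) -> str:
        return self.method + ("_sel" if self.select else "")

    def fit(self, X: np.ndarray, y: np.ndarray, names: list[str],
            alphas=None) -> FittedSuitabilityModel:
        if self.method == "GLM":
            return fit_glm_binomial(X, y, names, stepwise=self.select)
        if self.method == "GAM":
            return fit_gam_binomial(X, y, names, k=self.k, shrinkage=self.select,
                                    alphas=alphas)
        raise ValueError(f"unknown method {self.method!r}")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc(observed, predicted) -> float:
    """AUC as the Mann–Whitney rank statistic, ties counted half."""
    y = np.asarray(observed, dtype=float)
    s = np.asarray(predicted, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    r = rankdata(s)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def tss_max_threshold(observed, predicted) -> tuple[float, float]:
    """Maximize sensitivity + specificity − 1 over an exhaustive threshold scan.

    Candidates are the distinct predicted values and the midpoints between
    consecutive distinct values; presence is predicted when
    ``prediction ≥ threshold`` (inclusive). Ties on TSS resolve to the
    smallest maximizing threshold.
    """
    y = np.asarray(observed, dtype=float)
    s = np.asarray(predicted, dtype=float)
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("TSS needs both classes")
    vals = np.unique(s)
    cand = np.unique(np.concatenate([vals, (vals[:-1] + vals[1:]) / 2.0]))
    best_tss, best_t = -np.inf, cand[0]
    for t in cand:
        pred1 = s >= t
        sens = (pred1 & (y == 1)).sum() / n1
        spec = (~pred1 & (y == 0)).sum() / n0
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-15:
            best_tss, best_t = tss, t
    return float(best_tss), float(best_t)


@dataclass
class EvalMetrics:
    """Cross-validation summary for one SDM variant."""

    auc_folds: list[float]
    tss_folds: list[float]
    auc_mean: float
    tss_mean: float
    threshold: float              # TSS-maximizing threshold (full-data refit)
    passes: bool                  # AUC > 0.7 and TSS > 0.4 on the means
    n_resampled: int = 0


def crossval(spec: SDMSpec, X: np.ndarray, y: np.ndarray, names: list[str],
             folds: int = 5, calib_frac: float = 0.8, seed=None,
             mode: str = "monte_carlo",
             auc_min: float = 0.7, tss_min: float = 0.4) -> EvalMetrics:
    """Evaluate an SDM recipe with ``folds`` random calibration/evaluation splits.

    ``monte_carlo`` (default) draws independent random ``calib_frac`` splits;
    ``kfold`` uses disjoint folds. A split whose evaluation part lacks one of
    the classes is redrawn (logged via ``n_resampled``). The reported
    threshold maximizes TSS on the full-data refit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs, tsss = [], []
    n_resampled = 0
    if mode == "kfold":
        perm = rng.permutation(n)
        parts = np.array_split(perm, folds)
        splits = [(np.setdiff1d(perm, p), p) for p in parts]
    else:
        splits = []
        for _ in range(folds):
            for _attempt in range(100):
                perm = rng.permutation(n)
                cut = int(round(calib_frac * n))
                train, test = perm[:cut], perm[cut:]
                if len(np.unique(y[test])) == 2 and len(np.unique(y[train])) == 2:
                    break
                n_resampled += 1
            splits.append((train, test))
    # fit the full model first; GAM fold refits pin its smoothing parameters
    full = spec.fit(X, y, names)
    alphas = full.gam.alphas if full.gam is not None else None
    for train, test in splits:
        model = spec.fit(X[train], y[train], names, alphas=alphas)
        p = model.predict(X[test], names)
        aucs.append(auc(y[test], p))
        tsss.append(tss_max_threshold(y[test], p)[0])
    _, threshold = tss_max_threshold(y, full.predict(X, names))
    auc_mean = float(np.mean(aucs))
    tss_mean = float(np.mean(tsss))
    return EvalMetrics(aucs, tsss, auc_mean, tss_mean, threshold,
                       bool(auc_mean > auc_min and tss_mean > tss_min),
                       n_resampled)


# ---------------------------------------------------------------------------
# projection and importance
# ---------------------------------------------------------------------------

def project_suitability(model: FittedSuitabilityModel, stack: PredictorStack
                        ) -> RasterGrid:
    """Cell-wise occurrence probability over the stack; masked cells stay masked."""
    missing = [p for p in model.predictors if p not in stack.names]
    if missing:
        raise ValueError(f"stack is missing model predictor(s): {missing}")
    X, idx = stack.values_matrix(model.predictors)
    p = model.predict(X, model.predictors)
    out = np.full(stack.grid.shape[0] * stack.grid.shape[1], np.nan)
    out[idx] = p
    return stack.grid.like(out.reshape(stack.grid.shape))


def binarize(suitability: RasterGrid, threshold: float) -> RasterGrid:
    """Presence mask: 1 where suitability ≥ threshold (inclusive), else 0."""
    vals = np.ma.getdata(suitability.values)
    out = (vals >= threshold).astype(float)
    return suitability.like(np.ma.masked_where(suitability.mask, out))


@dataclass
class VariableImportance:
    """Permutation importance: 1 − mean r(original, permuted predictions)."""

    importance: dict[str, float]
    n_perm: int


def permutation_importance(model: FittedSuitabilityModel, X: np.ndarray,
                           names: list[str], n_perm: int = 100, seed=None
                           ) -> VariableImportance:
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    base = model.predict(X, names)
    out = {}
    for j, name in enumerate(names):
        rs = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            p = model.predict(Xp, names)
            if np.std(p) == 0 or np.std(base) == 0:
                rs.append(1.0)  # zero-variance predictions: defined as unimportant
            else:
                rs.append(np.corrcoef(base, p)[0, 1])
        out[name] = float(1.0 - np.mean(rs))
    return VariableImportance(out, n_perm)
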