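"""Penalized-regression GAM engine.

A small generalized additive model fitted by penalized IRLS. Each predictor
gets a cubic Bernstein (degree-3 B-spline with no interior knots) basis of
``k = 4`` functions — exactly the space of cubic polynomials, the classical
"k = 4 approximates a third-degree polynomial" choice — centered for
identifiability against the intercept. The wiggliness penalty is the squared
second difference of the basis coefficients; with ``select=True`` a scaled
null-space penalty is added to the same smoothing parameter (a
shrinkage-basis construction), so an uninformative smooth can be shrunk to
zero effective degrees of freedom, not just to a line. Per-smooth smoothing
parameters are chosen by coordinate-wise grid search on the deviance-based
GCV score.

Link/variance/deviance algebra is delegated to ``statsmodels`` family
objects; only the penalized solver and basis handling live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.genmod import families

K_DEFAULT = 4
_GCV_GRID = np.logspace(-3.0, 7.0, 11)


def make_family(name: str, theta: float | None = None):
    name = name.lower()
    if name == "binomial":
        return families.Binomial()
    if name == "poisson":
        return families.Poisson()
    if name == "gamma":
        return families.Gamma(link=families.links.Log())
    if name in ("negbin", "negativebinomial", "nb"):
        if theta is None or theta <= 0:
            raise ValueError("negative binomial requires theta > 0")
        return families.NegativeBinomial(alpha=1.0 / theta)
    raise ValueError(f"unknown family {name!r}")


@dataclass
class SmoothSpec:
    """Frozen basis description for one predictor.

    The raw degree-3 Bernstein basis is projected through ``Z`` — the null
    space of the training-sample column-mean constraint — which absorbs the
    sum-to-zero identifiability constraint against the intercept and leaves
    ``k − 1`` full-rank columns.
    """

    name: str
    kind: str                     # "spline" or "linear"
    lo: float
    hi: float
    Z: np.ndarray                 # (k, k-1) constraint projector; (1,) center for linear
    k: int = K_DEFAULT

    def _raw(self, x: np.ndarray) -> np.ndarray:
        degree = 3
        t = np.r_[[self.lo] * (degree + 1), [self.hi] * (degree + 1)]
        return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()

    def basis(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        if self.kind == "linear":
            return (x - self.Z[0]).reshape(-1, 1)
        return self._raw(x) @ self.Z

    @property
    def width(self) -> int:
        return 1 if self.kind == "linear" else self.k - 1


def _build_smooth(name: str, x: np.ndarray, k: int) -> SmoothSpec:
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1.0
    if np.unique(x).size < k + 1:
        # too few distinct values to support the basis: fall back to linear
        return SmoothSpec(name, "linear", lo, hi, np.array([x.mean()]), k)
    spec = SmoothSpec(name, "spline", lo, hi, np.eye(k), k)
    C = spec._raw(np.clip(x, lo, hi)).mean(axis=0, keepdims=True)
    Z = null_space(C)            # (k, k-1)
    return SmoothSpec(name, "spline", lo, hi, Z, k)


def _penalty_blocks(spec: SmoothSpec, shrink: float) -> np.ndarray:
    """Unit-normalized wiggliness (+ optional null-space) penalty for a smooth."""
    if spec.kind == "linear":
        p = np.zeros((1, 1))
        if shrink > 0:
            p[0, 0] = shrink
        return p
    k = spec.k
    D = np.diff(np.eye(k), n=2, axis=0)
    S = spec.Z.T @ (D.T @ D) @ spec.Z
    S = S / np.linalg.norm(S)
    if shrink > 0:
        w, V = np.linalg.eigh(S)
        null = V[:, w < 1e-8]
        if null.shape[1]:
            N = null @ null.T
            S = S + shrink * (N / max(np.linalg.norm(N), 1e-12))
    return S


@dataclass
class GamModel:
    """A fitted additive model; prediction re-uses the frozen bases."""

    smooths: list[SmoothSpec]
    coef: np.ndarray
    alphas: np.ndarray
    family_name: str
    theta: float | None
    edf: np.ndarray              # per-term EDF: [intercept, smooth_1, ...]
    deviance: float
    null_deviance: float
    aic: float
    select: bool
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.smooths]

    @property
    def edf_total(self) -> float:
        return float(self.edf.sum())

    def edf_by_smooth(self) -> dict[str, float]:
        return {s.name: float(e) for s, e in zip(self.smooths, self.edf[1:])}

    def design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = [np.ones((X.shape[0], 1))]
        cols += [s.basis(X[:, j]) for j, s in enumerate(self.smooths)]
        return np.hstack(cols)

    def predict_linear(self, X: np.ndarray, offset=None) -> np.ndarray:
        eta = self.design(X) @ self.coef
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return eta

    def predict(self, X: np.ndarray, offset=None, coef: np.ndarray | None = None
                ) -> np.ndarray:
        """Mean-scale predictions; ``coef`` overrides the fitted coefficients
        (used for bootstrap-averaged coefficient vectors)."""
        beta = self.coef if coef is None else np.asarray(coef, dtype=float)
        eta = self.design(X) @ beta
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        fam = make_family(self.family_name, self.theta)
        return fam.link.inverse(eta)


def _pirls(Xd: np.ndarray, y: np.ndarray, fam, S: np.ndarray, offset: np.ndarray,
           max_iter: int = 60, tol: float = 1e-8):
    """Penalized IRLS; returns (beta, deviance, edf_per_column, converged)."""
    n = len(y)
    mu = fam.starting_mu(y)
    eta = fam.link(mu)
    beta = None
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        gprime = fam.link.deriv(mu)
        var = fam.variance(mu)
        w = 1.0 / (gprime ** 2 * var)
        w = np.clip(w, 1e-10, 1e10)
        z = (eta - offset) + (y - mu) * gprime
        WX = Xd * w[:, None]
        H = Xd.T @ WX + S + 1e-9 * np.eye(Xd.shape[1])
        b = WX.T @ z
        try:
            beta_new = np.linalg.solve(H, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(H, b, rcond=None)[0]
        eta = Xd @ beta_new + offset
        eta = np.clip(eta, -30, 30)
        mu = fam.link.inverse(eta)
        dev_new = float(fam.deviance(y, mu))
        if beta is not None and abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            beta = beta_new
            dev = dev_new
            converged = True
            break
        beta, dev = beta_new, dev_new
    gprime = fam.link.deriv(mu)
    var = fam.variance(mu)
    w = np.clip(1.0 / (gprime ** 2 * var), 1e-10, 1e10)
    WX = Xd * w[:, None]
    H = Xd.T @ WX + S + 1e-9 * np.eye(Xd.shape[1])
    F = np.linalg.solve(H, Xd.T @ WX)
    edf_cols = np.diag(F)
    return beta, dev, edf_cols, converged, mu


def _assemble_penalty(specs, alphas, select: bool, p_total: int,
                      shrink: float = 0.5) -> np.ndarray:
    S = np.zeros((p_total, p_total))
    pos = 1
    for spec, a in zip(specs, alphas):
        blk = _penalty_blocks(spec, shrink if select else 0.0)
        w = blk.shape[0]
        S[pos:pos + w, pos:pos + w] = a * blk
        pos += w
    return S


def fit_gam(X: np.ndarray, y: np.ndarray, family: str = "binomial",
            names: list[str] | None = None, k: int = K_DEFAULT,
            select: bool = False, offset=None, theta: float | None = None,
            alphas: np.ndarray | None = None, gcv_sweeps: int = 2) -> GamModel:
    """Fit an additive model with per-smooth GCV-chosen smoothing parameters.

    ``alphas`` may pin the smoothing parameters (skips the GCV search — used
    to freeze them across bootstrap resamples).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p_in = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p_in)]
    fam = make_family(family, theta)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    specs = [_build_smooth(nm, X[:, j], k) for j, nm in enumerate(names)]
    notes = [f"{s.name}: fitted as linear (too few unique values)"
             for s in specs if s.kind == "linear"]
    cols = [np.ones((n, 1))] + [s.basis(X[:, j]) for j, s in enumerate(specs)]
    widths = [c.shape[1] for c in cols]
    Xd = np.hstack(cols)
    p_total = Xd.shape[1]

    def fit_at(alpha_vec):
        S = _assemble_penalty(specs, alpha_vec, select, p_total)
        return _pirls(Xd, y, fam, S, offset)

    if alphas is None:
        alpha_vec = np.full(len(specs), 1.0)
        best = fit_at(alpha_vec)
        best_gcv = _gcv(best, n)
        for _ in range(gcv_sweeps):
            for j in range(len(specs)):
                for a in _GCV_GRID:
                    trial_vec = alpha_vec.copy()
                    trial_vec[j] = a
                    trial = fit_at(trial_vec)
                    g = _gcv(trial, n)
                    if g < best_gcv - 1e-12:
                        best_gcv = g
                        alpha_vec = trial_vec
                        best = trial
    else:
        alpha_vec = np.asarray(alphas, dtype=float)
        best = fit_at(alpha_vec)
    beta, dev, edf_cols, converged, mu = best

    # per-term EDFs from the column-wise hat diagonal
    edf_terms = []
    pos = 0
    for w in widths:
        edf_terms.append(float(edf_cols[pos:pos + w].sum()))
        pos += w
    edf_terms = np.array(edf_terms)

    mu0 = np.full(n, _null_mu(y, fam, offset))
    null_dev = float(fam.deviance(y, fam.link.inverse(
        np.log(mu0) + offset) if _has_offsetlog(fam) else mu0))
    ll = _loglike(y, mu, fam, theta)
    aic = -2.0 * ll + 2.0 * edf_terms.sum()
    return GamModel(specs, beta, alpha_vec, family, theta, edf_terms, dev,
                    null_dev, aic, select, converged, notes)


def _gcv(fit_result, n: int) -> float:
    _, dev, edf_cols, _, _ = fit_result
    edf = edf_cols.sum()
    denom = max(n - edf, 1.0) ** 2
    return n * dev / denom


def _has_offsetlog(fam) -> bool:
    return isinstance(fam.link, (families.links.Log,)) or isinstance(
        fam, (families.Poisson, families.NegativeBinomial))


def _null_mu(y, fam, offset) -> float:
    """Intercept-only mean; with a log link the offset enters the null model."""
    if _has_offsetlog(fam):
        # closed form for log link: mu_i = exp(b0 + offset_i), b0 = log(Σy/Σe^off)
        return float(y.sum() / np.exp(offset).sum())
    return float(y.mean())


def null_deviance(y, family: str, offset=None, theta: float | None = None) -> float:
    """Deviance of the intercept(+offset)-only model."""
    y = np.asarray(y, dtype=float)
    fam = make_family(family, theta)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)
    if _has_offsetlog(fam):
        b0 = np.log(y.sum() / np.exp(off).sum())
        mu = np.exp(b0 + off)
    else:
        mu = np.full(len(y), y.mean())
    return float(fam.deviance(y, mu))


def _loglike(y, mu, fam, theta) -> float:
    if isinstance(fam, families.NegativeBinomial) and theta is not None:
        return nb_loglik(y, mu, theta)
    try:
        scale = fam.deviance(y, mu) / max(len(y) - 1, 1) \
            if isinstance(fam, families.Gamma) else 1.0
        return float(fam.loglike(y, mu, scale=scale))
    except Exception:  # pragma: no cover - defensive
        return -0.5 * float(fam.deviance(y, mu))


def nb_loglik(y, mu, theta: float) -> float:
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(np.sum(gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
                        + theta * np.log(theta / (theta + mu))
                        + y * np.log(np.maximum(mu, 1e-12) / (theta + mu))))


def estimate_nb_theta(y, mu, bounds=(1e-2, 1e4)) -> float:
    """Profile-ML dispersion given fitted means."""
    res = minimize_scalar(lambda lt: -nb_loglik(y, mu, np.exp(lt)),
                          bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded")
    return float(np.exp(res.x))
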