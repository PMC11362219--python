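"""Predictor-set construction and collinearity pruning.

Thirteen candidate sets are built from the seven predictor categories:
S1–S7 use one category each, S8–S12 gradually combine categories following a
configurable plan, and S13 starts from every layer and is pruned in two
stages (within category, then across the pooled survivors). Pruning is the
pairwise-|r| / highest-VIF loop: while any pair of layers correlates beyond
the threshold, drop the member of the worst pair with the larger variance
inflation factor, then recompute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import PREDICTOR_TYPES, PredictorStack

#: default gradual-combination plan for the multi-category sets S8–S12
DEFAULT_COMBINATION_PLAN: dict[str, tuple[str, ...]] = {
    "S8": ("water", "human"),
    "S9": ("water", "human", "topography"),
    "S10": ("water", "human", "topography", "precipitation", "temperature"),
    "S11": ("water", "human", "topography", "precipitation", "temperature", "dhi"),
    "S12": PREDICTOR_TYPES,
}

VIF_INF = np.inf  # sentinel for perfectly collinear layers


@dataclass
class CorrelationReport:
    """Pearson matrix and VIFs over a random sample of unmasked cells."""

    names: list[str]
    matrix: np.ndarray
    n_cells: int
    constant_layers: list[str] = field(default_factory=list)

    def pair(self, a: str, b: str) -> float:
        return float(self.matrix[self.names.index(a), self.names.index(b)])


@dataclass
class PredictorSet:
    """A named predictor set before and after decorrelation."""

    set_id: str
    input_members: list[str]
    members: list[str]
    pruning_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.members) <= set(self.input_members):
            raise ValueError("pruned members must come from the input members")


def sample_cells(stack: PredictorStack, n_cells: int = 1_000_000, seed=None,
                 names=None) -> np.ndarray:
    """(cells × layers) values over a random sample of jointly unmasked cells.

    The sample size is capped at the number of unmasked cells, so small
    synthetic grids simply use every cell.
    """
    X, _ = stack.values_matrix(names)
    if X.shape[0] > n_cells:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=n_cells, replace=False)]
    return X


def correlation_matrix(stack: PredictorStack, n_cells: int = 1_000_000, seed=None,
                       names=None) -> CorrelationReport:
    """Pairwise Pearson correlations on sampled cells.

    A constant layer has no defined correlation; it is flagged and its
    entries reported as NaN (diagonal stays 1).
    """
    names = list(names) if names is not None else stack.names
    X = sample_cells(stack, n_cells, seed, names)
    sd = X.std(axis=0)
    constant = [n for n, s in zip(names, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    np.fill_diagonal(C, 1.0)
    return CorrelationReport(names, C, X.shape[0], constant)


def vif(X: np.ndarray, names=None) -> dict[str, float]:
    """Variance inflation factors: VIF_j = 1/(1−R²_j) of layer j on the rest.

    Perfect collinearity yields the ``inf`` sentinel.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two layers")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("VIF is undefined for a constant layer")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    out = {}
    for j in range(X.shape[1]):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[names[j]] = VIF_INF if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def decorrelate(stack: PredictorStack, names=None, r_threshold: float = 0.7,
                n_cells: int = 1_000_000, seed=None) -> PredictorSet:
    """Iterative pairwise-|r| / highest-VIF pruning.

    While some pair exceeds ``|r| > r_threshold``: take the pair with the
    largest |r|, compute VIFs of both members within the current subset, and
    drop the one with the larger VIF (ties: drop the lexicographically later
    name). Every drop is logged with the offending pair, its |r|, and both
    VIFs. Constant layers are dropped first (logged) since their correlation
    is undefined.
    """
    names = list(names) if names is not None else stack.names
    X_full = sample_cells(stack, n_cells, seed, names)
    current = list(names)
    idx = {n: i for i, n in enumerate(names)}
    log: list[dict] = []
    for n in list(current):
        if X_full[:, idx[n]].std() == 0:
            current.remove(n)
            log.append({"dropped": n, "reason": "constant layer"})
    while len(current) >= 2:
        X = X_full[:, [idx[n] for n in current]]
        C = np.atleast_2d(np.corrcoef(X, rowvar=False))
        A = np.abs(C)
        np.fill_diagonal(A, 0.0)
        i, j = np.unravel_index(np.argmax(A), A.shape)
        if A[i, j] <= r_threshold:
            break
        a, b = current[i], current[j]
        vifs = vif(X, current)
        va, vb = vifs[a], vifs[b]
        if va > vb:
            drop = a
        elif vb > va:
            drop = b
        else:
            drop = max(a, b)  # deterministic tie-break
        log.append({"dropped": drop, "pair": (a, b), "abs_r": float(A[i, j]),
                    "vif": {a: va, b: vb}})
        current.remove(drop)
    if not current:
        raise ValueError(
            f"decorrelation at |r| <= {r_threshold} removed every layer")
    return PredictorSet("adhoc", list(names), current, log)


def build_sets(stack: PredictorStack, r_threshold: float = 0.7,
               combination_plan: dict[str, tuple[str, ...]] | None = None,
               n_cells: int = 1_000_000, seed=None) -> list[PredictorSet]:
    """The thirteen candidate predictor sets, each independently decorrelated.

    S1–S7 hold single categories in the fixed category order; S8–S12 follow
    the combination plan; S13 starts from all layers and is pruned in two
    stages (per category, then jointly). Empty categories skip their sets
    (logged on the returned objects' ids staying unused).
    """
    plan = dict(combination_plan or DEFAULT_COMBINATION_PLAN)
    groups = stack.by_type()
    sets: list[PredictorSet] = []
    for i, t in enumerate(PREDICTOR_TYPES, start=1):
        if t not in groups:
            continue
        ps = decorrelate(stack, groups[t], r_threshold, n_cells, seed)
        sets.append(PredictorSet(f"S{i}", ps.input_members, ps.members,
                                 ps.pruning_log))
    for sid in ("S8", "S9", "S10", "S11", "S12"):
        members = [n for t in plan.get(sid, ()) for n in groups.get(t, [])]
        if not members:
            continue
        ps = decorrelate(stack, members, r_threshold, n_cells, seed)
        sets.append(PredictorSet(sid, ps.input_members, ps.members, ps.pruning_log))
    # S13: two-stage — within-category pruning, then joint pruning of survivors
    stage1: list[str] = []
    stage1_log: list[dict] = []
    for t in PREDICTOR_TYPES:
        if t not in groups:
            continue
        ps = decorrelate(stack, groups[t], r_threshold, n_cells, seed)
        stage1.extend(ps.members)
        stage1_log.extend({"stage": 1, "type": t, **e} for e in ps.pruning_log)
    if stage1:
        ps = decorrelate(stack, stage1, r_threshold, n_cells, seed)
        all_members = [n for t in PREDICTOR_TYPES for n in groups.get(t, [])]
        sets.append(PredictorSet(
            "S13", all_members, ps.members,
            stage1_log + [{"stage": 2, **e} for e in ps.pruning_log]))
    return sets
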