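"""The Money Metric Index and the leave-one-out trial-specific indices.

Per trial, the normalized money-metric adjustment under a utility u is

    v*_i = 1 - m(x^i, p^i, u) / (p^i . x^i)   in [0, 1),

the fraction by which trial i's budget line must be shifted inward so that
nothing strictly better than the chosen bundle (according to u) remains
affordable.  The aggregate MMI of a dataset is the smallest averaged
sum-of-squares aggregate of the adjustments over a parametric utility
family,

    MMI(D, U) = inf_{u in U} sqrt( (1/n) sum_i v*_i(D, u)^2 ),

reported on the same 0-1 budget-share scale as the Afriat index.  It is
simultaneously an inconsistency score and a parameter-recovery criterion,
since the argmin parameters are the family's best fit to the choices.

The trial-specific index of observation i is the leave-one-out difference
``index(D) - index(D_-i)``: the trial's own contribution to the aggregate
inconsistency.  The same construction applies to the nonparametric Afriat
index and the GARP violation count.

Because v*_i depends on other trials only through the shared parameters,
the heavy part of the leave-one-out MMI is the re-estimation per subset;
it is warm-started from the full-data optimum and from the subset's best
grid cell (the per-trial squared adjustments of every grid cell are kept
from the full-data search, so subset grid objectives are free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .garp import _estar_with_loo, bottleneck_distances, cross_ratio_matrix
from .utility import (
    A_MAX,
    BETA_MAX,
    DA_CARA,
    DA_CRRA,
    RHO_MAX,
    UtilityParams,
    _money_metric_many,
)

__all__ = [
    "MmiResult",
    "TrialIndexSeries",
    "SearchConfig",
    "adjustments",
    "aggregate_mmi",
    "loo_index",
]

_A_MIN = 1e-3


def _default_beta_grid() -> np.ndarray:
    # includes the exact special points -1 (pure elation seeking) and 0
    # (expected utility); positive side log-spaced up to the estimation cap
    return np.concatenate([[-1.0, -0.75, -0.5, -0.25, 0.0], np.geomspace(0.1, BETA_MAX, 16)])


def _default_rho_grid() -> np.ndarray:
    # includes the exact special points 0 (risk neutral) and 1 (log / Cobb-Douglas)
    return np.unique(np.concatenate([[0.0, 1.0], np.geomspace(0.05, RHO_MAX, 19)]))


def _default_a_grid() -> np.ndarray:
    return np.geomspace(_A_MIN, A_MAX, 21)


@dataclass
class SearchConfig:
    """Deterministic grid + Nelder-Mead search over a utility family's box."""

    beta_grid: np.ndarray = field(default_factory=_default_beta_grid)
    curve_grid: np.ndarray | None = None  # rho grid (CRRA) or A grid (CARA)
    n_starts: int = 3          # local refinements launched from the best grid cells
    maxiter: int = 200         # Nelder-Mead iteration cap per start
    loo_maxiter: int = 60      # reduced cap for each leave-one-out re-estimation
    xatol: float = 1e-3
    fatol: float = 1e-9

    @classmethod
    def reduced(cls) -> "SearchConfig":
        """Cheaper settings for population-scale runs."""
        return cls(n_starts=1, maxiter=80, loo_maxiter=40)


@dataclass
class MmiResult:
    """Aggregate MMI (RMS adjustment), best-fitting parameters, adjustments."""

    aggregate_mmi: float
    best_params: UtilityParams
    adjustments: np.ndarray
    # full grid bookkeeping for warm-started leave-one-out re-estimation
    grid_params: list = field(default_factory=list, repr=False)
    grid_sq: np.ndarray | None = field(default=None, repr=False)


@dataclass
class TrialIndexSeries:
    """Per-trial leave-one-out series of an aggregate inconsistency index."""

    index_name: str
    values: np.ndarray


# ---------------------------------------------------------------------------
# Adjustments and the aggregate index
# ---------------------------------------------------------------------------

def adjustments(dataset, params: UtilityParams) -> np.ndarray:
    """Per-trial normalized money-metric adjustments v*_i in [0, 1)."""
    P, X, _ = dataset.arrays()
    return _adjustments_arrays(P, X, params)


def _adjustments_arrays(P: np.ndarray, X: np.ndarray, params: UtilityParams) -> np.ndarray:
    cost = np.einsum("ij,ij->i", P, X)
    m = _money_metric_many(P, X, params)
    v = 1.0 - m / cost
    return np.clip(v, 0.0, np.nextafter(1.0, 0.0))


def _family_box(family: str, search: SearchConfig):
    """(curve grid, theta<->params codec, Nelder-Mead bounds) for a family."""
    if family == DA_CRRA:
        grid = search.curve_grid if search.curve_grid is not None else _default_rho_grid()

        def make(theta):
            return UtilityParams.crra(beta=float(theta[0]), rho=float(theta[1]))

        def theta_of(params):
            return np.array([params.beta, params.rho])

        bounds = [(-1.0, BETA_MAX), (0.0, RHO_MAX)]
    elif family == DA_CARA:
        grid = search.curve_grid if search.curve_grid is not None else _default_a_grid()

        def make(theta):
            return UtilityParams.cara(beta=float(theta[0]), A=float(10.0 ** theta[1]))

        def theta_of(params):
            return np.array([params.beta, np.log10(params.A)])

        bounds = [(-1.0, BETA_MAX), (np.log10(_A_MIN), np.log10(A_MAX))]
    else:
        raise ValueError(f"unknown family {family!r}")
    return grid, make, theta_of, bounds


def aggregate_mmi(dataset, family: str = DA_CRRA, search: SearchConfig | None = None) -> MmiResult:
    """Minimize the RMS money-metric adjustment over a utility family's box.

    A deterministic coarse grid over (beta, rho) — or (beta, A) for the
    CARA robustness family — is refined by bounded Nelder-Mead from the
    best ``search.n_starts`` grid cells (the optimization runs on the mean
    of squares, whose argmin is the same; the reported index is its square
    root).  No stochastic restarts: repeated calls are bit-identical.
    """
    search = search or SearchConfig()
    P, X, _ = dataset.arrays()
    grid, make, theta_of, bounds = _family_box(family, search)

    grid_params: list[UtilityParams] = []
    grid_sq_rows = []
    for beta in search.beta_grid:
        for c in grid:
            p = (
                UtilityParams.crra(beta=float(beta), rho=float(c))
                if family == DA_CRRA
                else UtilityParams.cara(beta=float(beta), A=float(c))
            )
            grid_params.append(p)
            grid_sq_rows.append(_adjustments_arrays(P, X, p) ** 2)
    grid_sq = np.array(grid_sq_rows)
    grid_obj = grid_sq.mean(axis=1)

    def objective(theta) -> float:
        return float((_adjustments_arrays(P, X, make(theta)) ** 2).mean())

    order = np.argsort(grid_obj, kind="stable")
    best_val = float(grid_obj[order[0]])
    best_params = grid_params[order[0]]
    for k in order[: search.n_starts]:
        res = minimize(
            objective,
            theta_of(grid_params[k]),
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": search.maxiter,
                "xatol": search.xatol,
                "fatol": search.fatol,
            },
        )
        if res.fun < best_val:
            best_val = float(res.fun)
            best_params = make(res.x)
    return MmiResult(
        aggregate_mmi=float(np.sqrt(best_val)),
        best_params=best_params,
        adjustments=_adjustments_arrays(P, X, best_params),
        grid_params=grid_params,
        grid_sq=grid_sq,
    )


# ---------------------------------------------------------------------------
# Leave-one-out engine
# ---------------------------------------------------------------------------

def _loo_mmi(dataset, family, search, warm_start, full: MmiResult | None) -> np.ndarray:
    search = search or SearchConfig()
    P, X, _ = dataset.arrays()
    n = len(P)
    if full is None or full.grid_sq is None:
        full = aggregate_mmi(dataset, family=family, search=search)
    _, make, theta_of, bounds = _family_box(family, search)

    grid_sq = full.grid_sq
    grid_sums = grid_sq.sum(axis=1)
    full_sq = full.adjustments**2
    values = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        Pi, Xi = P[keep], X[keep]

        def objective(theta) -> float:
            return float((_adjustments_arrays(Pi, Xi, make(theta)) ** 2).mean())

        # subset objectives of every full-data grid cell come for free
        sub_grid_obj = (grid_sums - grid_sq[:, i]) / (n - 1)
        k = int(np.argmin(sub_grid_obj))
        best = float(sub_grid_obj[k])
        best_at_full = float((full_sq.sum() - full_sq[i]) / (n - 1))
        best = min(best, best_at_full)
        starts = [theta_of(full.grid_params[k])]
        if warm_start:
            starts.append(theta_of(full.best_params))
        if best <= 1e-12:  # subset already rationalizable: 0 is a hard floor
            starts = []
        for theta0 in starts:
            res = minimize(
                objective,
                theta0,
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "maxiter": search.loo_maxiter,
                    "xatol": search.xatol,
                    "fatol": search.fatol,
                },
            )
            best = min(best, float(res.fun))
        values[i] = full.aggregate_mmi - float(np.sqrt(best))
    return values


def loo_index(
    dataset,
    index_fn: str = "mmi",
    family: str = DA_CRRA,
    warm_start: bool = True,
    search: SearchConfig | None = None,
    full_result: MmiResult | None = None,
) -> TrialIndexSeries:
    """Trial-specific inconsistency series ``index(D) - index(D_-i)``.

    ``index_fn`` selects the aggregate index: ``'mmi'`` (parametric; the
    per-subset parameters are re-estimated, warm-started from the full-data
    fit unless ``warm_start=False``), ``'afriat'`` or ``'violations'``
    (nonparametric; exact per subset).  For the nonparametric indices
    removing an observation can only relax the revealed-preference
    relations, so every value is >= 0; the MMI series may contain small
    negative values at consistency-anchoring trials because the
    mean-of-squares denominator shrinks with the subset.
    """
    n = dataset.n
    if n < 3:
        raise ValueError(f"leave-one-out needs at least 3 observations, got {n}")
    if index_fn == "mmi":
        values = _loo_mmi(dataset, family, search, warm_start, full_result)
    elif index_fn == "afriat":
        W = cross_ratio_matrix(dataset)
        e_full, e_loo = _estar_with_loo(W)
        full = max(0.0, 1.0 - min(e_full, 1.0))
        values = full - np.maximum(0.0, 1.0 - np.minimum(e_loo, 1.0))
    elif index_fn == "violations":
        W = cross_ratio_matrix(dataset)
        values = np.empty(n)
        full = _count_from_ratios(W)
        idx = np.arange(n)
        for i in range(n):
            keep = idx != i
            values[i] = full - _count_from_ratios(W[np.ix_(keep, keep)])
    else:
        raise ValueError(f"unknown index_fn {index_fn!r}")
    return TrialIndexSeries(index_name=index_fn, values=values)


def _count_from_ratios(W: np.ndarray) -> int:
    B = bottleneck_distances(W)
    V = (B <= 1.0) & (W.T < 1.0)
    np.fill_diagonal(V, False)
    return int(V.sum())
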