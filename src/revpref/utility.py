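"""Disappointment-aversion utility over 50/50 two-account lotteries.

A bundle (x, y) is a 50/50 lottery between winning x tokens or y tokens.
Its subjective value under the disappointment-aversion (DA) model is

    SV(x, y) = gamma * omega(max(x, y)) + (1 - gamma) * omega(min(x, y)),
    gamma = 1 / (2 + beta),  beta in [-1, inf),

where ``omega`` is the outcome utility: CRRA ``z**(1-rho)/(1-rho)`` (natural
log at rho = 1), or CARA ``1 - exp(-A z)`` as a robustness family.  ``beta``
tilts the 50/50 weights: ``beta > 0`` overweights the worse outcome
(disappointment aversion), ``beta < 0`` the better outcome (elation
seeking); ``beta = 0`` is expected utility, and ``beta = 0, rho = 0`` is
expected value.

Besides point evaluation the module solves the two workhorse problems of
the money-metric machinery on a linear budget line:

* :func:`optimal_bundle` — the SV-argmax on the line (closed-form corner /
  kink / tangency candidates plus a grid-and-refine fallback for the
  non-convex elation-seeking case);
* :func:`money_metric` — the minimal expenditure, at given prices, that
  still affords some bundle at least as good as a target bundle.  Because
  the target itself is always a candidate, the money metric never exceeds
  the cost of the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UtilityParams",
    "DA_CRRA",
    "DA_CARA",
    "EPS_FLOOR",
    "subjective_value",
    "optimal_bundle",
    "money_metric",
]

DA_CRRA = "DA_CRRA"
DA_CARA = "DA_CARA"

#: Token floor at which the outcome utility is evaluated when it is
#: undefined at zero (CRRA with rho >= 1).
EPS_FLOOR = 1e-6

#: Estimation caps: beyond these the implied behavior is indistinguishable
#: from Leontief / corner choices at the task's 0.1-token resolution.
BETA_MAX = 10.0
RHO_MAX = 10.0
A_MAX = 1.0

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden-section ratio


@dataclass(frozen=True)
class UtilityParams:
    """Parameters of a DA utility: family plus (beta, rho) or (beta, A)."""

    family: str
    beta: float
    rho: float | None = None
    A: float | None = None

    def __post_init__(self) -> None:
        if self.family not in (DA_CRRA, DA_CARA):
            raise ValueError(f"unknown family {self.family!r}")
        if self.beta < -1:
            raise ValueError(f"beta must be >= -1, got {self.beta}")
        if self.family == DA_CRRA:
            if self.rho is None or self.A is not None:
                raise ValueError("DA_CRRA takes rho (and no A)")
            if self.rho < 0:
                raise ValueError(f"rho must be >= 0, got {self.rho}")
        else:
            if self.A is None or self.rho is not None:
                raise ValueError("DA_CARA takes A (and no rho)")
            if not self.A > 0:
                raise ValueError(f"A must be > 0, got {self.A}")

    @property
    def gamma(self) -> float:
        """Weight of the better outcome, 1/(2+beta) in (0, 1]."""
        return 1.0 / (2.0 + self.beta)

    @classmethod
    def crra(cls, beta: float, rho: float) -> "UtilityParams":
        return cls(DA_CRRA, beta=beta, rho=rho)

    @classmethod
    def cara(cls, beta: float, A: float) -> "UtilityParams":
        return cls(DA_CARA, beta=beta, A=A)


# ---------------------------------------------------------------------------
# Outcome utility omega and its inverse
# ---------------------------------------------------------------------------

def _omega(z, params: UtilityParams):
    z = np.asarray(z, dtype=float)
    if params.family == DA_CARA:
        return 1.0 - np.exp(-params.A * z)
    rho = params.rho
    if rho == 0.0:
        return z + 0.0
    if rho == 1.0:
        return np.log(np.maximum(z, EPS_FLOOR))
    if rho > 1.0:
        z = np.maximum(z, EPS_FLOOR)
    return z ** (1.0 - rho) / (1.0 - rho)


def _omega_inv(w, params: UtilityParams):
    """Inverse of omega; levels below omega(0) clamp to 0, unreachable -> inf."""
    w = np.asarray(w, dtype=float)
    if params.family == DA_CARA:
        A = params.A
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(w < 1.0, -np.log1p(-np.minimum(w, 1.0 - 1e-300)) / A, np.inf)
        return np.maximum(z, 0.0)
    rho = params.rho
    if rho == 0.0:
        return np.maximum(w, 0.0)
    if rho == 1.0:
        return np.exp(w)
    arg = (1.0 - rho) * w
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        z = np.where(arg > 0.0, np.where(arg > 0.0, arg, 1.0) ** (1.0 / (1.0 - rho)), 0.0)
    if rho > 1.0:
        # range of omega is (-inf, 0): nonnegative levels are unreachable
        z = np.where(arg > 0.0, z, np.inf)
    return z


def _sv_xy(x, y, params: UtilityParams):
    """Vectorized SV over coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g = params.gamma
    return g * _omega(np.maximum(x, y), params) + (1.0 - g) * _omega(np.minimum(x, y), params)


def subjective_value(bundle, params: UtilityParams) -> float:
    """SV of a bundle; symmetric in (x, y) since only max/min enter."""
    return float(_sv_xy(bundle.x, bundle.y, params))


# ---------------------------------------------------------------------------
# Optimal bundle on a budget line
# ---------------------------------------------------------------------------

def _budget_tangency_candidates(budget, params: UtilityParams) -> list[tuple[float, float]]:
    """Interior first-order-condition points on the budget line, if valid."""
    g = params.gamma
    if g >= 1.0:  # beta = -1: only extremes matter
        return []
    px, py, m = budget.price_x, budget.price_y, budget.expenditure
    out = []
    if params.family == DA_CRRA:
        rho = params.rho
        if rho and rho > 0:
            # region x > y, x carries the better-outcome weight gamma
            r = (g * py / ((1.0 - g) * px)) ** (1.0 / rho)
            if r >= 1.0:
                y = m / (px * r + py)
                out.append((r * y, y))
            r2 = (g * px / ((1.0 - g) * py)) ** (1.0 / rho)
            if r2 >= 1.0:
                x = m / (px + py * r2)
                out.append((x, r2 * x))
    else:
        A = params.A
        d = -np.log((1.0 - g) * px / (g * py)) / A
        if d >= 0:
            x = (m + py * d) / (px + py)
            if x - d >= 0:
                out.append((x, x - d))
        d2 = -np.log((1.0 - g) * py / (g * px)) / A
        if d2 >= 0:
            y = (m + px * d2) / (px + py)
            if y - d2 >= 0:
                out.append((y - d2, y))
    return out


def optimal_bundle(budget, params: UtilityParams, step: float = 0.1):
    """SV-maximizing bundle on the budget line, with its SV.

    Exact corner / safe-kink / tangency candidates are screened together
    with a grid argmax refined by golden section, so the result is the
    continuous-line optimum (symmetric ties break toward larger x).
    """
    from .choice_data import Bundle

    px, py, m = budget.price_x, budget.price_y, budget.expenditure
    xint, s = budget.x_intercept, budget.safe_portfolio
    cands: list[tuple[float, float]] = [(xint, 0.0), (0.0, budget.y_intercept), (s, s)]
    cands += _budget_tangency_candidates(budget, params)

    grid = budget.x_grid(step)
    gy = np.maximum(budget.y_at(grid), 0.0)
    vals = _sv_xy(grid, gy, params)
    j = int(np.argmax(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    # golden-section refinement of the grid optimum (deterministic)
    a, b = float(lo), float(hi)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc = _sv_xy(c, max((m - px * c) / py, 0.0), params)
    fd = _sv_xy(d, max((m - px * d) / py, 0.0), params)
    for _ in range(60):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = _sv_xy(c, max((m - px * c) / py, 0.0), params)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = _sv_xy(d, max((m - px * d) / py, 0.0), params)
    xg = 0.5 * (a + b)
    cands.append((xg, max((m - px * xg) / py, 0.0)))

    best_x, best_y, best_v = None, None, -np.inf
    for x, y in cands:
        if x < -1e-12 or y < -1e-12:
            continue
        x, y = max(x, 0.0), max(y, 0.0)
        v = float(_sv_xy(x, y, params))
        # ties (within float noise) break toward the larger x coordinate
        if v > best_v + 1e-12 or (abs(v - best_v) <= 1e-12 and x > best_x):
            best_x, best_y, best_v = x, y, v
    return Bundle(best_x, best_y), best_v


# ---------------------------------------------------------------------------
# Money metric: minimal expenditure attaining a utility level
# ---------------------------------------------------------------------------

def _min_y_for_level(x, u0, params: UtilityParams):
    """Minimal y >= 0 with SV(x, y) >= u0 (inf where unattainable)."""
    x = np.asarray(x, dtype=float)
    u0 = np.asarray(u0, dtype=float)
    g = params.gamma
    wx = _omega(x, params)
    w0 = float(_omega(0.0, params))
    if g >= 1.0:
        # beta = -1: SV depends only on the better coordinate
        return np.where(wx >= u0, 0.0, _omega_inv(u0, params))
    # y above x: the better outcome is y with weight gamma
    req_hi = (u0 - (1.0 - g) * wx) / g
    y_hi = _omega_inv(req_hi, params)
    # y below x: x is the better outcome
    req_lo = (u0 - g * wx) / (1.0 - g)
    y_lo = np.where(req_lo <= w0, 0.0, _omega_inv(req_lo, params))
    return np.where(wx >= u0, y_lo, y_hi)


# relative x positions scanned along the candidate range (dense near the
# axis to resolve steep indifference curves at rho >= 1)
_SCAN_FRACTIONS = np.unique(
    np.concatenate([np.geomspace(1e-4, 0.08, 12), np.linspace(0.0, 1.0, 49)])
)


def _money_metric_many(
    P: np.ndarray,
    targets: np.ndarray,
    params: UtilityParams,
    golden_iters: int = 35,
) -> np.ndarray:
    """Vectorized money metric for rows of prices ``P`` and ``targets``.

    Returns m_i = min { p_i . y : SV(y) >= SV(target_i) } for each row.
    The search combines closed-form candidates (the target itself, the safe
    kink, both axis corners — the minimum can jump there for non-convex
    beta < 0 preferences — and interior tangency points) with a scan over x
    on a geometric+linear grid, each scan point solved exactly for the
    minimal y on the indifference level, followed by golden-section
    refinement around the scan minimum.
    """
    P = np.asarray(P, dtype=float)
    targets = np.asarray(targets, dtype=float)
    px, py = P[:, 0], P[:, 1]
    u0 = _sv_xy(targets[:, 0], targets[:, 1], params)
    cost_target = px * targets[:, 0] + py * targets[:, 1]
    g = params.gamma

    costs = [cost_target]

    # safe kink x = y: SV(z, z) = omega(z)
    z = _omega_inv(u0, params)
    costs.append(np.where(np.isfinite(z), (px + py) * z, np.inf))

    # axis corners (a, 0) and (0, a)
    w0 = float(_omega(0.0, params))
    with np.errstate(invalid="ignore"):
        a = _omega_inv((u0 - (1.0 - g) * w0) / g, params)
    corner_ok = np.isfinite(a)
    costs.append(np.where(corner_ok, px * a, np.inf))
    costs.append(np.where(corner_ok, py * a, np.inf))

    # interior tangency on the indifference level (both orientations)
    if g < 1.0:
        if params.family == DA_CRRA and params.rho and params.rho > 0:
            rho = params.rho
            for hi_is_x in (True, False):
                p_hi, p_lo = (px, py) if hi_is_x else (py, px)
                r = (g * p_lo / ((1.0 - g) * p_hi)) ** (1.0 / rho)
                if rho == 1.0:
                    lo = np.exp(u0 - g * np.log(np.maximum(r, 1.0)))
                else:
                    denom = g * r ** (1.0 - rho) + (1.0 - g)
                    lo = _omega_inv(u0 / denom, params)
                hi = r * lo
                cost = p_hi * hi + p_lo * lo
                valid = (r >= 1.0) & np.isfinite(cost)
                costs.append(np.where(valid, cost, np.inf))
        elif params.family == DA_CARA:
            A = params.A
            for hi_is_x in (True, False):
                p_hi, p_lo = (px, py) if hi_is_x else (py, px)
                d = -np.log((1.0 - g) * p_hi / (g * p_lo)) / A
                with np.errstate(invalid="ignore", divide="ignore"):
                    ratio = (1.0 - u0) / (g * np.exp(-A * d) + (1.0 - g))
                    lo = np.where(ratio > 0, -np.log(np.maximum(ratio, 1e-300)) / A, np.inf)
                lo = np.maximum(lo, 0.0)
                cost = p_hi * (lo + d) + p_lo * lo
                valid = (d >= 0.0) & np.isfinite(cost)
                costs.append(np.where(valid, cost, np.inf))

    # grid scan over x in (0, cost_target / px]: beyond that x alone is too dear
    xmax = cost_target / px
    X = xmax[:, None] * _SCAN_FRACTIONS[None, :]
    Y = _min_y_for_level(X, u0[:, None], params)
    with np.errstate(invalid="ignore"):
        C = px[:, None] * X + py[:, None] * Y
    C = np.where(np.isfinite(C), C, np.inf)
    j = np.argmin(C, axis=1)
    costs.append(C[np.arange(len(j)), j])

    # golden-section refinement around the scan minimum
    nfr = len(_SCAN_FRACTIONS)
    lo_f = _SCAN_FRACTIONS[np.maximum(j - 1, 0)]
    hi_f = _SCAN_FRACTIONS[np.minimum(j + 1, nfr - 1)]
    a_x = xmax * lo_f
    b_x = xmax * hi_f

    def cost_at(x):
        y = _min_y_for_level(x, u0, params)
        c = px * x + py * y
        return np.where(np.isfinite(c), c, np.inf)

    c_x = b_x - _INVPHI * (b_x - a_x)
    d_x = a_x + _INVPHI * (b_x - a_x)
    fc, fd = cost_at(c_x), cost_at(d_x)
    for _ in range(golden_iters):
        take_c = fc < fd
        b_x = np.where(take_c, d_x, b_x)
        a_x = np.where(take_c, a_x, c_x)
        c_x = b_x - _INVPHI * (b_x - a_x)
        d_x = a_x + _INVPHI * (b_x - a_x)
        fc, fd = cost_at(c_x), cost_at(d_x)
    costs.append(np.minimum(fc, fd))

    m = np.min(np.vstack(costs), axis=0)
    if not np.all(np.isfinite(m)):
        raise ArithmeticError("money metric search failed to produce a finite value")
    return m


def money_metric(target, budget, params: UtilityParams) -> float:
    """Minimal expenditure at ``budget``'s prices attaining SV(target).

    Always at most the cost of ``target`` at those prices, since the target
    itself attains its own level.
    """
    P = np.array([[budget.price_x, budget.price_y]])
    T = np.array([[target.x, target.y]])
    return float(_money_metric_many(P, T, params)[0])
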