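"""Revealed-preference relations, GARP testing, and the Afriat index.

For a dataset D = {(p^i, x^i)} the directly-revealed-preferred relation at
efficiency level e in [0, 1] is

    x^i R0(e) x^j   iff   e * (p^i . x^i) >= p^i . x^j        (P0: strict)

and R(e) is the transitive closure of R0(e).  GARP(e) holds when no ordered
pair has x^i R x^j together with x^j P0 x^i.  The Afriat (critical cost
efficiency) index is 1 - e*, where e* is the supremal e at which GARP(e)
still holds; consistent data score 0.

Everything here works on the scale-free ratio matrix

    W[i, j] = (p^i . x^j) / (p^i . x^i),

so all results are invariant to rescaling any trial's prices and
expenditure.  An edge i -> j of R0(e) exists exactly when e >= W[i, j], so
the closure at every level is encoded by the bottleneck (minimax-path)
distances of W, which yields the Afriat index exactly in one O(n^3) pass —
no efficiency grid.  A bisection-over-closure route is kept as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RelationMatrices",
    "GarpReport",
    "relations",
    "count_violations",
    "afriat_index",
    "cross_ratio_matrix",
    "bottleneck_distances",
]

try:  # numba accelerates the O(n^3) inner loops; numpy fallback is exact too
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class RelationMatrices:
    """Boolean revealed-preference relations at one efficiency level."""

    R0: np.ndarray
    P0: np.ndarray
    R: np.ndarray
    e_level: float


@dataclass
class GarpReport:
    """Outcome of a GARP test: violating ordered pairs at one level."""

    n_violations: int
    violating_pairs: np.ndarray  # (k, 2) array of ordered (i, j)
    satisfied: bool
    e_level: float


# ---------------------------------------------------------------------------
# Ratio matrix and bottleneck distances
# ---------------------------------------------------------------------------

def cross_ratio_matrix(dataset) -> np.ndarray:
    """W[i, j] = (p^i . x^j) / (p^i . x^i): scale-free cross-expenditures."""
    P, X, _ = dataset.arrays()
    E = P @ X.T
    own = np.diag(E).copy()
    if np.any(own <= 0):
        raise ValueError("each observation must have positive expenditure on its choice")
    return E / own[:, None]


def _bottleneck_numpy(W: np.ndarray) -> np.ndarray:
    B = W.copy()
    for k in range(len(B)):
        np.minimum(B, np.maximum.outer(B[:, k], B[k, :]), out=B)
    return B


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _bottleneck_numba(W):  # pragma: no cover - exercised via wrapper
        n = W.shape[0]
        B = W.copy()
        for k in range(n):
            for i in range(n):
                bik = B[i, k]
                for j in range(n):
                    m = bik if bik > B[k, j] else B[k, j]
                    if m < B[i, j]:
                        B[i, j] = m
        return B

    @numba.njit(cache=True)
    def _loo_estar_numba(W):  # pragma: no cover - exercised via wrapper
        """Critical efficiency e* for the full data and each leave-one-out."""
        n = W.shape[0]
        out = np.empty(n + 1)
        sub = np.empty((n - 1, n - 1))
        for drop in range(-1, n):
            if drop < 0:
                m = n
                B = W.copy()
                Wv = W
            else:
                m = n - 1
                r = 0
                for i in range(n):
                    if i == drop:
                        continue
                    c = 0
                    for j in range(n):
                        if j == drop:
                            continue
                        sub[r, c] = W[i, j]
                        c += 1
                    r += 1
                B = sub[:m, :m].copy()
                Wv = sub
            for k in range(m):
                for i in range(m):
                    bik = B[i, k]
                    for j in range(m):
                        t = bik if bik > B[k, j] else B[k, j]
                        if t < B[i, j]:
                            B[i, j] = t
            best = np.inf
            for i in range(m):
                for j in range(m):
                    if i == j:
                        continue
                    t = B[i, j] if B[i, j] > Wv[j, i] else Wv[j, i]
                    if t < best:
                        best = t
            out[drop + 1] = best
        return out


def bottleneck_distances(W: np.ndarray) -> np.ndarray:
    """Minimax edge weight over directed paths (length >= 1) of W."""
    if _HAVE_NUMBA:
        return _bottleneck_numba(np.ascontiguousarray(W, dtype=np.float64))
    return _bottleneck_numpy(np.asarray(W, dtype=np.float64))


def _critical_e(W: np.ndarray, B: np.ndarray | None = None) -> float:
    """Supremal e at which GARP(e) holds, from the ratio matrix.

    A violation (x^i R x^j and x^j P0 x^i) first appears, as e grows, at
    max(B[i, j], W[j, i]); e* is the minimum of that over ordered pairs.
    """
    if B is None:
        B = bottleneck_distances(W)
    T = np.maximum(B, W.T)
    np.fill_diagonal(T, np.inf)
    return float(T.min())


def _estar_with_loo(W: np.ndarray) -> tuple[float, np.ndarray]:
    """e* of the full dataset and of each leave-one-out subset."""
    n = len(W)
    if _HAVE_NUMBA:
        out = _loo_estar_numba(np.ascontiguousarray(W, dtype=np.float64))
        return float(out[0]), out[1:]
    full = _critical_e(W)
    loo = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        loo[i] = _critical_e(W[np.ix_(keep, keep)])
    return full, loo


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def relations(dataset, e: float = 1.0) -> RelationMatrices:
    """R0, P0 and the transitive closure R at efficiency level ``e``."""
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"efficiency level must lie in [0, 1], got {e}")
    W = cross_ratio_matrix(dataset)
    R0 = W <= e
    P0 = W < e
    R = bottleneck_distances(W) <= e
    return RelationMatrices(R0=R0, P0=P0, R=R, e_level=e)


def count_violations(dataset, e: float = 1.0) -> GarpReport:
    """Count ordered pairs (i, j), i != j, with x^i R x^j and x^j P0 x^i."""
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"efficiency level must lie in [0, 1], got {e}")
    W = cross_ratio_matrix(dataset)
    B = bottleneck_distances(W)
    V = (B <= e) & (W.T < e)
    np.fill_diagonal(V, False)
    pairs = np.argwhere(V)
    return GarpReport(
        n_violations=int(V.sum()),
        violating_pairs=pairs,
        satisfied=not V.any(),
        e_level=e,
    )


def afriat_index(dataset, tol: float = 1e-4, method: str = "exact") -> float:
    """Afriat critical-cost-efficiency index, 1 - e*, in [0, 1].

    ``method='exact'`` (default) computes e* in closed form from the
    bottleneck distances; ``method='bisection'`` brackets e* on [0, 1] by
    testing GARP(e) with a boolean transitive closure, to tolerance ``tol``
    (the two agree to within ``tol``).
    """
    W = cross_ratio_matrix(dataset)
    if method == "exact":
        return max(0.0, 1.0 - min(_critical_e(W), 1.0))
    if method != "bisection":
        raise ValueError(f"unknown method {method!r}")

    def satisfied(e: float) -> bool:
        R0 = W <= e
        R = _boolean_closure(R0)
        V = R & (W.T < e)
        np.fill_diagonal(V, False)
        return not V.any()

    if satisfied(1.0):
        return 0.0
    lo, hi = 0.0, 1.0  # satisfied at 0 (nothing is affordable), violated at 1
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if satisfied(mid):
            lo = mid
        else:
            hi = mid
    return 1.0 - 0.5 * (lo + hi)


def _boolean_closure(R0: np.ndarray) -> np.ndarray:
    """Transitive closure (paths of length >= 1) by repeated squaring."""
    R = R0.astype(np.float64)
    n = len(R)
    steps = max(1, int(np.ceil(np.log2(max(n, 2)))))
    for _ in range(steps):
        R = np.minimum(R + R @ R, 1.0)
    return R > 0
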