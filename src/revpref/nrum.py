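"""Neural random utility simulation and the noise-inconsistency diagnostic.

The random-utility model of choice on a budget line: each candidate bundle
i on the discretized line carries a valuation v_i (its subjective value
under the subject's utility) plus an independent random term e_i drawn from
a *skewed* distribution,

    v~_i = v_i + e_i,

and the bundle with the largest v~ is chosen.  Inconsistent choices — picks
of low-valuation bundles — then require unusually large noise draws, so if
a neural signal tracks v~, it should be *higher* on more severely
inconsistent trials.  The module provides:

* the two skewed noise families used as examples (zero-mode Gumbel and
  mean-centred log-normal);
* dataset simulation under the model and calibration of the noise scale so
  the simulated mean Afriat index matches an observed level;
* the pooled correlation diagnostic between the chosen bundle's noise draw
  and the trial-specific (leave-one-out) Afriat index across many simulated
  sessions;
* small Monte-Carlo demonstrations of the conditional choice-probability /
  conditional-mean-utility logic with 2 and 6 discrete alternatives under
  multiplicative log-normal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .choice_data import Bundle, ChoiceDataset, Observation
from .garp import _critical_e, _estar_with_loo
from .utility import UtilityParams, _sv_xy

__all__ = [
    "NoiseSpec",
    "NRUMRun",
    "DemoAlternative",
    "CalibrationError",
    "nrum_choice",
    "simulate_dataset",
    "calibrate_noise",
    "assess",
    "conditional_utility_demo",
]

NOISE_FAMILIES = ("gumbel_zero_mode", "lognormal_zero_mean")


class CalibrationError(RuntimeError):
    """Noise calibration could not reach the target inconsistency level."""


@dataclass(frozen=True)
class NoiseSpec:
    """A skewed zero-centred noise family with one dispersion parameter.

    ``gumbel_zero_mode``: Gumbel with location 0 (mode at 0) and the given
    scale.  ``lognormal_zero_mean``: log-normal with log-mean 0 and log-sd
    equal to ``scale``, shifted by -exp(scale^2 / 2) so the mean is 0.
    Both are right-skewed at every scale.
    """

    family: str
    scale: float

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.family == "gumbel_zero_mode":
            return rng.gumbel(0.0, self.scale, size)
        return rng.lognormal(0.0, self.scale, size) - math.exp(self.scale**2 / 2.0)

    def from_standard(self, z: np.ndarray) -> np.ndarray:
        """Map standard draws to this spec (common random numbers across scales).

        ``z`` is standard Gumbel(0, 1) for the Gumbel family and standard
        normal for the log-normal family.
        """
        if self.family == "gumbel_zero_mode":
            return self.scale * z
        return np.exp(self.scale * z) - math.exp(self.scale**2 / 2.0)

    @staticmethod
    def standard_draws(family: str, rng: np.random.Generator, size) -> np.ndarray:
        if family == "gumbel_zero_mode":
            return rng.gumbel(0.0, 1.0, size)
        return rng.standard_normal(size)


# ---------------------------------------------------------------------------
# Line precomputation and simulation
# ---------------------------------------------------------------------------

class _LineGrid:
    """Padded per-trial grids of bundles and their valuations."""

    def __init__(self, budgets, params: UtilityParams, step: float = 0.1):
        self.budgets = list(budgets)
        xs, ys, vs = [], [], []
        for b in self.budgets:
            gx = b.x_grid(step)
            gy = np.maximum(b.y_at(gx), 0.0)
            xs.append(gx)
            ys.append(gy)
            vs.append(_sv_xy(gx, gy, params))
        n = len(self.budgets)
        L = max(len(g) for g in xs)
        self.X = np.zeros((n, L))
        self.Y = np.zeros((n, L))
        self.V = np.full((n, L), -np.inf)
        for i, (gx, gy, gv) in enumerate(zip(xs, ys, vs)):
            self.X[i, : len(gx)] = gx
            self.Y[i, : len(gx)] = gy
            self.V[i, : len(gx)] = gv
        self.lengths = np.array([len(g) for g in xs])
        self.mask = np.arange(L)[None, :] < self.lengths[:, None]

    def choices_for_noise(self, E: np.ndarray):
        """Argmax of V + E per trial; returns (x, y, chosen noise) arrays."""
        U = np.where(self.mask, self.V + E, -np.inf)
        j = np.argmax(U, axis=1)
        rows = np.arange(len(j))
        return self.X[rows, j], self.Y[rows, j], E[rows, j]


def nrum_choice(budget, params: UtilityParams, noise: NoiseSpec, seed):
    """Single-trial random-utility choice; returns (Bundle, chosen noise)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    gx = budget.x_grid()
    gy = np.maximum(budget.y_at(gx), 0.0)
    v = _sv_xy(gx, gy, params)
    e = noise.sample(rng, v.shape)
    j = int(np.argmax(v + e))
    return Bundle(float(gx[j]), float(gy[j])), float(e[j])


def simulate_dataset(budgets, params: UtilityParams, noise: NoiseSpec, seed):
    """Simulate one session: a noisy-argmax choice on every budget line.

    Returns the simulated :class:`ChoiceDataset` and the per-trial noise
    draw of the chosen bundle (the model's analogue of the valuation signal
    on that trial).
    """
    grid = _LineGrid(budgets, params)
    rng = np.random.Generator(np.random.PCG64(_as_ss(seed)))
    E = noise.sample(rng, grid.V.shape)
    x, y, e = grid.choices_for_noise(E)
    obs = [Observation(b, Bundle(float(xi), float(yi))) for b, xi, yi in zip(budgets, x, y)]
    return ChoiceDataset(obs), e


def _as_ss(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def _ratio_matrix_from(P: np.ndarray, X: np.ndarray) -> np.ndarray:
    E = P @ X.T
    own = np.diag(E).copy()
    return E / own[:, None]


def _afriat_full_and_loo(P: np.ndarray, X: np.ndarray):
    e_full, e_loo = _estar_with_loo(_ratio_matrix_from(P, X))
    a_full = max(0.0, 1.0 - min(e_full, 1.0))
    return a_full, a_full - np.maximum(0.0, 1.0 - np.minimum(e_loo, 1.0))


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_noise(
    budgets,
    params: UtilityParams,
    target_afriat: float,
    noise_family: str = "gumbel_zero_mode",
    reps: int = 50,
    seed=0,
    rel_tol: float = 0.1,
    max_doublings: int = 40,
    max_bisections: int = 60,
    full_output: bool = False,
):
    """Choose the noise scale whose simulated mean Afriat index hits a target.

    The mean (over repeated simulated sessions) of the Afriat index is
    nondecreasing in the noise scale; the scale is bisected until the mean
    is within ``rel_tol`` (relative) of ``target_afriat``.  Each stage
    reuses one set of standard noise draws across scale evaluations
    (common random numbers), which keeps the bracketing monotone and
    stable; bisection runs at ``reps`` sessions per evaluation and the
    accepted scale is then polished against a fresh set of ``4 * reps``
    sessions to shrink the Monte-Carlo slop of the stopping rule.

    With ``full_output=True`` returns ``(NoiseSpec, info)`` where ``info``
    carries the achieved mean Afriat level and the evaluation sizes.
    """
    if not 0.0 < target_afriat < 0.5:
        raise ValueError(f"target_afriat must lie in (0, 0.5), got {target_afriat}")
    if reps < 10:
        raise ValueError(f"reps must be >= 10, got {reps}")
    grid = _LineGrid(budgets, params)
    P = np.array([[b.price_x, b.price_y] for b in grid.budgets])
    rng = np.random.Generator(np.random.PCG64(_as_ss(seed)))

    def make_evaluator(n_reps: int):
        Z = NoiseSpec.standard_draws(noise_family, rng, (n_reps,) + grid.V.shape)

        def mean_afriat(scale: float) -> float:
            spec = NoiseSpec(noise_family, scale)
            total = 0.0
            for r in range(n_reps):
                x, y, _ = grid.choices_for_noise(spec.from_standard(Z[r]))
                W = _ratio_matrix_from(P, np.column_stack([x, y]))
                total += max(0.0, 1.0 - min(_critical_e(W), 1.0))
            return total / n_reps

        return mean_afriat

    # stage 1: bracket and bisect at `reps` sessions per evaluation
    f1 = make_evaluator(reps)
    v_span = float(
        np.nanmax(np.where(grid.mask, grid.V, np.nan))
        - np.nanmin(np.where(grid.mask, grid.V, np.nan))
    )
    hi = max(v_span, 1e-6) * 0.01
    f_hi = f1(hi)
    n_doubles = 0
    while f_hi < target_afriat:
        hi *= 2.0
        n_doubles += 1
        if n_doubles > max_doublings:
            raise CalibrationError(
                f"target {target_afriat} unattainable: mean Afriat {f_hi:.4f} "
                f"at scale {hi:.3g}"
            )
        f_hi = f1(hi)
    lo = 0.0
    scale, f_mid = hi, f_hi
    for _ in range(max_bisections):
        if abs(f_mid - target_afriat) <= rel_tol * target_afriat and scale > 0:
            break
        mid = 0.5 * (lo + hi)
        f_mid = f1(mid)
        scale = mid
        if f_mid < target_afriat:
            lo = mid
        else:
            hi = mid
    else:
        raise CalibrationError(
            f"calibration did not converge: bracket [{lo:.3g}, {hi:.3g}] "
            f"around mean Afriat {f_mid:.4f}, target {target_afriat}"
        )

    # stage 2: polish against a fresh, larger common-random-number set
    f2 = make_evaluator(4 * reps)
    achieved = f2(scale)
    lo2, hi2 = max(lo, 0.5 * scale), max(hi, 1.5 * scale)
    for _ in range(12):
        if abs(achieved - target_afriat) <= rel_tol * target_afriat:
            break
        if achieved < target_afriat:
            lo2 = scale
        else:
            hi2 = scale
        scale = 0.5 * (lo2 + hi2)
        achieved = f2(scale)
    spec = NoiseSpec(noise_family, scale)
    if full_output:
        return spec, {"achieved_mean_afriat": achieved, "reps": reps, "polish_reps": 4 * reps}
    return spec


# ---------------------------------------------------------------------------
# The pooled diagnostic
# ---------------------------------------------------------------------------

@dataclass
class NRUMRun:
    """Pooled noise-vs-inconsistency diagnostic over simulated sessions."""

    n_reps: int
    budgets: list
    params: UtilityParams
    noise: NoiseSpec
    choices: np.ndarray        # (n_reps, n_trials, 2)
    chosen_noise: np.ndarray   # (n_reps, n_trials)
    trial_afriat: np.ndarray   # (n_reps, n_trials) leave-one-out Afriat values
    pooled_r: float
    pooled_p: float
    degenerate: bool = False   # True when a pooled series had zero variance

    @property
    def datasets(self) -> list:
        """The simulated sessions materialized as ChoiceDataset objects."""
        out = []
        for r in range(self.n_reps):
            obs = [
                Observation(b, Bundle(float(x), float(y)))
                for b, (x, y) in zip(self.budgets, self.choices[r])
            ]
            out.append(ChoiceDataset(obs, subject_id=f"sim{r}"))
        return out


def assess(budgets, params: UtilityParams, noise: NoiseSpec, n_reps: int = 1000, seed=0) -> NRUMRun:
    """Simulate ``n_reps`` sessions and correlate noise with inconsistency.

    Per session the chosen bundle's noise draw and the trial-specific
    (leave-one-out) Afriat index are recorded per trial; both series are
    pooled across trials and sessions and their Pearson correlation is the
    model's diagnostic: under skewed noise it should be positive.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    grid = _LineGrid(budgets, params)
    n = len(grid.budgets)
    P = np.array([[b.price_x, b.price_y] for b in grid.budgets])
    rng = np.random.Generator(np.random.PCG64(_as_ss(seed)))
    choices = np.empty((n_reps, n, 2))
    chosen_noise = np.empty((n_reps, n))
    trial_afriat = np.empty((n_reps, n))
    for r in range(n_reps):
        E = noise.sample(rng, grid.V.shape)
        x, y, e = grid.choices_for_noise(E)
        choices[r, :, 0], choices[r, :, 1] = x, y
        chosen_noise[r] = e
        _, trial_afriat[r] = _afriat_full_and_loo(P, np.column_stack([x, y]))
    pooled_e = chosen_noise.ravel()
    pooled_a = trial_afriat.ravel()
    degenerate = pooled_e.std() == 0.0 or pooled_a.std() == 0.0
    if degenerate:
        r_val, p_val = float("nan"), float("nan")
    else:
        res = stats.pearsonr(pooled_e, pooled_a)
        r_val, p_val = float(res.statistic), float(res.pvalue)
    return NRUMRun(
        n_reps=n_reps,
        budgets=list(grid.budgets),
        params=params,
        noise=noise,
        choices=choices,
        chosen_noise=chosen_noise,
        trial_afriat=trial_afriat,
        pooled_r=r_val,
        pooled_p=p_val,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Discrete-alternative demonstrations
# ---------------------------------------------------------------------------

@dataclass
class DemoAlternative:
    """Monte-Carlo summary for one alternative in the discrete demo."""

    mean_valuation: float
    p_choice: float
    mean_chosen_utility: float
    se_chosen_utility: float
    n_chosen: int


def conditional_utility_demo(
    means, log_sd: float, n_samples: int, seed=0, noise_mode: str = "multiplicative"
) -> list[DemoAlternative]:
    """Noisy-valuation choice among discrete alternatives, by simulation.

    Each alternative's realized utility is skewed around its stated
    arithmetic mean; the largest realized utility is chosen.  Returns, per
    alternative, the choice probability and the mean (with standard error)
    of the chosen utility conditional on that alternative winning.

    Two noise parameterizations are supported, because the random-utility
    story can be told either way and they emphasize different conclusions:

    ``multiplicative`` (default)
        v~_k is log-normal with arithmetic mean ``means[k]`` and the given
        log-sd.  Choice probabilities have a bivariate-normal closed form
        (for two alternatives, P(worse chosen) = Phi(-log(m1/m2) /
        (log_sd * sqrt(2)))).
    ``additive``
        v~_k = means[k] + e_k with e_k an i.i.d. zero-mean log-normal of
        the given log-sd.  Here the chosen bundle's *conditional mean
        utility rises as worse alternatives are chosen* — the noise term
        had to make up the valuation gap — which is the signature the
        model predicts for a valuation-tracking neural signal.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("all mean valuations must be positive")
    if n_samples < 10_000:
        raise ValueError(f"n_samples must be >= 10000, got {n_samples}")
    rng = np.random.Generator(np.random.PCG64(_as_ss(seed)))
    z = rng.standard_normal((n_samples, len(means)))
    if noise_mode == "multiplicative":
        # log-mean set so the arithmetic mean equals the stated valuation
        mu = np.log(means) - log_sd**2 / 2.0
        draws = np.exp(mu[None, :] + log_sd * z)
    elif noise_mode == "additive":
        draws = means[None, :] + np.exp(log_sd * z) - math.exp(log_sd**2 / 2.0)
    else:
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    winner = np.argmax(draws, axis=1)
    top = draws[np.arange(n_samples), winner]
    out = []
    for k in range(len(means)):
        sel = winner == k
        cnt = int(sel.sum())
        chosen = top[sel]
        out.append(
            DemoAlternative(
                mean_valuation=float(means[k]),
                p_choice=cnt / n_samples,
                mean_chosen_utility=float(chosen.mean()) if cnt else float("nan"),
                se_chosen_utility=float(chosen.std(ddof=1) / np.sqrt(cnt)) if cnt > 1 else float("nan"),
                n_chosen=cnt,
            )
        )
    return out
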