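"""Domain types and synthetic data for linear budget-line choice experiments.

The experimental unit is a *trial*: a subject faces a linear budget line over
two accounts (X and Y), each point on the line being a 50/50 lottery between
the token amounts allocated to the two accounts, and picks one bundle.  A
subject's session is an ordered :class:`ChoiceDataset` of such observations,
which is the input to every consistency index in this package.

The module also provides the synthetic task generator (randomized budget
lines on a 0.1-token grid over axes scaled 0-100) and a small library of
chooser strategies (uniform random, safe, corner, expenditure-split,
deterministic utility maximization, and noisy random-utility choice) used to
build test populations without any subject data.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bundle",
    "BudgetSet",
    "Observation",
    "ChoiceDataset",
    "DatasetFormatError",
    "TOL_BUDGET",
    "GRID_STEP",
    "generate_budgets",
    "choose",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
    "STRATEGIES",
]

#: Default tolerance for the "choice lies on the budget line" invariant,
#: relative to the trial's expenditure.
TOL_BUDGET = 1e-6

#: Token resolution of the experimental task.
GRID_STEP = 0.1


class DatasetFormatError(ValueError):
    """A tabular dataset file violates the expected format."""


@dataclass(frozen=True)
class Bundle:
    """A two-account token allocation (x tokens to X, y tokens to Y)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"bundle coordinates must be nonnegative, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class BudgetSet:
    """A linear budget line: two positive per-token prices and an expenditure.

    Prices and expenditure are only identified up to a common positive scale;
    every index in this package is invariant to that scale.  The canonical
    normalization (used by :meth:`from_intercepts`) sets the expenditure to 1
    so each price is the inverse of the corresponding axis intercept.
    """

    price_x: float
    price_y: float
    expenditure: float = 1.0

    def __post_init__(self) -> None:
        if not (self.price_x > 0 and self.price_y > 0 and self.expenditure > 0):
            raise ValueError(
                "prices and expenditure must be positive, got "
                f"({self.price_x}, {self.price_y}, {self.expenditure})"
            )

    @classmethod
    def from_intercepts(cls, x_intercept: float, y_intercept: float) -> "BudgetSet":
        if not (x_intercept > 0 and y_intercept > 0):
            raise ValueError("intercepts must be positive")
        return cls(price_x=1.0 / x_intercept, price_y=1.0 / y_intercept, expenditure=1.0)

    @property
    def x_intercept(self) -> float:
        return self.expenditure / self.price_x

    @property
    def y_intercept(self) -> float:
        return self.expenditure / self.price_y

    @property
    def log_price_ratio(self) -> float:
        """log(price_x / price_y); the (signed) steepness of the line."""
        return math.log(self.price_x / self.price_y)

    @property
    def safe_portfolio(self) -> float:
        """Token count of the riskless bundle on the 45-degree line."""
        return self.expenditure / (self.price_x + self.price_y)

    def x_grid(self, step: float = GRID_STEP) -> np.ndarray:
        """Grid of x coordinates along the line at the task's resolution."""
        n = int(round(self.x_intercept / step))
        return np.arange(n + 1) * step

    def y_at(self, x: np.ndarray | float):
        """Solve the line for y at the given x coordinate(s)."""
        return (self.expenditure - self.price_x * np.asarray(x, dtype=float)) / self.price_y

    def cost(self, bundle: Bundle) -> float:
        return self.price_x * bundle.x + self.price_y * bundle.y

    def on_line(self, bundle: Bundle, tol: float = TOL_BUDGET) -> bool:
        return abs(self.cost(bundle) - self.expenditure) <= tol * self.expenditure


@dataclass(frozen=True)
class Observation:
    """One trial: a budget line, the chosen bundle, and an optional RT (s)."""

    budget: BudgetSet
    choice: Bundle
    rt: float | None = None
    tol_budget: float = TOL_BUDGET

    def __post_init__(self) -> None:
        if self.rt is not None and not self.rt > 0:
            raise ValueError(f"rt must be positive when present, got {self.rt}")
        if not self.budget.on_line(self.choice, self.tol_budget):
            raise ValueError(
                f"choice {self.choice} is off the budget line "
                f"(cost {self.budget.cost(self.choice):.6g} != "
                f"expenditure {self.budget.expenditure:.6g})"
            )


@dataclass
class ChoiceDataset:
    """An ordered collection of observations for one subject.

    Trial order is preserved: the leave-one-out indices are positional.
    """

    observations: list[Observation]
    subject_id: str = ""
    #: (row, reason) pairs for input rows excluded while reading a file.
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def __getitem__(self, i: int) -> Observation:
        return self.observations[i]

    def drop(self, i: int) -> "ChoiceDataset":
        """The dataset with observation ``i`` removed (for leave-one-out)."""
        obs = list(self.observations)
        del obs[i]
        return ChoiceDataset(obs, subject_id=self.subject_id)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Prices (n,2), chosen bundles (n,2) and expenditures (n,) as arrays."""
        P = np.array([[o.budget.price_x, o.budget.price_y] for o in self.observations])
        X = np.array([[o.choice.x, o.choice.y] for o in self.observations])
        M = np.array([o.budget.expenditure for o in self.observations])
        return P, X, M


# ---------------------------------------------------------------------------
# Synthetic task generator
# ---------------------------------------------------------------------------

def _as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def generate_budgets(
    n_trials: int,
    seed,
    min_major_intercept: float = 50.0,
    max_intercept: float = 100.0,
    min_minor_intercept: float = 5.0,
) -> list[BudgetSet]:
    """Sample randomized budget lines emulating the graphical choice task.

    Each axis intercept is drawn uniformly on the 0.1-token grid in
    ``[min_minor_intercept, max_intercept]``; the pair is redrawn until the
    larger intercept is at least ``min_major_intercept``, which reproduces
    the task's substantial variation of slopes and endowments while keeping
    every line visible on the 0-100 token axes.  The default minor-intercept
    floor of 5 tokens excludes near-degenerate slivers that could not be
    displayed or clicked at the task's resolution; it is the value at which
    simulated uniform-random choosers reproduce the published
    random-behavior benchmarks of all three aggregate indices.  Trial ``k``
    is driven by its own random substream, so it does not depend on
    ``n_trials``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if not (0 < min_major_intercept <= max_intercept):
        raise ValueError("need 0 < min_major_intercept <= max_intercept")
    if not (0 < min_minor_intercept <= min_major_intercept):
        raise ValueError("need 0 < min_minor_intercept <= min_major_intercept")
    lo = int(round(min_minor_intercept / GRID_STEP))
    hi = int(round(max_intercept / GRID_STEP))
    major = int(round(min_major_intercept / GRID_STEP))
    budgets = []
    for child in _as_seed_sequence(seed).spawn(n_trials):
        rng = np.random.Generator(np.random.PCG64(child))
        while True:
            xg, yg = rng.integers(lo, hi + 1, size=2)
            if max(xg, yg) >= major:
                break
        budgets.append(BudgetSet.from_intercepts(xg * GRID_STEP, yg * GRID_STEP))
    return budgets


STRATEGIES = (
    "uniform_random",
    "safe_45",
    "cheaper_corner",
    "expenditure_split",
    "maximize",
    "nrum",
)


def choose(budget: BudgetSet, strategy: str, seed=0, params=None, noise=None) -> Bundle:
    """Pick a bundle on ``budget`` according to a chooser strategy.

    Strategies
    ----------
    ``uniform_random``
        Uniform draw over the discretized line (0.1-token x-grid).
    ``safe_45``
        The riskless bundle x = y at the 45-degree intersection.
    ``cheaper_corner``
        All tokens to the cheaper account (ties go to X).
    ``expenditure_split``
        Equal spending on the two accounts (Cobb-Douglas behavior).
    ``maximize``
        The deterministic optimum of a parametric utility (requires
        ``params``; see :mod:`revpref.utility`).
    ``nrum``
        Random-utility choice: utility plus one skewed noise draw per grid
        bundle, argmax wins (requires ``params`` and ``noise``; see
        :mod:`revpref.nrum`).
    """
    m, px, py = budget.expenditure, budget.price_x, budget.price_y
    if strategy == "uniform_random":
        rng = np.random.Generator(np.random.PCG64(_as_seed_sequence(seed)))
        grid = budget.x_grid()
        x = float(rng.choice(grid))
        return Bundle(x, max(float(budget.y_at(x)), 0.0))
    if strategy == "safe_45":
        s = budget.safe_portfolio
        return Bundle(s, s)
    if strategy == "cheaper_corner":
        if px <= py:
            return Bundle(m / px, 0.0)
        return Bundle(0.0, m / py)
    if strategy == "expenditure_split":
        return Bundle(m / (2 * px), m / (2 * py))
    if strategy == "maximize":
        if params is None:
            raise ValueError("maximize strategy requires utility params")
        from .utility import optimal_bundle

        bundle, _ = optimal_bundle(budget, params)
        return bundle
    if strategy == "nrum":
        if params is None or noise is None:
            raise ValueError("nrum strategy requires utility params and a noise spec")
        from .nrum import nrum_choice

        bundle, _ = nrum_choice(budget, params, noise, seed)
        return bundle
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def generate_dataset(
    n_trials: int,
    strategy: str,
    seed,
    subject_id: str = "",
    params=None,
    noise=None,
    min_major_intercept: float = 50.0,
    max_intercept: float = 100.0,
) -> ChoiceDataset:
    """Generate a full synthetic session: random budgets plus chosen bundles.

    Budget lines and strategy draws consume separate substreams of ``seed``;
    the whole dataset is reproducible from the one integer.
    """
    root = _as_seed_sequence(seed)
    budget_ss, choice_ss = root.spawn(2)
    budgets = generate_budgets(n_trials, budget_ss, min_major_intercept, max_intercept)
    obs = []
    for budget, child in zip(budgets, choice_ss.spawn(n_trials)):
        bundle = choose(budget, strategy, seed=child, params=params, noise=noise)
        obs.append(Observation(budget, bundle))
    return ChoiceDataset(obs, subject_id=subject_id)


# ---------------------------------------------------------------------------
# Tabular dataset format
# ---------------------------------------------------------------------------

_COLUMNS = ["trial", "price_x", "price_y", "expenditure", "x", "y", "rt"]


def _fmt(v: float) -> str:
    # repr of a Python float is the shortest exact round-trip form
    return repr(float(v))


def write_dataset(dataset: ChoiceDataset, path) -> None:
    """Write a dataset as CSV with columns trial,price_x,price_y,expenditure,x,y,rt."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COLUMNS)
        for i, o in enumerate(dataset.observations, start=1):
            w.writerow(
                [
                    i,
                    _fmt(o.budget.price_x),
                    _fmt(o.budget.price_y),
                    _fmt(o.budget.expenditure),
                    _fmt(o.choice.x),
                    _fmt(o.choice.y),
                    "" if o.rt is None else _fmt(o.rt),
                ]
            )


def read_dataset(
    path,
    subject_id: str = "",
    drop_invalid: bool = False,
    tol_budget: float = TOL_BUDGET,
) -> ChoiceDataset:
    """Read a CSV choice dataset, validating the on-line invariant per row.

    Rows whose chosen bundle lies off the budget line beyond ``tol_budget``
    (relative to expenditure) are format errors; with ``drop_invalid=True``
    they are excluded instead and reported in ``dataset.excluded`` — the same
    treatment the task applies to no-choice trials.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        fh: io.TextIOBase = open(path, newline="")
        close = True
    else:
        fh, close = path, False
    try:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetFormatError("empty file") from None
        if [h.strip() for h in header] != _COLUMNS:
            raise DatasetFormatError(
                f"expected header {','.join(_COLUMNS)}, got {','.join(header)}"
            )
        observations: list[Observation] = []
        excluded: list[tuple[int, str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(_COLUMNS):
                raise DatasetFormatError(f"row {lineno}: expected {len(_COLUMNS)} fields")
            try:
                px, py, m, x, y = (float(row[i]) for i in range(1, 6))
                rt = float(row[6]) if row[6].strip() else None
            except ValueError as exc:
                raise DatasetFormatError(f"row {lineno}: {exc}") from None
            try:
                budget = BudgetSet(px, py, m)
            except ValueError as exc:
                raise DatasetFormatError(f"row {lineno}: {exc}") from None
            try:
                obs = Observation(budget, Bundle(x, y), rt=rt, tol_budget=tol_budget)
            except ValueError as exc:
                if drop_invalid:
                    excluded.append((lineno, str(exc)))
                    continue
                raise DatasetFormatError(f"row {lineno}: {exc}") from None
            observations.append(obs)
        return ChoiceDataset(observations, subject_id=subject_id, excluded=excluded)
    finally:
        if close:
            fh.close()
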