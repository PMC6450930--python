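import numpy as np
import pytest

from revpref import (
    Bundle,
    BudgetSet,
    ChoiceDataset,
    Observation,
    UtilityParams,
    generate_dataset,
)


@pytest.fixture
def crossing_toy() -> ChoiceDataset:
    """Two crossing budget lines whose choices form a strict 2-cycle.

    Trial 1: prices (1, 2), expenditure 100, choice (20, 40).
    Trial 2: prices (2, 1), expenditure 100, choice (40, 20).
    Each choice costs 80 < 100 at the other trial's prices, so the two
    bundles are mutually strictly revealed preferred.
    """
    return ChoiceDataset(
        [
            Observation(BudgetSet(1, 2, 100), Bundle(20, 40)),
            Observation(BudgetSet(2, 1, 100), Bundle(40, 20)),
        ]
    )


@pytest.fixture
def embedded_toy() -> tuple[ChoiceDataset, list[int]]:
    """The crossing toy embedded among 8 mutually non-comparable trials.

    The consistent trials are expenditure-split (Cobb-Douglas) choices on
    lines tangent to the hyperbola x*y = 2025; tangency makes every other
    tangent line's choice strictly unaffordable, so the consistent trials
    generate no revealed-preference edges among themselves, and the
    hyperbola sits far enough out that its choices are unaffordable under
    the toy budgets (no cycles beyond the intended toy 2-cycle).
    Returns the dataset and the positions of the two toy trials.
    """
    obs = []
    for x0 in [41, 42, 43, 44]:
        y0 = 2025.0 / x0
        obs.append(Observation(BudgetSet.from_intercepts(2 * x0, 2 * y0), Bundle(x0, y0)))
    obs.append(Observation(BudgetSet.from_intercepts(100, 50), Bundle(20, 40)))
    for x0 in [45, 46, 47, 48]:
        y0 = 2025.0 / x0
        obs.append(Observation(BudgetSet.from_intercepts(2 * x0, 2 * y0), Bundle(x0, y0)))
    obs.append(Observation(BudgetSet.from_intercepts(50, 100), Bundle(40, 20)))
    return ChoiceDataset(obs), [4, 9]


@pytest.fixture
def ev_params() -> UtilityParams:
    """Risk-neutral expected value: beta = 0, rho = 0."""
    return UtilityParams.crra(beta=0, rho=0)


@pytest.fixture
def da_params() -> UtilityParams:
    """A moderately disappointment-averse, risk-averse subject."""
    return UtilityParams.crra(beta=0.5, rho=0.5)


def make_random_dataset(n_trials: int, seed: int) -> ChoiceDataset:
    return generate_dataset(n_trials, "uniform_random", seed=seed)


def rescale_trial(dataset: ChoiceDataset, i: int, c: float) -> ChoiceDataset:
    """Multiply one trial's prices and expenditure by a constant."""
    obs = list(dataset.observations)
    o = obs[i]
    b = o.budget
    obs[i] = Observation(
        BudgetSet(c * b.price_x, c * b.price_y, c * b.expenditure), o.choice, o.rt
    )
    return ChoiceDataset(obs, subject_id=dataset.subject_id)
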