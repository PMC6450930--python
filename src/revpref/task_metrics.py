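"""Choice difficulty on continuous budget sets and the per-trial regressors.

In binary choice, difficulty is the (small) subjective-value difference
between the two options.  On a continuous budget line the analogue must
account for the whole menu and for the subject's own preferences, so the
*Choice Simplicity* index discretizes the line into N bundles, measures how
far each falls short of the best one, and averages:

    Simplicity_b = mean_i( V_b - v_ib ) / Endowment_b,
    V_b = max_i v_ib,

with v_ib the subjective value of bundle i on line b under the subject's
recovered utility parameters.  Values near 0 mean the menu is full of
near-ties with the optimum — a difficult choice; larger values mean an
easy, peaked problem.  The endowment normalization (by default the
safe-portfolio token count, the line's distance from the origin along the
45-degree ray) stops longer lines from scoring higher merely because their
bundles are farther apart.

The module also assembles the per-trial regressor table used to relate
behavior (or a neural signal) to inconsistency: response time, the
trial-specific MMI, the chosen bundle's subjective value, the log price
ratio, the endowment, simplicity, and a confidence proxy (the second-order
polynomial of SV, i.e. SV squared alongside SV itself).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .utility import UtilityParams, _sv_xy

__all__ = ["choice_simplicity", "regressor_table"]


def choice_simplicity(
    budget,
    params: UtilityParams,
    N: int = 1000,
    denominator: str = "safe_portfolio",
) -> float:
    """Endowment-normalized mean SV shortfall along the discretized line.

    The line is discretized into ``N`` bundles uniformly in x (both corners
    included).  ``denominator`` selects the endowment normalization:
    ``'safe_portfolio'`` (default) divides by the token count of the safe
    bundle on the 45-degree line; ``'expenditure'`` divides by the raw
    expenditure in price units (the two differ by the factor
    price_x + price_y).
    """
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    xint = budget.x_intercept
    if not xint > 0 or not budget.y_intercept > 0:
        raise ValueError("degenerate budget line")
    xs = np.linspace(0.0, xint, N)
    ys = np.maximum(budget.y_at(xs), 0.0)
    v = _sv_xy(xs, ys, params)
    gap = v.max() - v
    if denominator == "safe_portfolio":
        denom = budget.safe_portfolio
    elif denominator == "expenditure":
        denom = budget.expenditure
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return float(gap.mean() / denom)


def regressor_table(
    dataset,
    mmi_result,
    loo_series,
    N_simplicity: int = 1000,
    simplicity_denominator: str = "safe_portfolio",
) -> pd.DataFrame:
    """One row per trial: rt, trial_mmi, sv, price_ratio, endowment,
    simplicity, confidence (= sv**2).

    ``mmi_result`` supplies the recovered utility parameters (SV and
    simplicity are computed under them); ``loo_series`` must be the
    trial-specific series computed on the same dataset.
    """
    values = np.asarray(loo_series.values, dtype=float)
    if len(values) != dataset.n:
        raise ValueError(
            f"loo series length {len(values)} does not match dataset n {dataset.n}"
        )
    params: UtilityParams = mmi_result.best_params
    rows = []
    for obs, trial_mmi in zip(dataset, values):
        sv = float(_sv_xy(obs.choice.x, obs.choice.y, params))
        rows.append(
            {
                "rt": obs.rt if obs.rt is not None else np.nan,
                "trial_mmi": trial_mmi,
                "sv": sv,
                "price_ratio": obs.budget.log_price_ratio,
                "endowment": obs.budget.safe_portfolio,
                "simplicity": choice_simplicity(
                    obs.budget, params, N=N_simplicity,
                    denominator=simplicity_denominator,
                ),
                "confidence": sv**2,
            }
        )
    return pd.DataFrame(rows)
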