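"""Why inconsistent choices carry *higher* utility signals: discrete demo.

Two parameterizations of noisy valuations over discrete alternatives:

* multiplicative (log-normal utilities with stated arithmetic means) — the
  choice probability of the worse option has a normal-cdf closed form;
* additive (valuation plus zero-mean log-normal noise) — conditioning on a
  worse alternative winning selects large noise draws, so the chosen
  option's mean realized utility *rises* as worse alternatives are chosen.
"""

import numpy as np
from scipy import stats

from revpref import conditional_utility_demo

demo = conditional_utility_demo([4, 2], 0.7, 2_000_000, seed=3)
closed_form = stats.norm.cdf(-np.log(2) / (0.7 * np.sqrt(2)))
print("multiplicative, means (4, 2), log-sd 0.7:")
print(f"  P(worse option chosen) = {demo[1].p_choice:.4f} (closed form {closed_form:.4f})")

print("\nadditive, means (7, 6, 5, 4, 3, 2), log-sd 0.7:")
six = conditional_utility_demo([7, 6, 5, 4, 3, 2], 0.7, 2_000_000, seed=6,
                               noise_mode="additive")
for k, alt in enumerate(six, start=1):
    print(
        f"  chose option {k} (mean value {alt.mean_valuation:g}): "
        f"P = {alt.p_choice:.4f}, E[utility | chosen] = "
        f"{alt.mean_chosen_utility:.2f} +- {alt.se_chosen_utility:.2f}"
    )
print(
    "\nThe conditional mean utility climbs from the best to the worst\n"
    "alternative: the worse the chosen option, the larger the noise draw\n"
    "that made it win."
)
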