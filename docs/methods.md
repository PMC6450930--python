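# Methods

## Setting

The package analyzes choices from *linear budget sets over two accounts*:
on each trial a decision-maker sees a line of 50/50 lotteries (x tokens in
account X, y tokens in account Y, axes scaled 0–100 tokens at 0.1-token
resolution) and picks one bundle on it.  A session is an ordered list of
(prices, chosen bundle) pairs; prices and expenditure are only identified
up to a common scale, and every quantity computed here is invariant to
per-trial rescaling (tested as such).  The canonical normalization sets
expenditure to 1, so each price is the inverse of an axis intercept.

## Revealed preference and GARP

Bundle x^i is directly revealed preferred to x (x^i R0 x) when x was
affordable at trial i's prices, strictly (P0) when strictly cheaper; R is
the transitive closure of R0.  GARP requires that x^i R x^j never coexist
with x^j P0 x^i.  At efficiency level e ∈ [0, 1] the relations are built
from deflated budgets, e·(p^i·x^i) ≥ p^i·x^j.

Violations are counted as *ordered pairs* (i, j), i ≠ j, with x^i R x^j
and x^j P0 x^i, so a mutual strict 2-cycle counts as 2.  This is the only
convention whose random-chooser magnitudes land on the published
random-behavior benchmark (~4,500 of the 108·107 = 11,556 ordered pairs).

### Exact Afriat index

The Afriat (critical cost efficiency) index is 1 − e*, with e* the
supremal e at which GARP(e) holds.  Everything depends on e only through
the scale-free ratio matrix W[i, j] = (p^i·x^j)/(p^i·x^i): an R0(e) edge
i→j exists iff e ≥ W[i, j].  A violation pair (i, j) therefore first
appears at max(B[i, j], W[j, i]), where B is the *bottleneck* (minimax
edge weight over directed paths) distance matrix of W, and

    e* = min over ordered pairs (i, j), i ≠ j, of max(B[i, j], W[j, i]).

B is one Floyd–Warshall-style O(n³) pass, so e* is exact — no efficiency
grid or tolerance.  A conventional bisection over boolean-closure GARP
tests is retained (`afriat_index(..., method="bisection")`) purely as an
independent cross-check; the suite asserts the two routes agree.  The
leave-one-out Afriat series recomputes the bottleneck pass per left-out
observation (numba-compiled when available, with an identical numpy
fallback).

## Disappointment-aversion utility

Bundles are 50/50 lotteries, valued by rank-dependent weights on the
better and worse outcome:

    SV(x, y) = γ ω(max(x, y)) + (1 − γ) ω(min(x, y)),  γ = 1/(2 + β),

with β ∈ [−1, ∞): β > 0 overweights the worse outcome (disappointment
aversion), β < 0 the better one (elation seeking), β = 0 is expected
utility.  The outcome utility ω is CRRA, z^(1−ρ)/(1−ρ) with ln z at
ρ = 1, or CARA, 1 − e^(−Az), as a robustness family.  Numerical
conventions:

* ω is evaluated at max(z, 10⁻⁶ tokens) where it is undefined at zero
  (CRRA with ρ ≥ 1); the floor is far below the task's 0.1-token grid.
* During estimation β and ρ are capped at 10 (A at 1): beyond these the
  implied behavior is indistinguishable from Leontief/corner choices at
  the task resolution.
* ρ = 1 uses ln z exactly; no blending near 1 is needed because the MMI
  objective compares expenditures, never utility levels across ρ.

**Optimal bundles** on a line combine closed-form candidates — both
corners, the safe 45° kink, and the interior tangency points of each
orientation (solved analytically for CRRA and CARA) — with a 0.1-token
grid argmax refined by golden section, so maximizer choices are exact
continuous-line optima (ties break toward larger x).  Exactness matters:
it is what guarantees simulated maximizers satisfy GARP exactly rather
than up to grid slack.

**The money metric** m(x^i, p^i, u) = min{p^i·y : SV(y) ≥ SV(x^i)} is
solved on the indifference level through the target.  The minimal y
attaining the level at a given x has a closed form (ω is invertible), so
the search is a 1-D scan over x on a geometric-plus-linear grid bounded by
the target's own cost, refined by vectorized golden section, with the
target, kink, both axis corners (the minimum jumps there for non-convex
β < 0 preferences), and the analytic tangency candidates always included.
Because the target is a candidate, m ≤ p^i·x^i holds identically and the
normalized adjustment v*_i = 1 − m/(p^i·x^i) lies in [0, 1).  The
implementation is validated in the suite against an independent 2-D
brute-force scan.

## Aggregate MMI and parameter recovery

The aggregate Money Metric Index minimizes the averaged sum of squares of
the adjustments over the family box,

    MMI(D, U) = inf_{u ∈ U} sqrt( (1/n) Σ_i v*_i(D, u)² ),

reported on the 0–1 budget-share scale (the same scale as the Afriat
index; this is what makes the two indices directly comparable and matches
the published magnitudes of both real subjects and random-behavior
benchmarks).  The optimizer is a deterministic 21×21 coarse grid — β and
ρ grids include the exact special points −1, 0 and 0, 1 so the named
special cases are always candidates; A is log-spaced — followed by
bounded Nelder–Mead from the best cells.  No stochastic restarts: every
estimate is bit-reproducible.  On noiseless 108-trial maximizer data the
recovered (β, ρ) land within ±0.1 of truth across the empirically
relevant box (tested over 20 draws).

### Trial-specific indices

The trial-specific index of observation i is ε_D − ε_{D−i} for an
aggregate index ε and the dataset with observation i removed.  For the
nonparametric indices removal can only relax the relations, so the series
is nonnegative.  For the MMI the per-subset parameters are re-estimated;
the re-estimation is warm-started from the full-data optimum and from the
subset's best grid cell (subset grid objectives are free because the
per-trial squared adjustments of every grid cell are cached), with a
reduced Nelder–Mead budget.  A subset whose best known objective is
already ≤ 10⁻¹² skips refinement — zero is a hard floor.  Small negative
trial-specific MMI values are expected at consistency-anchoring trials
(the averaging denominator shrinks), and `warm_start=False` gives the
slower fully-searched mode.

## Synthetic task and chooser strategies

The budget generator draws each axis intercept uniformly on the 0.1-token
grid in [5, 100] and redraws until the larger intercept is ≥ 50,
emulating the graphical task's randomized slopes and endowments.  The
5-token minor-intercept floor excludes near-degenerate slivers that could
not be displayed or clicked on a 0–100 screen, and it is the floor at
which simulated uniform-random choosers reproduce the published
random-behavior benchmarks of all three aggregate indices simultaneously
(with a floor of 1 token the violation and Afriat medians still match but
the MMI median runs ~10% high).  The law is exposed as parameters
(`min_major_intercept`, `max_intercept`, `min_minor_intercept`) because
published task descriptions pin down only the constraints, not the law
itself; population benchmarks computed from this sampler
(`scripts/acceptance.py`) depend on that inference.  Chooser
strategies: uniform-random over the discretized line, the safe 45°
bundle, the cheaper corner, expenditure splitting (Cobb–Douglas
behavior), exact utility maximization, and noisy random-utility choice.
Budgets and strategy draws consume per-trial substreams of one integer
seed, so trial k is reproducible regardless of the session length.

What the generator does *not* emulate: response-time generation, motor or
numerical imprecision of a pointing device, payment lotteries, and
block-level preference change.  Tests passing on synthetic populations
therefore validate the indices' computational properties, not any claim
about human behavior.

## Random-utility simulation

Noisy sessions add one independent draw of skewed noise to the subjective
value of *every* grid bundle on every line and choose the argmax (Gumbel
with mode 0, or log-normal shifted to mean 0; both right-skewed at every
scale).  The noise scale is calibrated so the mean Afriat index over
simulated sessions matches a target level: the mean is nondecreasing in
the scale, so a bisection with common random numbers (50 sessions per
evaluation, the accepted scale re-polished against a fresh 200-session
set) converges; the achieved level is reported and carries the target's
±10% relative tolerance plus the Monte-Carlo error of the evaluation.

The diagnostic pools, across sessions and trials, the chosen bundle's
noise draw and the trial-specific Afriat index (the nonparametric stand-in
for the trial-specific MMI — re-using the MMI here would recycle the very
parameters that generated the valuations), and reports their Pearson
correlation: positive and overwhelmingly significant under both noise
families at calibrated scales.

### Discrete demonstrations

`conditional_utility_demo` exposes two parameterizations because the
random-utility story is told in two ways and they highlight different
facts.  With *multiplicative* noise (log-normal utilities with stated
arithmetic means, shared log-sd) choice probabilities have a closed form
— for means (4, 2) and log-sd 0.7, P(worse chosen) = Φ(−ln 2/(0.7√2)) ≈
0.242 — but the chosen option's conditional mean utility *falls* as worse
options are chosen.  With *additive* noise (valuation plus i.i.d.
zero-mean log-normal) the signature inequalities hold: the chosen
utility's conditional mean is higher on inconsistent choices, grows with
the valuation gap, and rises monotonically as worse alternatives are
chosen.  The default is multiplicative; the suite asserts the closed-form
probability under it and the orderings under the additive mode.

## Choice simplicity and regressors

Choice Simplicity discretizes a line into N = 1000 bundles uniform in x
(both corners included), averages the subjective-value shortfall from the
best bundle, and normalizes by the endowment.  The endowment is taken as
the safe-portfolio token count m/(p_x + p_y) — the same units as the
endowment regressor — with raw expenditure available as an option, since
the published normalization does not pin the units down.  Near-zero
values mean a menu of near-ties (a difficult choice).  For a risk-averse
subject the index is minimized at interior slopes near the tie between
the safe bundle and the cheap-corner temptation, and on noisy simulated
subjects it correlates weakly and negatively with trial-specific
inconsistency (R² < 0.1) — difficulty enables, but does not by itself
produce, inconsistency.

The regressor table exports, per trial: RT, trial-specific MMI, the
chosen bundle's SV under the recovered parameters, its square (a
confidence proxy — confidence is modeled as a second-order polynomial of
value), the log price ratio, the safe-portfolio endowment, and
simplicity.  Downstream regressions (OLS, clustered, or neural GLMs) are
deliberately out of scope.

## Problem sizes and tolerances

Population benchmarks use 500 simulated subjects for the violation count,
300 for the Afriat median, and 50 (with the reduced refinement budget)
for the MMI median — sizes at which the medians are stable to well within
the comparison tolerances.  The Afriat bisection cross-check runs at
tolerance 10⁻⁴; money-metric golden-section refinement uses 35
iterations (interval shrinkage < 10⁻⁷ of the bracket); Nelder–Mead stops
at xatol 10⁻³ / fatol 10⁻⁹.

## Known limitations

* The budget-sampling law is inferred from the task's constraints;
  population benchmarks shift if the original law differed.
* MMI values are upper bounds on the family infimum (any search is); the
  grid + refinement scheme is converged to ~5 decimal places on random
  choosers, but a differently-converged optimizer can differ at the
  margin.
* Varian and Houtman–Maks indices are not implemented (combinatorially
  hard at n = 108), so the MMI's misspecification split (MMI = Varian +
  misspecification) is only exercised as an inequality between families.
* The leave-one-out MMI with warm starts is an approximation knob; the
  exact full-search mode is available but ~20× slower.
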