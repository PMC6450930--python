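import numpy as np
import pytest
from scipy import stats

from revpref import (
    CalibrationError,
    NoiseSpec,
    UtilityParams,
    assess,
    calibrate_noise,
    conditional_utility_demo,
    count_violations,
    generate_budgets,
    optimal_bundle,
    simulate_dataset,
)


@pytest.fixture(scope="module")
def budgets():
    return generate_budgets(108, seed=42)


@pytest.fixture(scope="module")
def params():
    return UtilityParams.crra(beta=0.5, rho=0.5)


class TestNoiseSpec:
    @pytest.mark.parametrize("family", ["gumbel_zero_mode", "lognormal_zero_mean"])
    @pytest.mark.parametrize("scale", [0.1, 0.7])
    def test_positive_skew(self, family, scale):
        rng = np.random.default_rng(1)
        x = NoiseSpec(family, scale).sample(rng, 200_000)
        assert stats.skew(x) > 0

    def test_lognormal_centred_on_zero_mean(self):
        rng = np.random.default_rng(2)
        x = NoiseSpec("lognormal_zero_mean", 0.7).sample(rng, 1_000_000)
        assert abs(x.mean()) < 3 * x.std() / np.sqrt(len(x))

    def test_gumbel_mode_at_zero(self):
        # the histogram peak of Gumbel(0, s) sits at 0
        rng = np.random.default_rng(3)
        x = NoiseSpec("gumbel_zero_mode", 1.0).sample(rng, 500_000)
        hist, edges = np.histogram(x, bins=200, range=(-4, 8))
        peak = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(peak) < 0.2

    def test_validation(self):
        with pytest.raises(ValueError):
            NoiseSpec("cauchy", 1.0)
        with pytest.raises(ValueError):
            NoiseSpec("gumbel_zero_mode", 0.0)


class TestSimulate:
    def test_vanishing_noise_recovers_deterministic_optimum(self, budgets, params):
        spec = NoiseSpec("gumbel_zero_mode", 1e-12)
        ds, e = simulate_dataset(budgets, params, spec, seed=1)
        assert count_violations(ds).n_violations == 0
        for b, o in zip(budgets[:10], ds):
            opt, _ = optimal_bundle(b, params)
            assert abs(o.choice.x - opt.x) <= 0.1 + 1e-6  # grid resolution
        assert np.abs(e).max() < 1e-9

    def test_finite_noise_generates_violations(self, budgets, params):
        spec = NoiseSpec("gumbel_zero_mode", 0.5)
        hits = 0
        for s in range(3):
            ds, _ = simulate_dataset(budgets, params, spec, seed=10 + s)
            hits += count_violations(ds).n_violations > 0
        assert hits == 3

    def test_choices_on_line(self, budgets, params):
        ds, _ = simulate_dataset(budgets, params, NoiseSpec("lognormal_zero_mean", 0.4), seed=5)
        for o in ds:
            assert o.budget.on_line(o.choice)


class TestCalibration:
    def test_roundtrip_to_target(self, budgets, params):
        target = 0.05
        spec, info = calibrate_noise(
            budgets, params, target, "gumbel_zero_mode", reps=30, seed=5, full_output=True
        )
        # the stopping rule's own evaluation is within tolerance...
        assert abs(info["achieved_mean_afriat"] - target) <= 0.1 * target
        # ...and a fresh-seed re-simulation agrees up to Monte-Carlo error
        from revpref import afriat_index

        vals = [
            afriat_index(simulate_dataset(budgets, params, spec, seed=700 + s)[0])
            for s in range(40)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) <= 0.1 * target + 3 * se

    def test_mean_afriat_monotone_in_scale(self, budgets, params):
        from revpref import afriat_index

        means = []
        for scale in (0.05, 0.25, 1.0):
            spec = NoiseSpec("gumbel_zero_mode", scale)
            vals = [
                afriat_index(simulate_dataset(budgets, params, spec, seed=50 + s)[0])
                for s in range(12)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_argument_validation(self, budgets, params):
        with pytest.raises(ValueError):
            calibrate_noise(budgets, params, 0.0)
        with pytest.raises(ValueError):
            calibrate_noise(budgets, params, 0.05, reps=5)


class TestAssess:
    def test_positive_pooled_correlation(self, budgets, params):
        spec = NoiseSpec("gumbel_zero_mode", 0.25)
        run = assess(budgets, params, spec, n_reps=60, seed=6)
        assert run.pooled_r > 0
        assert run.pooled_p < 1e-10
        # shuffling the noise across trials destroys the correlation
        rng = np.random.default_rng(0)
        shuffled = run.chosen_noise.ravel().copy()
        rng.shuffle(shuffled)
        r, p = stats.pearsonr(shuffled, run.trial_afriat.ravel())
        assert abs(r) < abs(run.pooled_r) / 3
        assert p > 1e-4

    def test_seed_stability(self, budgets, params):
        spec = NoiseSpec("lognormal_zero_mean", 0.3)
        r1 = assess(budgets, params, spec, n_reps=40, seed=1).pooled_r
        r2 = assess(budgets, params, spec, n_reps=40, seed=2).pooled_r
        assert abs(r1 - r2) < 0.05

    def test_datasets_materialize(self, params):
        small = generate_budgets(10, seed=9)
        run = assess(small, params, NoiseSpec("gumbel_zero_mode", 0.3), n_reps=3, seed=3)
        ds_list = run.datasets
        assert len(ds_list) == 3 and all(d.n == 10 for d in ds_list)


class TestDiscreteDemo:
    def test_two_alternative_choice_probability_closed_form(self):
        # P(worse chosen) = Phi(-ln 2 / (0.7 sqrt 2)) for lognormal
        # valuations with means 4 and 2, log-sd 0.7
        demo = conditional_utility_demo([4, 2], 0.7, 400_000, seed=3)
        expected = stats.norm.cdf(-np.log(2) / (0.7 * np.sqrt(2)))
        assert demo[1].p_choice == pytest.approx(expected, abs=0.005)

    def test_additive_mode_inconsistent_choice_raises_mean_utility(self):
        demo = conditional_utility_demo([4, 2], 0.7, 400_000, seed=4, noise_mode="additive")
        assert demo[1].mean_chosen_utility > demo[0].mean_chosen_utility

    def test_gap_effect(self):
        # a larger valuation gap needs a larger noise draw to overcome
        for mode in ("multiplicative", "additive"):
            small = conditional_utility_demo([4, 2], 0.7, 400_000, seed=5, noise_mode=mode)
            large = conditional_utility_demo([7, 2], 0.7, 400_000, seed=5, noise_mode=mode)
            assert (
                large[1].mean_chosen_utility
                > small[1].mean_chosen_utility + 2 * large[1].se_chosen_utility
            )

    def test_six_alternative_severity_gradient(self):
        demo = conditional_utility_demo(
            [7, 6, 5, 4, 3, 2], 0.7, 1_000_000, seed=6, noise_mode="additive"
        )
        means = [d.mean_chosen_utility for d in demo]
        ses = [d.se_chosen_utility for d in demo]
        for k in range(1, 5):  # monotone from 2nd best to worst, within MC error
            assert means[k + 1] > means[k] - 2 * (ses[k] + ses[k + 1])

    def test_validation(self):
        with pytest.raises(ValueError):
            conditional_utility_demo([4, -2], 0.7, 20_000)
        with pytest.raises(ValueError):
            conditional_utility_demo([4, 2], 0.7, 100)
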