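import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revpref import (
    Bundle,
    BudgetSet,
    UtilityParams,
    generate_budgets,
    money_metric,
    optimal_bundle,
    subjective_value,
)
from revpref.utility import _sv_xy


class TestSubjectiveValue:
    @pytest.mark.parametrize(
        "x, y, beta, rho, expected",
        [
            (10, 30, 0, 0, 20.0),  # expected value: gamma = 1/2, omega identity
            (10, 30, -1, 0, 30.0),  # beta = -1 cares only about the larger prize
            # gamma = 0.25; 0.25 * 30**0.5/0.5 + 0.75 * 10**0.5/0.5
            (10, 30, 2, 0.5, 7.4820292778),
        ],
    )
    def test_crra_examples(self, x, y, beta, rho, expected):
        params = UtilityParams.crra(beta=beta, rho=rho)
        assert subjective_value(Bundle(x, y), params) == pytest.approx(expected, abs=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        x=st.floats(0.1, 100),
        y=st.floats(0.1, 100),
        beta=st.floats(-1, 5),
        rho=st.floats(0, 4),
    )
    def test_swap_symmetry(self, x, y, beta, rho):
        # SV depends on the bundle only through max and min
        params = UtilityParams.crra(beta=beta, rho=rho)
        assert subjective_value(Bundle(x, y), params) == pytest.approx(
            subjective_value(Bundle(y, x), params), rel=1e-12
        )

    def test_beta_zero_is_expected_utility(self):
        for rho in (0.0, 0.5, 1.0, 2.0):
            params = UtilityParams.crra(beta=0, rho=rho)
            x, y = 12.3, 47.1
            eu = 0.5 * float(_sv_xy(x, x, params)) + 0.5 * float(_sv_xy(y, y, params))
            assert subjective_value(Bundle(x, y), params) == pytest.approx(eu, rel=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            UtilityParams.crra(beta=-1.5, rho=0.5)
        with pytest.raises(ValueError):
            UtilityParams.cara(beta=0, A=0.0)
        with pytest.raises(ValueError):
            UtilityParams(family="DA_CRRA", beta=0, rho=0.5, A=1.0)


class TestOptimalBundle:
    def test_extreme_disappointment_aversion_chooses_safe(self):
        # beta -> infinity is Leontief: always the 45-degree bundle
        params = UtilityParams.crra(beta=1e6, rho=0.5)
        b = BudgetSet.from_intercepts(100, 50)
        bundle, _ = optimal_bundle(b, params)
        s = b.safe_portfolio
        assert bundle.x == pytest.approx(s, abs=1e-3)
        assert bundle.y == pytest.approx(s, abs=1e-3)

    def test_risk_neutral_chooses_cheaper_corner(self):
        params = UtilityParams.crra(beta=0, rho=0)
        b = BudgetSet.from_intercepts(100, 50)  # X cheaper
        bundle, _ = optimal_bundle(b, params)
        assert (bundle.x, bundle.y) == (pytest.approx(100), pytest.approx(0))

    def test_cobb_douglas_splits_expenditure(self):
        # beta = 0, rho = 1 is Cobb-Douglas with equal exponents
        params = UtilityParams.crra(beta=0, rho=1)
        b = BudgetSet.from_intercepts(100, 50)
        bundle, _ = optimal_bundle(b, params)
        assert b.price_x * bundle.x == pytest.approx(b.expenditure / 2, abs=1e-5)
        assert b.price_y * bundle.y == pytest.approx(b.expenditure / 2, abs=1e-5)

    def test_matches_dense_grid_argmax(self):
        rng = np.random.default_rng(4)
        budgets = generate_budgets(100, seed=12)
        for b in budgets:
            beta = rng.uniform(-1, 4)
            rho = rng.uniform(0, 3)
            params = UtilityParams.crra(beta=beta, rho=rho)
            bundle, sv = optimal_bundle(b, params)
            xs = np.linspace(0, b.x_intercept, 100_000)
            ys = np.maximum(b.y_at(xs), 0.0)
            vals = _sv_xy(xs, ys, params)
            j = int(np.argmax(vals))
            assert sv >= vals[j] - 1e-9
            # within 0.05 tokens of the dense argmax unless an SV tie
            if sv - vals[j] < 1e-12:
                assert abs(bundle.x - xs[j]) < 0.05 or abs(bundle.y - ys[j]) < 0.05


class TestMoneyMetric:
    def test_linear_indifference_reaches_corner(self, ev_params):
        # EV level of (20, 40) is 30; cheapest point with x + y = 60 at
        # prices (1, 2) is the corner (60, 0) costing 60
        b = BudgetSet(1, 2, 100)
        assert money_metric(Bundle(20, 40), b, ev_params) == pytest.approx(60.0, abs=1e-6)

    def test_own_optimum_costs_full_expenditure(self, da_params):
        b = BudgetSet.from_intercepts(80, 60)
        bundle, _ = optimal_bundle(b, da_params)
        m = money_metric(bundle, b, da_params)
        assert m == pytest.approx(b.expenditure, rel=1e-6)

    def test_never_exceeds_target_cost(self):
        rng = np.random.default_rng(11)
        budgets = generate_budgets(40, seed=21)
        for b in budgets:
            params = UtilityParams.crra(beta=rng.uniform(-1, 5), rho=rng.uniform(0, 4))
            x = rng.uniform(0, b.x_intercept)
            target = Bundle(x, max(float(b.y_at(x)), 0.0))
            m = money_metric(target, b, params)
            assert 0 < m <= b.cost(target) * (1 + 1e-12)

    def _brute_force(self, prices, target, params, n=1200):
        px, py = prices
        u0 = float(_sv_xy(target.x, target.y, params))
        cost_t = px * target.x + py * target.y
        xs = np.linspace(0, cost_t / px, n)
        ys = np.linspace(0, cost_t / py, n)
        XX, YY = np.meshgrid(xs, ys)
        feas = _sv_xy(XX, YY, params) >= u0
        C = px * XX + py * YY
        return min(float(C[feas].min()), cost_t) if feas.any() else cost_t

    def test_elation_seeking_corner_minimum(self):
        # beta = -1 preferences are non-convex: the cheapest attainment of a
        # level sits at an axis corner
        params = UtilityParams.crra(beta=-1, rho=0.5)
        b = BudgetSet(1, 1.7, 90)
        target = Bundle(30, (90 - 30) / 1.7)
        m = money_metric(target, b, params)
        hi = max(target.x, target.y)
        corner = min(b.price_x, b.price_y) * hi
        assert m == pytest.approx(corner, rel=1e-6)
        assert m == pytest.approx(self._brute_force((1, 1.7), target, params), rel=2e-3)

    @pytest.mark.parametrize(
        "params",
        [
            UtilityParams.crra(beta=0.5, rho=0.5),
            UtilityParams.crra(beta=-0.5, rho=1.0),
            UtilityParams.crra(beta=2.0, rho=2.5),
            UtilityParams.crra(beta=-1.0, rho=0.3),
            UtilityParams.cara(beta=0.7, A=0.05),
            UtilityParams.cara(beta=-0.6, A=0.02),
        ],
    )
    def test_agrees_with_independent_2d_scan(self, params):
        budgets = generate_budgets(6, seed=33)
        rng = np.random.default_rng(8)
        for b in budgets:
            x = rng.uniform(0.1 * b.x_intercept, 0.9 * b.x_intercept)
            target = Bundle(x, max(float(b.y_at(x)), 0.0))
            m = money_metric(target, b, params)
            brute = self._brute_force((b.price_x, b.price_y), target, params)
            # the 2-D scan only evaluates feasible grid points, so it can
            # only overestimate the true minimum, and by no more than one
            # grid cell's worth of expenditure in each coordinate
            cost_t = b.cost(target)
            assert brute - 2 * cost_t / 1200 <= m <= brute + 1e-9
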