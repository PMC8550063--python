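import math

import numpy as np
import pytest

from squidsem import (
    ForcingSeries,
    InvalidInputError,
    InvalidParameterError,
    SSTModel,
    default_initial_state,
    default_parameters,
    fisher_price_competitive,
    fisher_price_sem,
    incomes,
    market_price,
    simulate,
    step_effort,
    step_population,
    trader_cooperation,
)
from squidsem.errors import ConfigurationError


class TestPopulationStep:
    def test_carrying_capacity_fixed_point(self, params):
        nxt, catch = step_population(params.K, 0.0, params.q_max, params)
        assert (nxt, catch) == (params.K, 0.0)

    def test_extinction_is_absorbing(self, params):
        assert step_population(0.0, 50.0, params.q_max, params) == (0.0, 0.0)

    def test_logistic_update_hand_value(self):
        p = default_parameters(r=0.5, K=100.0)
        nxt, catch = step_population(50.0, 10.0, 0.01, p)
        assert catch == pytest.approx(5.0)
        assert nxt == pytest.approx(57.5)

    def test_catch_capped_at_stock(self, params):
        nxt, catch = step_population(10.0, 1e9, params.q_max, params)
        assert catch == 10.0 and nxt >= 0.0

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(InvalidInputError):
            step_population(-1.0, 0.0, params.q_max, params)


class TestMarketPrice:
    def test_reference_anchor(self, params):
        assert market_price(params.C_ref, params) == pytest.approx(params.p0)

    def test_isoelastic_hand_value(self):
        p = default_parameters(p0=10_000.0, C_ref=1_000.0, beta=2.0)
        assert market_price(4_000.0, p) == pytest.approx(5_000.0)

    def test_demand_multiplier_scales_price(self, params):
        doubled = params.replace(demand_mult=2.0)
        for catch in (10.0, 1_000.0, 80_000.0):
            assert market_price(catch, doubled) == pytest.approx(
                2 * market_price(catch, params)
            )

    def test_strictly_decreasing_in_catch(self, params):
        grid = np.linspace(params.eps_catch, 2e5, 500)
        prices = np.array([market_price(c, params) for c in grid])
        assert np.all(np.diff(prices) < 0)

    def test_zero_catch_evaluated_at_floor(self, params):
        assert market_price(0.0, params) == market_price(
            params.eps_catch, params
        )

    def test_invalid_flexibility_rejected(self):
        with pytest.raises(InvalidParameterError):
            default_parameters(beta=0.0)


class TestFisherPrices:
    def test_competitive_subtraction_and_floor(self, params):
        assert fisher_price_competitive(8_000.0, params.replace(c_proc=1_500.0)) == 6_500.0
        assert fisher_price_competitive(5_000.0, params.replace(c_proc=0.0)) == 5_000.0
        assert fisher_price_competitive(500.0, params.replace(c_proc=1_500.0)) == 0.0

    def test_full_cooperation_pins_price_to_minimum(self, params):
        assert fisher_price_sem(50_000.0, 1.0, params) == params.p_f_min

    def test_no_cooperation_recovers_competitive_price(self, params):
        p = params.replace(p_f_min=0.0, p_f_max=math.inf)
        assert fisher_price_sem(10_000.0, 0.0, p) == fisher_price_competitive(
            10_000.0, p
        )

    def test_interpolation_hand_value(self):
        p = default_parameters(c_proc=1_000.0, p_f_min=2_000.0, p_f_max=20_000.0)
        assert fisher_price_sem(10_000.0, 0.5, p) == pytest.approx(5_500.0)

    def test_monotone_in_both_arguments(self, params):
        mkt = np.linspace(2_000, 60_000, 30)
        coop = np.linspace(0, 1, 30)
        for c in coop:
            vals = [fisher_price_sem(m, c, params) for m in mkt]
            assert np.all(np.diff(vals) >= -1e-12)
        for m in mkt:
            vals = [fisher_price_sem(m, c, params) for c in coop]
            assert np.all(np.diff(vals) <= 1e-12)

    def test_never_exceeds_competitive_level(self, params):
        for m in (1_500.0, 5_000.0, 80_000.0):
            for c in (0.0, 0.3, 1.0):
                assert fisher_price_sem(m, c, params) <= max(
                    m - params.c_proc, params.p_f_min
                ) + 1e-9


class TestCooperation:
    def test_gulf_only_landings_full_cooperation(self, params):
        assert trader_cooperation(0.0, params) == params.coop_cap

    def test_exponential_breakdown_hand_value(self):
        p = default_parameters(gamma=3.0)
        assert trader_cooperation(1.0, p) == pytest.approx(math.exp(-3.0))

    def test_cooperation_cap_zero_kills_cooperation(self, params):
        p = params.replace(coop_cap=0.0)
        for r in (0.0, 0.5, 1.0):
            assert trader_cooperation(r, p) == 0.0

    def test_out_of_range_proportion_rejected(self, params):
        with pytest.raises(InvalidInputError):
            trader_cooperation(1.5, params)


class TestEffortAndIncomes:
    def test_zero_profit_is_equilibrium(self, params):
        p = params.replace(c_E=1_000.0)
        effort = 100.0
        # revenue exactly offsets cost: 1000*100 = 2000*50
        assert step_effort(effort, 2_000.0, 50.0, p) == effort

    def test_effort_adjustment_hand_value(self):
        p = default_parameters(k_E=1e-6, c_E=1_000.0)
        assert step_effort(100.0, 5_000.0, 50.0, p) == pytest.approx(100.15)

    def test_effort_floors_at_zero(self, params):
        p = params.replace(k_E=1.0, c_E=1e9)
        assert step_effort(10.0, 0.0, 0.0, p) == 0.0

    def test_no_fishery_no_income(self, params):
        p = params.replace(c_E=0.0)
        assert incomes(0.0, 10_000.0, 5_000.0, 0.0, p) == (0.0, 0.0)

    def test_income_split_hand_value(self):
        p = default_parameters(c_proc=1_000.0, c_E=0.0)
        inc_f, inc_t = incomes(100.0, 10_000.0, 5_500.0, 0.0, p)
        assert inc_f == pytest.approx(550_000.0)
        assert inc_t == pytest.approx(350_000.0)

    def test_competitive_margin_leaves_traders_nothing(self, params):
        p_m = 10_000.0
        p_f = p_m - params.c_proc
        _, inc_t = incomes(100.0, p_m, p_f, 0.0, params)
        assert inc_t == 0.0

    def test_price_inversion_rejected(self, params):
        with pytest.raises(InvalidInputError):
            incomes(10.0, 1_000.0, 2_000.0, 1.0, params)


def _flat_forcing(params, years, ml, pacific=0.0):
    n = len(years)
    return ForcingSeries(
        years=years,
        sst=np.zeros(n),
        mantle_length=np.full(n, ml),
        pacific_prop=np.full(n, pacific),
    )


class TestSimulate:
    YEARS50 = np.arange(1976, 2026)

    def test_zero_effort_converges_to_carrying_capacity(self, params):
        from squidsem import ModelState

        init = ModelState(
            stock=0.2 * params.K, effort=0.0, catch=0.0, market_price=0.0,
            fisher_price=0.0, cooperation=1.0, income_fishers=0.0,
            income_traders=0.0,
        )
        p = params.replace(k_E=0.0)
        traj = simulate("BEM", p, None, init, years=np.arange(0, 300))
        assert traj.column("stock")[-1] == pytest.approx(p.K, rel=1e-6)
        assert np.all(traj.catch == 0.0)
        # zero catch is evaluated at the price floor
        assert traj.market_price[-1] == market_price(0.0, p)

    def test_sem_without_cooperation_reduces_to_edm(self, params, fifty_year_forcing):
        init = default_initial_state(params)
        p_off = params.replace(coop_cap=0.0, p_f_min=0.0, p_f_max=math.inf)
        sem = simulate("SEM", p_off, fifty_year_forcing, init)
        edm = simulate("EDM", p_off, fifty_year_forcing, init)
        np.testing.assert_allclose(
            sem.to_frame().drop(columns="cooperation"),
            edm.to_frame().drop(columns="cooperation"),
            atol=1e-9,
        )

    def test_edm_with_temperate_phenotype_reduces_to_bem(self, params):
        init = default_initial_state(params)
        f = _flat_forcing(params, self.YEARS50, ml=params.ML_max)
        edm = simulate("EDM", params, f, init)
        bem = simulate("BEM", params, f, init)
        np.testing.assert_allclose(
            edm.to_frame().to_numpy(), bem.to_frame().to_numpy(), atol=1e-9
        )

    def test_constant_effort_logistic_closed_form(self, params):
        rng = np.random.default_rng(3)
        for _ in range(5):
            r = rng.uniform(0.2, 1.0)
            qE = rng.uniform(0.1, 0.9) * r
            p = default_parameters(r=r, K=rng.uniform(1e5, 1e6), k_E=0.0)
            stock = 0.5 * p.K
            for _ in range(500):
                stock, _ = step_population(stock, qE / p.q_max, p.q_max, p)
            assert stock == pytest.approx(p.K * (1 - qE / r), rel=1e-3)

    def test_missing_forcing_years_raise(self, params):
        f = _flat_forcing(params, np.arange(2000, 2010), ml=100.0)
        with pytest.raises(ConfigurationError):
            simulate("SEM", params, f, years=np.arange(1995, 2010))

    def test_bem_ignores_forcing(self, params, fifty_year_forcing):
        init = default_initial_state(params)
        a = simulate("BEM", params, fifty_year_forcing, init)
        b = simulate("BEM", params, None, init, years=self.YEARS50)
        np.testing.assert_array_equal(
            a.to_frame().to_numpy(), b.to_frame().to_numpy()
        )

    def test_cooperation_lag_shifts_response(self, params, fifty_year_forcing):
        init = default_initial_state(params)
        lagged = simulate("SEM", params, fifty_year_forcing, init, coop_lag=True)
        coop = lagged.column("cooperation")
        expected = [
            trader_cooperation(
                float(fifty_year_forcing.pacific_prop[max(i - 1, 0)]), params
            )
            for i in range(len(lagged))
        ]
        np.testing.assert_allclose(coop, expected)

    def test_trajectory_csv_schema(self, tmp_path, params, fifty_year_forcing):
        traj = simulate("SEM", params, fifty_year_forcing)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == (
            "year,stock_t,effort,catch_t,market_price_mxn_t,"
            "fisher_price_mxn_t,cooperation,income_fishers_mxn,"
            "income_traders_mxn"
        )


class TestStateInvariants:
    def test_random_parameterizations_respect_invariants(self, fifty_year_forcing):
        """Across random valid parameter draws and 50-year runs, state
        variables stay in their physical ranges."""
        rng = np.random.default_rng(12)
        base = default_parameters()
        for _ in range(40):
            p = base.replace(
                r=rng.uniform(0.2, 1.2),
                K=rng.uniform(2e5, 8e5),
                q_max=rng.uniform(1e-5, 5e-5),
                k_E=rng.uniform(0.0, 5e-6),
                c_E=rng.uniform(3e3, 2e4),
                p0=rng.uniform(6e3, 2e4),
                beta=rng.uniform(1.0, 5.0),
                gamma=rng.uniform(0.0, 8.0),
            )
            for kind in ("BEM", "EDM", "SEM"):
                traj = simulate(kind, p, fifty_year_forcing)
                df = traj.to_frame()
                assert (df["stock_t"] >= 0).all()
                assert (df["effort"] >= 0).all()
                assert (df["catch_t"] >= 0).all()
                assert df["cooperation"].between(0, 1).all()
                comp = np.maximum(
                    df["market_price_mxn_t"] - p.c_proc, 0.0
                )
                assert (
                    df["fisher_price_mxn_t"] <= comp + 1e-9
                ).all()
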