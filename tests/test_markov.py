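"""Cohort engine: matrix validity, traces, discounting, closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mcrc_cea import (
    EconomicConfig,
    InfeasibleStrategyError,
    StateSpec,
    StrategyParams,
    TransitionMatrix,
    ValidationError,
    build_strategy,
    discounted_cost,
    discounted_life_years,
    discounted_outcome,
    run_cohort,
)

ECON = EconomicConfig()


def moab_params(p_progress=0.29, p_death=0.20, p_death_bsc=0.36, name="moab"):
    return StrategyParams(
        name=name, p_death_bsc=p_death_bsc, p_progress=p_progress, p_death_on_tx=p_death
    )


BSC_PARAMS = StrategyParams(name="BSC", p_death_bsc=0.36)


class TestBuildStrategy:
    def test_moab_base_case_row(self):
        matrix = build_strategy(moab_params())
        assert matrix.state_names == ["OnTreatment", "BSC", "Dead"]
        assert matrix.probabilities[0] == pytest.approx([0.51, 0.29, 0.20], abs=1e-15)
        assert matrix.probabilities[1] == pytest.approx([0.0, 0.64, 0.36], abs=1e-15)

    def test_bsc_base_case_row(self):
        matrix = build_strategy(BSC_PARAMS)
        assert matrix.state_names == ["BSC", "Dead"]
        assert matrix.probabilities[0] == pytest.approx([0.64, 0.36], abs=1e-15)

    def test_forced_death_row(self):
        matrix = build_strategy(moab_params(p_progress=0.0, p_death=1.0))
        assert matrix.probabilities[0] == pytest.approx([0.0, 0.0, 1.0], abs=0)

    def test_infeasible_strategy_named_in_error(self):
        with pytest.raises((InfeasibleStrategyError, ValidationError)):
            build_strategy(
                StrategyParams(name="bad", p_death_bsc=0.3, p_progress=0.8, p_death_on_tx=0.3)
            )


class TestMatrixValidation:
    def test_rows_must_be_stochastic(self):
        states = (
            StateSpec("A"),
            StateSpec("Dead", is_absorbing=True, counts_as_alive=False),
        )
        with pytest.raises(ValidationError):
            TransitionMatrix(states, np.array([[0.5, 0.4], [0.0, 1.0]]))

    def test_absorbing_row_must_be_identity(self):
        states = (
            StateSpec("A"),
            StateSpec("Dead", is_absorbing=True, counts_as_alive=False),
        )
        with pytest.raises(ValidationError):
            TransitionMatrix(states, np.array([[0.5, 0.5], [0.1, 0.9]]))

    def test_no_return_from_bsc_to_treatment(self):
        states = (
            StateSpec("OnTreatment"),
            StateSpec("BSC"),
            StateSpec("Dead", is_absorbing=True, counts_as_alive=False),
        )
        probs = np.array([[0.5, 0.3, 0.2], [0.1, 0.6, 0.3], [0.0, 0.0, 1.0]])
        with pytest.raises(ValidationError):
            TransitionMatrix(states, probs)

    def test_exactly_one_absorbing_state(self):
        states = (StateSpec("A"), StateSpec("B"))
        with pytest.raises(ValidationError):
            TransitionMatrix(states, np.eye(2))


class TestCohortTrace:
    def test_bsc_alive_fraction_is_geometric(self):
        trace = run_cohort(build_strategy(BSC_PARAMS), ECON)
        t = np.arange(trace.n_cycles + 1)
        assert trace.alive == pytest.approx(0.64 ** t, abs=1e-12)
        assert trace.extinct

    def test_on_treatment_fraction_is_geometric(self):
        trace = run_cohort(build_strategy(moab_params()), ECON)
        t = np.arange(trace.n_cycles + 1)
        assert trace.occupancy[:, 0] == pytest.approx(0.51 ** t, abs=1e-12)

    def test_occupancy_conserved_every_cycle(self):
        trace = run_cohort(build_strategy(moab_params()), ECON)
        assert np.abs(trace.occupancy.sum(axis=1) - 1.0).max() < 1e-9

    def test_dead_fraction_non_decreasing(self):
        trace = run_cohort(build_strategy(moab_params()), ECON)
        dead = trace.occupancy[:, -1]
        assert np.all(np.diff(dead) >= -1e-15)

    def test_identity_matrix_runs_to_cap_without_extinction(self):
        states = (
            StateSpec("Alive"),
            StateSpec("Dead", is_absorbing=True, counts_as_alive=False),
        )
        matrix = TransitionMatrix(states, np.eye(2))
        trace = run_cohort(matrix, ECON)
        assert not trace.extinct
        assert trace.n_cycles == ECON.horizon_max_cycles
        assert np.all(trace.occupancy[:, 0] == 1.0)

    def test_bad_initial_distribution_rejected(self):
        matrix = build_strategy(BSC_PARAMS)
        with pytest.raises(ValidationError):
            run_cohort(matrix, ECON, initial=[0.5, 0.4])


def geometric_model_ly_closed_form(stay, econ):
    """Brute-force-free oracle: Σ (s·d)^t · cycle_length for the start convention."""
    d = econ.per_cycle_discount_factor
    return econ.cycle_length / (1.0 - stay * d)


class TestDiscounting:
    @pytest.mark.parametrize("stay", [0.2, 0.5, 0.64, 0.8])
    def test_start_convention_matches_geometric_closed_form(self, stay):
        econ = EconomicConfig(horizon_max_cycles=400, extinction_tolerance=1e-16)
        params = StrategyParams(name="g", p_death_bsc=1.0 - stay)
        trace = run_cohort(build_strategy(params), econ)
        engine = discounted_life_years(trace, econ, correction="start")
        assert engine == pytest.approx(geometric_model_ly_closed_form(stay, econ), abs=1e-10)

    def test_half_cycle_lies_between_end_and_start(self):
        trace = run_cohort(build_strategy(moab_params()), ECON)
        start = discounted_life_years(trace, ECON, correction="start")
        end = discounted_life_years(trace, ECON, correction="end")
        half = discounted_life_years(trace, ECON, correction="half_cycle")
        assert end < half < start

    def test_discounted_never_exceeds_undiscounted(self):
        trace = run_cohort(build_strategy(moab_params()), ECON)
        undiscounted = EconomicConfig(annual_discount_rate=0.0)
        for correction in ("start", "end", "half_cycle"):
            assert discounted_life_years(trace, ECON, correction) <= discounted_life_years(
                trace, undiscounted, correction
            )
            costs = {"OnTreatment": 100.0, "BSC": 10.0}
            assert discounted_cost(trace, ECON, costs, correction) <= discounted_cost(
                trace, undiscounted, costs, correction
            )

    def test_zero_discount_immortal_cohort_start_convention(self):
        states = (
            StateSpec("Alive"),
            StateSpec("Dead", is_absorbing=True, counts_as_alive=False),
        )
        matrix = TransitionMatrix(states, np.eye(2))
        econ = EconomicConfig(annual_discount_rate=0.0, horizon_max_cycles=40)
        trace = run_cohort(matrix, econ)
        ly = discounted_life_years(trace, econ, correction="start")
        assert ly == pytest.approx(40 * 0.25, abs=1e-12)

    @given(st.sampled_from([0.0, 0.05, 0.1, 0.2, 0.36, 0.5, 0.71]))
    def test_raising_death_probability_never_raises_life_years(self, p_death):
        # p_progress fixed at 0.29; compare with a strictly higher death probability
        higher = min(p_death + 0.2, 0.71)
        lys = []
        for p in (p_death, higher):
            trace = run_cohort(build_strategy(moab_params(p_death=p)), ECON)
            lys.append(discounted_life_years(trace, ECON))
        assert lys[1] <= lys[0] + 1e-12

    def test_unknown_convention_rejected(self):
        trace = run_cohort(build_strategy(BSC_PARAMS), ECON)
        with pytest.raises(ValidationError):
            discounted_life_years(trace, ECON, correction="middle")


class TestCosts:
    def test_zero_costs_zero_total(self):
        trace = run_cohort(build_strategy(moab_params()), ECON)
        assert discounted_cost(trace, ECON, {}) == 0.0

    def test_single_cycle_cohort_start_accrual_pays_one_cycle(self):
        # immediate death: the only occupancy is the initial state at cycle 0
        params = StrategyParams(name="d", p_death_bsc=1.0)
        econ = EconomicConfig(extinction_tolerance=1e-9)
        trace = run_cohort(build_strategy(params), econ)
        cost = discounted_cost(trace, econ, {"BSC": 321.0}, accrual="start")
        assert cost == pytest.approx(321.0, abs=1e-12)

    def test_negative_cost_rejected(self):
        trace = run_cohort(build_strategy(BSC_PARAMS), ECON)
        with pytest.raises(ValidationError):
            discounted_cost(trace, ECON, {"BSC": -1.0})

    def test_outcome_breakdown_sums_to_totals(self):
        costs = {"OnTreatment": 9402.27, "BSC": 147.18}
        matrix = build_strategy(moab_params(), state_costs=costs)
        trace = run_cohort(matrix, ECON)
        outcome = discounted_outcome(trace, ECON, strategy="moab")
        assert outcome.per_cycle["life_years"].sum() == pytest.approx(outcome.life_years, abs=1e-12)
        assert outcome.per_cycle["cost"].sum() == pytest.approx(outcome.total_cost, abs=1e-9)
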