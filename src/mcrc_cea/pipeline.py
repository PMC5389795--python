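"""End-to-end evaluation of a scenario: costs → Markov cohort → CEA inputs.

This is the single code path every analysis (base case, one-way
sensitivity, threshold-price search) goes through, so a perturbed
scenario is always evaluated exactly like the base case.
"""

from __future__ import annotations

from typing import Optional

from .cea import CEAResult, icer
from .config import Scenario
from .costs import state_cycle_costs
from .errors import ValidationError
from .markov import (
    BSC,
    DEAD,
    ON_TREATMENT,
    CohortTrace,
    DiscountedOutcome,
    build_strategy,
    discounted_outcome,
    run_cohort,
)

__all__ = [
    "strategy_state_costs",
    "evaluate_strategy",
    "evaluate_all",
    "pipeline_icer",
]


def strategy_state_costs(scenario: Scenario, name: str) -> dict[str, float]:
    """Quarterly cost per health state for one strategy.

    The on-treatment state carries the strategy's drug, routine-care and
    adverse-event costs; the BSC state always carries the reference
    strategy's routine-care cost (patients off antibodies receive best
    supportive care regardless of the arm they started in); the dead
    state is free.
    """
    params = scenario.strategy(name)
    reference = scenario.reference_strategy
    bsc_cost = state_cycle_costs(scenario.costs[reference.name]).total
    if not params.has_treatment_state:
        return {BSC: bsc_cost, DEAD: 0.0}
    on_tx = state_cycle_costs(
        scenario.costs[name],
        p_dose_reduction=params.p_dose_reduction or 0.0,
    ).total
    return {ON_TREATMENT: on_tx, BSC: bsc_cost, DEAD: 0.0}


def evaluate_strategy(
    scenario: Scenario, name: str
) -> tuple[CEAResult, CohortTrace, DiscountedOutcome]:
    """Run one strategy's cohort and discount its life-years and costs."""
    params = scenario.strategy(name)
    costs = strategy_state_costs(scenario, name)
    matrix = build_strategy(params, state_costs=costs)
    trace = run_cohort(matrix, scenario.economics)
    outcome = discounted_outcome(
        trace,
        scenario.economics,
        strategy=name,
        ly_correction=scenario.conventions.life_years,
        cost_accrual=scenario.conventions.costs,
    )
    result = CEAResult(
        strategy=name, cost=outcome.total_cost, effectiveness=outcome.life_years
    )
    return result, trace, outcome


def evaluate_all(scenario: Scenario) -> dict[str, CEAResult]:
    return {s.name: evaluate_strategy(scenario, s.name)[0] for s in scenario.strategies}


def pipeline_icer(scenario: Scenario, strategy: str) -> float:
    """ICER of one active strategy against the BSC reference arm."""
    reference = scenario.reference_strategy
    if strategy == reference.name:
        raise ValidationError("the reference strategy has no ICER against itself")
    ref_result, _, _ = evaluate_strategy(scenario, reference.name)
    result, _, _ = evaluate_strategy(scenario, strategy)
    return icer(ref_result, result)
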