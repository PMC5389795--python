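"""Three-state cohort Markov engine in quarterly cycles.

The model tracks a cohort of patients with chemotherapy-refractory
metastatic colorectal cancer through mutually exclusive health states.
An active-treatment strategy has three states — on treatment with a
monoclonal antibody, best supportive care (BSC) after progression, and
dead — while the BSC-only strategy has two (BSC, dead).  Transitions
apply at cycle boundaries; the dead state is absorbing and there is no
return from BSC to treatment.  The cohort is run to a lifetime horizon,
operationalized as the alive mass falling below an extinction tolerance
or a cycle cap, whichever comes first.

Discounted life-years and costs are accumulated under one of three
accrual conventions: ``start`` (occupancy at cycle starts, discounted at
cycle-start times), ``end`` (occupancy at cycle ends, discounted at
cycle-end times) or ``half_cycle`` (their mean — the trapezoidal
half-cycle correction, the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import EconomicConfig, StrategyParams
from .errors import InfeasibleStrategyError, ValidationError

__all__ = [
    "StateSpec",
    "TransitionMatrix",
    "CohortTrace",
    "DiscountedOutcome",
    "build_strategy",
    "run_cohort",
    "discounted_life_years",
    "discounted_cost",
    "discounted_outcome",
    "trace_frame",
]

ROW_SUM_TOL = 1e-12
OCCUPANCY_TOL = 1e-9

ON_TREATMENT = "OnTreatment"
BSC = "BSC"
DEAD = "Dead"


@dataclass(frozen=True)
class StateSpec:
    name: str
    is_absorbing: bool = False
    counts_as_alive: bool = True
    cycle_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.cycle_cost < 0:
            raise ValidationError(f"state {self.name!r}: negative cycle cost")
        if self.is_absorbing and (self.counts_as_alive or self.cycle_cost != 0.0):
            raise ValidationError(
                f"state {self.name!r}: the absorbing (dead) state must be "
                "costless and not count as alive"
            )


@dataclass(frozen=True)
class TransitionMatrix:
    """Ordered states plus a row-stochastic per-cycle probability matrix."""

    states: tuple[StateSpec, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        n = len(self.states)
        if probs.shape != (n, n):
            raise ValidationError(f"probability matrix must be {n}x{n}")
        if np.any(probs < 0.0) or np.any(probs > 1.0):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        row_sums = probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > ROW_SUM_TOL):
            raise ValidationError("every transition-matrix row must sum to 1")
        absorbing = [i for i, s in enumerate(self.states) if s.is_absorbing]
        if len(absorbing) != 1:
            raise ValidationError("exactly one absorbing (dead) state is required")
        i = absorbing[0]
        identity_row = np.zeros(n)
        identity_row[i] = 1.0
        if not np.array_equal(probs[i], identity_row):
            raise ValidationError("the absorbing row must be an identity row")
        names = [s.name for s in self.states]
        if BSC in names and ON_TREATMENT in names:
            if probs[names.index(BSC), names.index(ON_TREATMENT)] != 0.0:
                raise ValidationError("no transition from BSC back to treatment is allowed")

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def alive_mask(self) -> np.ndarray:
        return np.array([s.counts_as_alive for s in self.states])

    @property
    def cycle_costs(self) -> np.ndarray:
        return np.array([s.cycle_cost for s in self.states])


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle; row 0 is the initial distribution."""

    matrix: TransitionMatrix
    occupancy: np.ndarray
    extinct: bool

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > OCCUPANCY_TOL):
            raise ValidationError("occupancy must sum to 1 at every cycle")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        """Alive fraction at each cycle boundary (length n_cycles + 1)."""
        return self.occupancy[:, self.matrix.alive_mask].sum(axis=1)


@dataclass(frozen=True)
class DiscountedOutcome:
    strategy: str
    life_years: float
    total_cost: float
    per_cycle: pd.DataFrame

    def __post_init__(self) -> None:
        if self.life_years < 0 or self.total_cost < 0:
            raise ValidationError("discounted outcomes must be non-negative")


def build_strategy(
    params: StrategyParams,
    state_costs: Optional[Mapping[str, float]] = None,
) -> TransitionMatrix:
    """Build the transition matrix of one strategy.

    Active-treatment strategies yield a 3x3 matrix over
    (OnTreatment, BSC, Dead); the BSC-only strategy a 2x2 over (BSC, Dead).
    ``state_costs`` maps state names to quarterly USD costs (default 0).
    """
    state_costs = dict(state_costs or {})
    p_db = params.p_death_bsc

    def spec(name: str, absorbing: bool = False) -> StateSpec:
        return StateSpec(
            name=name,
            is_absorbing=absorbing,
            counts_as_alive=not absorbing,
            cycle_cost=0.0 if absorbing else state_costs.get(name, 0.0),
        )

    if params.has_treatment_state:
        p_prog, p_die = params.p_progress, params.p_death_on_tx
        stay = 1.0 - p_prog - p_die
        if stay < 0:
            raise InfeasibleStrategyError(
                f"{params.name}: p_progress + p_death_on_tx exceeds 1"
            )
        states = (spec(ON_TREATMENT), spec(BSC), spec(DEAD, absorbing=True))
        probs = np.array(
            [
                [stay, p_prog, p_die],
                [0.0, 1.0 - p_db, p_db],
                [0.0, 0.0, 1.0],
            ]
        )
    else:
        states = (spec(BSC), spec(DEAD, absorbing=True))
        probs = np.array([[1.0 - p_db, p_db], [0.0, 1.0]])
    return TransitionMatrix(states=states, probabilities=probs)


def run_cohort(
    matrix: TransitionMatrix,
    econ: EconomicConfig,
    initial: Optional[Sequence[float]] = None,
) -> CohortTrace:
    """Iterate the cohort until extinction or the cycle cap.

    The cohort enters with full mass in the first state unless ``initial``
    is given.  ``occupancy[t + 1] = occupancy[t] @ matrix``; iteration stops
    once the alive mass drops below ``econ.extinction_tolerance`` or after
    ``econ.horizon_max_cycles`` cycles.
    """
    n = len(matrix.states)
    if initial is None:
        dist = np.zeros(n)
        dist[0] = 1.0
    else:
        dist = np.asarray(initial, dtype=float)
        if dist.shape != (n,) or np.any(dist < 0) or abs(dist.sum() - 1.0) > OCCUPANCY_TOL:
            raise ValidationError("initial distribution must be non-negative and sum to 1")
    alive_mask = matrix.alive_mask
    rows = [dist]
    extinct = dist[alive_mask].sum() < econ.extinction_tolerance
    for _ in range(econ.horizon_max_cycles):
        if extinct:
            break
        dist = dist @ matrix.probabilities
        rows.append(dist)
        extinct = dist[alive_mask].sum() < econ.extinction_tolerance
    return CohortTrace(matrix=matrix, occupancy=np.vstack(rows), extinct=extinct)


def _discount_factors(econ: EconomicConfig, n_boundaries: int) -> np.ndarray:
    """(1 + r)^(−t × cycle_length) at each cycle boundary t = 0 .. n."""
    t = np.arange(n_boundaries)
    return (1.0 + econ.annual_discount_rate) ** (-t * econ.cycle_length)


def _accrue(values: np.ndarray, factors: np.ndarray, convention: str) -> np.ndarray:
    """Per-cycle discounted contributions under an accrual convention.

    ``values`` holds a quantity at each cycle boundary (length n + 1).
    ``start`` takes the boundary opening each cycle (discounted at its
    time), ``end`` the boundary closing it, and ``half_cycle`` the
    trapezoidal mean of the two.
    """
    start = values[:-1] * factors[:-1]
    end = values[1:] * factors[1:]
    if convention == "start":
        return start
    if convention == "end":
        return end
    if convention == "half_cycle":
        return 0.5 * (start + end)
    raise ValidationError(f"unknown accrual convention {convention!r}")


def discounted_life_years(
    trace: CohortTrace, econ: EconomicConfig, correction: str = "half_cycle"
) -> float:
    """Discounted life-years accumulated by the cohort."""
    factors = _discount_factors(econ, trace.n_cycles + 1)
    return float(_accrue(trace.alive, factors, correction).sum() * econ.cycle_length)


def discounted_cost(
    trace: CohortTrace,
    econ: EconomicConfig,
    state_costs: Optional[Mapping[str, float]] = None,
    accrual: str = "half_cycle",
) -> float:
    """Discounted total cost accumulated by the cohort.

    ``state_costs`` overrides the per-cycle costs attached to the states
    (useful for costing the same trace under perturbed prices).
    """
    if state_costs is None:
        costs = trace.matrix.cycle_costs
    else:
        costs = np.array(
            [state_costs.get(s.name, s.cycle_cost) for s in trace.matrix.states]
        )
        if np.any(costs < 0):
            raise ValidationError("state costs must be non-negative")
    per_boundary = trace.occupancy @ costs
    factors = _discount_factors(econ, trace.n_cycles + 1)
    return float(_accrue(per_boundary, factors, accrual).sum())


def discounted_outcome(
    trace: CohortTrace,
    econ: EconomicConfig,
    strategy: str = "",
    ly_correction: str = "half_cycle",
    cost_accrual: str = "half_cycle",
) -> DiscountedOutcome:
    """Life-years and cost with a per-cycle audit breakdown."""
    factors = _discount_factors(econ, trace.n_cycles + 1)
    ly_contrib = _accrue(trace.alive, factors, ly_correction) * econ.cycle_length
    cost_contrib = _accrue(trace.occupancy @ trace.matrix.cycle_costs, factors, cost_accrual)
    per_cycle = pd.DataFrame(
        {
            "cycle": np.arange(trace.n_cycles),
            "discount_factor": factors[:-1],
            "life_years": ly_contrib,
            "cost": cost_contrib,
        }
    )
    return DiscountedOutcome(
        strategy=strategy,
        life_years=float(ly_contrib.sum()),
        total_cost=float(cost_contrib.sum()),
        per_cycle=per_cycle,
    )


def trace_frame(trace: CohortTrace, econ: EconomicConfig) -> pd.DataFrame:
    """Audit table: per-cycle occupancy, discount factor and contributions."""
    factors = _discount_factors(econ, trace.n_cycles + 1)
    data = {"cycle": np.arange(trace.n_cycles + 1)}
    for i, s in enumerate(trace.matrix.states):
        data[s.name] = trace.occupancy[:, i]
    data["alive"] = trace.alive
    data["discount_factor"] = factors
    return pd.DataFrame(data)
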