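"""One-way sensitivity analysis, tornado ordering and threshold price search.

Each parameter is perturbed to its low and high bound with everything else
held at baseline; the full pipeline (costs → Markov → ICER against BSC) is
re-run at each bound and the two ICERs and their absolute span are
reported.  A tornado is the per-parameter spans sorted descending.

The threshold-price search bisects a drug's vial price between given
bounds until the strategy's ICER against BSC equals the willingness-to-pay
threshold (within $1 per life-year).  The vial count is held fixed at its
base-case value during the search so the ICER is continuous and strictly
increasing in price; body-surface and body-weight perturbations in the
tornado, by contrast, re-trigger the vial ceiling and may therefore
produce step changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import Scenario, SensitivityRange
from .errors import BracketingError, ValidationError
from .pipeline import pipeline_icer

__all__ = [
    "TornadoEntry",
    "apply_parameter",
    "one_way",
    "tornado",
    "threshold_price",
]

#: Convergence tolerance of the threshold-price bisection, in USD per
#: life-year on the ICER scale (~4e-5 of the threshold itself).
ICER_TOL = 1.0
MAX_BISECTIONS = 100

_TRANSITION_FIELDS = {"p_progress", "p_death_on_tx", "p_death_bsc", "p_dose_reduction"}
_SCHEDULE_FIELDS = {"vial_unit_price", "body_surface", "body_weight", "dose", "vial_size"}


def apply_parameter(scenario: Scenario, parameter: str, value: float) -> Scenario:
    """Return a copy of the scenario with one parameter set to ``value``.

    ``parameter`` is either a bare transition-probability name (applied to
    every strategy that has the field) or ``<strategy>.<field>`` where the
    field is a transition probability or a dose-schedule field.
    """
    new = scenario.copy()
    if "." in parameter:
        strategy_name, field_name = parameter.split(".", 1)
        targets = [new.strategy(strategy_name)]
    else:
        field_name = parameter
        targets = [
            s for s in new.strategies if getattr(s, field_name, None) is not None
        ] if field_name in _TRANSITION_FIELDS else []
        if not targets and field_name not in _SCHEDULE_FIELDS:
            raise ValidationError(f"cannot resolve parameter {parameter!r}")
    if field_name in _TRANSITION_FIELDS:
        for params in targets:
            idx = new.strategies.index(params)
            new.strategies[idx] = dataclasses.replace(params, **{field_name: value})
        return new
    if field_name in _SCHEDULE_FIELDS:
        if "." not in parameter:
            raise ValidationError(
                f"dose-schedule parameter {field_name!r} must be strategy-qualified"
            )
        inputs = new.costs[strategy_name]
        if inputs.dose_schedule is None:
            raise ValidationError(f"{strategy_name} has no dose schedule")
        schedule = dataclasses.replace(inputs.dose_schedule, **{field_name: value})
        new.costs[strategy_name] = dataclasses.replace(inputs, dose_schedule=schedule)
        return new
    raise ValidationError(f"cannot resolve parameter {parameter!r}")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    strategy: str
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(
    srange: SensitivityRange,
    scenario: Scenario,
    strategy: Optional[str] = None,
) -> TornadoEntry:
    """Re-run the pipeline at the low and high bound of one parameter.

    ``strategy`` is the arm whose ICER against BSC is tracked; it defaults
    to the range's own strategy and finally to the first active strategy.
    """
    arm = strategy or srange.icer_strategy
    if arm is None:
        arm = scenario.active_strategies[0].name
    low = pipeline_icer(apply_parameter(scenario, srange.parameter, srange.low), arm)
    high = pipeline_icer(apply_parameter(scenario, srange.parameter, srange.high), arm)
    return TornadoEntry(
        parameter=srange.parameter, strategy=arm, icer_at_low=low, icer_at_high=high
    )


def tornado(
    ranges: Sequence[SensitivityRange],
    scenario: Scenario,
) -> list[TornadoEntry]:
    """One-way analysis of every range, sorted descending by ICER span.

    The sort is stable: entries with equal spans keep their input order.
    """
    if not ranges:
        raise ValidationError("tornado needs at least one sensitivity range")
    entries = [one_way(r, scenario) for r in ranges]
    return sorted(entries, key=lambda e: -e.span)


def _fixed_vial_icer(scenario: Scenario, strategy: str, price: float) -> float:
    """Pipeline ICER with the vial count frozen at its base-case value."""
    inputs = scenario.costs[strategy]
    schedule = inputs.dose_schedule
    if schedule is None:
        raise ValidationError(f"{strategy} has no dose schedule to reprice")
    # the vial count depends only on dose and vial size, neither of which is
    # touched here, so it stays at its base-case value throughout the search
    perturbed = scenario.copy()
    new_schedule = dataclasses.replace(schedule, vial_unit_price=price)
    perturbed.costs[strategy] = dataclasses.replace(inputs, dose_schedule=new_schedule)
    return pipeline_icer(perturbed, strategy)


def threshold_price(
    strategy: str,
    scenario: Scenario,
    price_bounds: Optional[tuple[float, float]] = None,
) -> tuple[float, float]:
    """Vial price at which the strategy's ICER equals the WTP threshold.

    Bisects between ``price_bounds`` (default: 0 to the base-case price)
    until |ICER − threshold| < $1 per life-year or 100 iterations, and
    returns ``(price, reduction_percent)`` where the reduction is relative
    to the base-case vial price.
    """
    schedule = scenario.costs[strategy].dose_schedule
    if schedule is None:
        raise ValidationError(f"{strategy} has no dose schedule")
    baseline_price = schedule.vial_unit_price
    lo, hi = price_bounds if price_bounds is not None else (0.0, baseline_price)
    if not 0.0 <= lo < hi:
        raise ValidationError("price bounds must satisfy 0 <= low < high")
    wtp = scenario.economics.wtp_threshold
    f_lo = _fixed_vial_icer(scenario, strategy, lo) - wtp
    f_hi = _fixed_vial_icer(scenario, strategy, hi) - wtp
    if f_lo > 0 or f_hi < 0:
        raise BracketingError(
            f"{strategy}: ICER does not bracket the threshold on "
            f"[{lo}, {hi}] (f(low)={f_lo:+.2f}, f(high)={f_hi:+.2f})"
        )
    price = 0.5 * (lo + hi)
    for _ in range(MAX_BISECTIONS):
        f_mid = _fixed_vial_icer(scenario, strategy, price) - wtp
        if abs(f_mid) < ICER_TOL:
            break
        if f_mid > 0:
            hi = price
        else:
            lo = price
        price = 0.5 * (lo + hi)
    reduction = 100.0 * (1.0 - price / baseline_price)
    return price, reduction
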