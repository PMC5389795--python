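"""Per-cycle, per-state cost construction.

Drug acquisition costs are built bottom-up from vial arithmetic: the total
dose per administration is derived from body surface area (cetuximab,
mg/m²) or body weight (panitumumab, mg/kg), rounded *up* to whole
100 mg vials (no vial sharing, no wastage discount), priced per vial and
multiplied by the number of administrations per quarterly cycle (six, i.e.
biweekly dosing).  Routine-care resources (outpatient appointments,
laboratory tests, imaging, hospitalization) enter as fixed quarterly
amounts per health state, and grade-3/4 adverse-event management enters the
on-treatment state as an expected hospitalization cost per cycle.

All monetary amounts are US dollars at full floating precision; rounding to
cents happens only in the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

from .errors import ValidationError

__all__ = [
    "DoseSchedule",
    "AdverseEvent",
    "AdverseEventProfile",
    "StateCycleCosts",
    "CostInputs",
    "total_dose",
    "vials_per_administration",
    "cost_per_administration",
    "moab_cycle_cost",
    "expected_ae_cost",
    "state_cycle_costs",
]

RESOURCE_COMPONENTS = ("outpatient", "laboratory", "imaging", "hospitalization")


@dataclass(frozen=True)
class DoseSchedule:
    """Dosing and vial-pricing inputs for one monoclonal antibody.

    ``dose`` is mg per m² when ``dose_basis`` is ``per_body_surface``
    and mg per kg when it is ``per_weight``.
    """

    dose_basis: Literal["per_body_surface", "per_weight"]
    dose: float
    vial_unit_price: float
    body_surface: float = 1.75
    body_weight: float = 70.0
    vial_size: float = 100.0
    administrations_per_cycle: int = 6

    def __post_init__(self) -> None:
        if self.dose_basis not in ("per_body_surface", "per_weight"):
            raise ValidationError(f"unknown dose_basis {self.dose_basis!r}")
        for name in ("dose", "body_surface", "body_weight", "vial_size"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"DoseSchedule.{name} must be positive")
        if self.vial_unit_price < 0:
            raise ValidationError("vial_unit_price must be non-negative")
        if self.administrations_per_cycle < 1 or int(self.administrations_per_cycle) != self.administrations_per_cycle:
            raise ValidationError("administrations_per_cycle must be an integer >= 1")


@dataclass(frozen=True)
class AdverseEvent:
    name: str
    probability: float
    unit_cost: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(f"adverse event {self.name!r}: probability outside [0, 1]")
        if self.unit_cost is not None and self.unit_cost < 0:
            raise ValidationError(f"adverse event {self.name!r}: negative unit cost")


@dataclass(frozen=True)
class AdverseEventProfile:
    """Grade-3/4 adverse events that require hospitalization.

    The published aggregate (average hospitalization cost per quarterly
    cycle) is carried as ``average_cycle_cost``; per-event unit costs are
    optional and, when supplied for every event, take precedence via the
    expectation Σ probability × unit cost.
    """

    events: tuple[AdverseEvent, ...] = ()
    average_cycle_cost: Optional[float] = None

    def __post_init__(self) -> None:
        if self.average_cycle_cost is not None and self.average_cycle_cost < 0:
            raise ValidationError("average_cycle_cost must be non-negative")


@dataclass(frozen=True)
class StateCycleCosts:
    """Quarterly cost of one health state, broken down by component."""

    moab: float = 0.0
    outpatient: float = 0.0
    laboratory: float = 0.0
    imaging: float = 0.0
    hospitalization: float = 0.0
    adverse_event: float = 0.0

    def __post_init__(self) -> None:
        for name in ("moab", *RESOURCE_COMPONENTS, "adverse_event"):
            if getattr(self, name) < 0:
                raise ValidationError(f"StateCycleCosts.{name} must be non-negative")

    @property
    def total(self) -> float:
        return (
            self.moab
            + self.outpatient
            + self.laboratory
            + self.imaging
            + self.hospitalization
            + self.adverse_event
        )


@dataclass(frozen=True)
class CostInputs:
    """Everything needed to cost one strategy.

    ``resources`` maps the four routine-care components to quarterly USD
    amounts.  ``dose_schedule`` and ``adverse_events`` are absent for the
    best-supportive-care strategy.  ``printed_moab_cycle_cost`` and
    ``printed_state_total`` record the published quarterly figures for
    cross-checking; they are never used in computation.
    ``dose_reduction_fraction`` scales how strongly the per-cycle
    dose-reduction probability discounts drug cost (default 0: dose
    reductions do not change base-case cost).
    """

    strategy: str
    resources: Mapping[str, float] = field(default_factory=dict)
    dose_schedule: Optional[DoseSchedule] = None
    adverse_events: Optional[AdverseEventProfile] = None
    dose_reduction_fraction: float = 0.0
    printed_moab_cycle_cost: Optional[float] = None
    printed_state_total: Optional[float] = None

    def __post_init__(self) -> None:
        for name, value in self.resources.items():
            if name not in RESOURCE_COMPONENTS:
                raise ValidationError(f"unknown resource component {name!r}")
            if value < 0:
                raise ValidationError(f"resource {name!r} must be non-negative")
        if not 0.0 <= self.dose_reduction_fraction <= 1.0:
            raise ValidationError("dose_reduction_fraction must be in [0, 1]")


def total_dose(schedule: DoseSchedule) -> float:
    """Total drug amount (mg) per administration for the average patient."""
    if schedule.dose_basis == "per_body_surface":
        return schedule.dose * schedule.body_surface
    return schedule.dose * schedule.body_weight


def vials_per_administration(total_dose_mg: float, vial_size_mg: float) -> int:
    """Smallest vial count covering the dose (round up, no vial sharing)."""
    if total_dose_mg < 0 or vial_size_mg <= 0:
        raise ValidationError("dose must be >= 0 and vial size > 0")
    if total_dose_mg == 0:
        return 0
    count = math.ceil(total_dose_mg / vial_size_mg)
    # guard against float division landing on the wrong side of an integer
    while count * vial_size_mg < total_dose_mg:
        count += 1
    while count > 1 and (count - 1) * vial_size_mg >= total_dose_mg:
        count -= 1
    return count


def cost_per_administration(schedule: DoseSchedule) -> float:
    """USD drug cost of a single administration (whole vials)."""
    vials = vials_per_administration(total_dose(schedule), schedule.vial_size)
    return vials * schedule.vial_unit_price


def moab_cycle_cost(schedule: DoseSchedule) -> float:
    """USD drug cost per quarterly cycle (all administrations)."""
    return cost_per_administration(schedule) * schedule.administrations_per_cycle


def expected_ae_cost(profile: AdverseEventProfile) -> float:
    """Expected adverse-event hospitalization cost per quarterly cycle.

    Uses Σ probability × unit cost when per-event unit costs are
    supplied for every event, otherwise falls back to the published
    aggregate average.
    """
    if profile.events and all(e.unit_cost is not None for e in profile.events):
        return sum(e.probability * e.unit_cost for e in profile.events)  # type: ignore[operator]
    if profile.average_cycle_cost is not None:
        return profile.average_cycle_cost
    raise ValidationError(
        "adverse-event profile needs either per-event unit costs or an aggregate average_cycle_cost"
    )


def _resource_total(inputs: CostInputs) -> float:
    return sum(inputs.resources.get(name, 0.0) for name in RESOURCE_COMPONENTS)


def state_cycle_costs(
    inputs: CostInputs,
    p_dose_reduction: float = 0.0,
) -> StateCycleCosts:
    """Quarterly cost of the strategy's active (drug- or care-receiving) state.

    For an antibody strategy this is the on-treatment state: vial-level drug
    cost (optionally discounted by ``p_dose_reduction ×
    dose_reduction_fraction``), routine-care resources, and the expected
    adverse-event cost.  For best supportive care it is the BSC state
    (routine care only).  The dead state always costs zero.
    """
    if not 0.0 <= p_dose_reduction <= 1.0:
        raise ValidationError("p_dose_reduction must be in [0, 1]")
    moab = 0.0
    if inputs.dose_schedule is not None:
        moab = moab_cycle_cost(inputs.dose_schedule)
        moab *= 1.0 - p_dose_reduction * inputs.dose_reduction_fraction
    ae = 0.0
    if inputs.adverse_events is not None:
        ae = expected_ae_cost(inputs.adverse_events)
    return StateCycleCosts(
        moab=moab,
        outpatient=inputs.resources.get("outpatient", 0.0),
        laboratory=inputs.resources.get("laboratory", 0.0),
        imaging=inputs.resources.get("imaging", 0.0),
        hospitalization=inputs.resources.get("hospitalization", 0.0),
        adverse_event=ae,
    )


def cost_breakdown_rows(all_inputs: Sequence[CostInputs]) -> list[dict]:
    """Rows mirroring the published quarterly-cost table, one per strategy."""
    rows = []
    for inputs in all_inputs:
        costs = state_cycle_costs(inputs)
        row = {"strategy": inputs.strategy, "moab": costs.moab}
        for name in RESOURCE_COMPONENTS:
            row[name] = getattr(costs, name)
        row["adverse_event"] = costs.adverse_event
        row["total"] = costs.total
        rows.append(row)
    return rows
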