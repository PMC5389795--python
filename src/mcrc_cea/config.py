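"""Scenario configuration: schema, validation, and the bundled base case.

A scenario is a single human-editable YAML document holding the economic
assumptions (quarterly cycles, 5% annual discount, willingness-to-pay
threshold of three times GDP per capita), the per-strategy transition
probabilities, the cost inputs for each strategy, and the one-way
sensitivity ranges.  ``fixtures/base_case.yaml`` encodes the published
Brazilian public-payer base case for cetuximab, panitumumab and best
supportive care (BSC); it is package data, loadable with
:func:`load_base_case`.

Unknown keys are rejected so that typos never silently fall back to
defaults.  All stored monetary values are USD (the BRL→USD exchange rate is
recorded as metadata only and never applied at runtime).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional, Union

import yaml

from .costs import (
    AdverseEvent,
    AdverseEventProfile,
    CostInputs,
    DoseSchedule,
)
from .errors import SchemaError, ValidationError

__all__ = [
    "EconomicConfig",
    "StrategyParams",
    "Conventions",
    "SensitivityRange",
    "Scenario",
    "load_config",
    "load_base_case",
    "save_config",
    "BASE_CASE_FIXTURE",
]

Convention = Literal["start", "end", "half_cycle"]
CONVENTIONS = ("start", "end", "half_cycle")

BASE_CASE_FIXTURE = "base_case"


@dataclass(frozen=True)
class EconomicConfig:
    """Economic assumptions shared by every strategy.

    ``wtp_threshold`` is stored as published rather than recomputed from
    ``gdp_per_capita`` (the two disagree by $1: 3 × 8,250 = 24,750 vs the
    printed 24,751).  ``exchange_rate`` (BRL per USD) is informational.
    """

    cycle_length: float = 0.25
    annual_discount_rate: float = 0.05
    gdp_per_capita: float = 8250.0
    wtp_threshold: float = 24751.0
    exchange_rate: float = 3.50
    horizon_max_cycles: int = 200
    extinction_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ValidationError("annual_discount_rate must be in [0, 1)")
        if self.cycle_length <= 0:
            raise ValidationError("cycle_length must be positive")
        if self.wtp_threshold <= 0:
            raise ValidationError("wtp_threshold must be positive")
        if self.horizon_max_cycles < 1:
            raise ValidationError("horizon_max_cycles must be >= 1")
        if not 0.0 < self.extinction_tolerance < 1.0:
            raise ValidationError("extinction_tolerance must be in (0, 1)")

    @property
    def per_cycle_discount_factor(self) -> float:
        """Compound per-cycle factor: (1 + r)^(−cycle_length)."""
        return (1.0 + self.annual_discount_rate) ** (-self.cycle_length)


@dataclass(frozen=True)
class StrategyParams:
    """Per-cycle transition probabilities of one strategy.

    ``p_progress`` and ``p_death_on_tx`` are ``None`` for the BSC-only
    strategy (no on-treatment state).  ``p_dose_reduction`` is carried for
    the sensitivity analysis; it does not alter base-case transitions.
    """

    name: str
    p_death_bsc: float
    p_progress: Optional[float] = None
    p_death_on_tx: Optional[float] = None
    p_dose_reduction: Optional[float] = None

    def __post_init__(self) -> None:
        for label in ("p_death_bsc", "p_progress", "p_death_on_tx", "p_dose_reduction"):
            value = getattr(self, label)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValidationError(f"{self.name}: {label}={value} outside [0, 1]")
        if (self.p_progress is None) != (self.p_death_on_tx is None):
            raise ValidationError(
                f"{self.name}: p_progress and p_death_on_tx must be given together"
            )
        if self.p_progress is not None and self.p_progress + self.p_death_on_tx > 1.0:
            raise ValidationError(
                f"{self.name}: p_progress + p_death_on_tx > 1"
            )

    @property
    def has_treatment_state(self) -> bool:
        return self.p_progress is not None


@dataclass(frozen=True)
class Conventions:
    """Accrual conventions for life-years and costs.

    ``start`` counts state occupancy at cycle starts (discounted at the
    cycle-start time), ``end`` at cycle ends (discounted at the cycle-end
    time), and ``half_cycle`` is their arithmetic mean (trapezoidal
    half-cycle correction, the default for both quantities).
    """

    life_years: Convention = "half_cycle"
    costs: Convention = "half_cycle"

    def __post_init__(self) -> None:
        for label in ("life_years", "costs"):
            if getattr(self, label) not in CONVENTIONS:
                raise ValidationError(f"unknown convention {getattr(self, label)!r}")


@dataclass(frozen=True)
class SensitivityRange:
    """One-way perturbation range for a single parameter.

    ``parameter`` is either a shared transition-probability name
    (``p_progress``, ``p_death_on_tx``) or a strategy-qualified field such
    as ``cetuximab.vial_unit_price``.  ``strategy`` names the arm whose
    ICER against BSC is tracked (defaults to the qualified strategy).
    """

    parameter: str
    baseline: float
    low: float
    high: float
    strategy: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.low <= self.baseline <= self.high:
            raise ValidationError(
                f"{self.parameter}: require low <= baseline <= high"
            )
        if self.parameter.split(".")[-1].startswith("p_") and not (
            self.low >= 0.0 and self.high <= 1.0
        ):
            raise ValidationError(f"{self.parameter}: probability range outside [0, 1]")

    @property
    def icer_strategy(self) -> Optional[str]:
        if self.strategy is not None:
            return self.strategy
        if "." in self.parameter:
            return self.parameter.split(".", 1)[0]
        return None


@dataclass
class Scenario:
    """A fully validated model scenario (economics + strategies + costs)."""

    economics: EconomicConfig
    strategies: list[StrategyParams]
    costs: dict[str, CostInputs]
    sensitivity_ranges: list[SensitivityRange] = field(default_factory=list)
    conventions: Conventions = field(default_factory=Conventions)
    name: str = "scenario"

    def __post_init__(self) -> None:
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate strategy names")
        for n in names:
            if n not in self.costs:
                raise ValidationError(f"strategy {n!r} has no cost inputs")
        if not any(not s.has_treatment_state for s in self.strategies):
            raise ValidationError("a BSC-only reference strategy is required")

    def strategy(self, name: str) -> StrategyParams:
        for s in self.strategies:
            if s.name == name:
                return s
        raise ValidationError(f"unknown strategy {name!r}")

    @property
    def reference_strategy(self) -> StrategyParams:
        """The BSC-only arm (the comparator for all ICERs)."""
        return next(s for s in self.strategies if not s.has_treatment_state)

    @property
    def active_strategies(self) -> list[StrategyParams]:
        return [s for s in self.strategies if s.has_treatment_state]

    def copy(self) -> "Scenario":
        return copy.deepcopy(self)


# --------------------------------------------------------------------------
# schema helpers

def _check_keys(mapping: dict, allowed: set[str], required: set[str], where: str) -> None:
    if not isinstance(mapping, dict):
        raise SchemaError(f"{where}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"{where}: unknown key(s) {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise SchemaError(f"{where}: missing required key(s) {sorted(missing)}")


def _parse_economics(raw: dict) -> EconomicConfig:
    allowed = {
        "cycle_length_years",
        "annual_discount_rate",
        "gdp_per_capita_usd",
        "wtp_threshold_usd_per_ly",
        "exchange_rate_brl_per_usd",
        "horizon_max_cycles",
        "extinction_tolerance",
    }
    _check_keys(raw, allowed, set(), "economics")
    kwargs = {}
    rename = {
        "cycle_length_years": "cycle_length",
        "gdp_per_capita_usd": "gdp_per_capita",
        "wtp_threshold_usd_per_ly": "wtp_threshold",
        "exchange_rate_brl_per_usd": "exchange_rate",
    }
    for key, value in raw.items():
        kwargs[rename.get(key, key)] = value
    return EconomicConfig(**kwargs)


def _parse_dose_schedule(raw: dict, where: str) -> DoseSchedule:
    allowed = {
        "dose_basis",
        "dose_mg",
        "body_surface_m2",
        "body_weight_kg",
        "vial_size_mg",
        "vial_unit_price_usd",
        "administrations_per_cycle",
    }
    _check_keys(raw, allowed, {"dose_basis", "dose_mg", "vial_unit_price_usd"}, where)
    kwargs = {
        "dose_basis": raw["dose_basis"],
        "dose": raw["dose_mg"],
        "vial_unit_price": raw["vial_unit_price_usd"],
    }
    if "body_surface_m2" in raw:
        kwargs["body_surface"] = raw["body_surface_m2"]
    if "body_weight_kg" in raw:
        kwargs["body_weight"] = raw["body_weight_kg"]
    if "vial_size_mg" in raw:
        kwargs["vial_size"] = raw["vial_size_mg"]
    if "administrations_per_cycle" in raw:
        kwargs["administrations_per_cycle"] = raw["administrations_per_cycle"]
    return DoseSchedule(**kwargs)


def _parse_adverse_events(raw: dict, where: str) -> AdverseEventProfile:
    allowed = {"average_cycle_cost_usd", "events"}
    _check_keys(raw, allowed, set(), where)
    events = []
    for i, ev in enumerate(raw.get("events", [])):
        _check_keys(ev, {"name", "probability", "unit_cost_usd"}, {"name", "probability"}, f"{where}.events[{i}]")
        events.append(
            AdverseEvent(
                name=ev["name"],
                probability=ev["probability"],
                unit_cost=ev.get("unit_cost_usd"),
            )
        )
    return AdverseEventProfile(
        events=tuple(events),
        average_cycle_cost=raw.get("average_cycle_cost_usd"),
    )


def _parse_strategy(raw: dict, index: int) -> tuple[StrategyParams, CostInputs]:
    where = f"strategies[{index}]"
    _check_keys(raw, {"name", "transitions", "costs"}, {"name", "transitions", "costs"}, where)
    name = raw["name"]
    trans = raw["transitions"]
    _check_keys(
        trans,
        {"p_death_bsc", "p_progress", "p_death_on_tx", "p_dose_reduction"},
        {"p_death_bsc"},
        f"{where}.transitions",
    )
    params = StrategyParams(name=name, **trans)

    craw = raw["costs"]
    allowed = {
        "resources",
        "dose_schedule",
        "adverse_events",
        "dose_reduction_fraction",
        "printed_moab_cycle_cost_usd",
        "printed_state_total_usd",
    }
    _check_keys(craw, allowed, {"resources"}, f"{where}.costs")
    schedule = None
    if "dose_schedule" in craw:
        schedule = _parse_dose_schedule(craw["dose_schedule"], f"{where}.costs.dose_schedule")
    ae = None
    if "adverse_events" in craw:
        ae = _parse_adverse_events(craw["adverse_events"], f"{where}.costs.adverse_events")
    inputs = CostInputs(
        strategy=name,
        resources=dict(craw["resources"]),
        dose_schedule=schedule,
        adverse_events=ae,
        dose_reduction_fraction=craw.get("dose_reduction_fraction", 0.0),
        printed_moab_cycle_cost=craw.get("printed_moab_cycle_cost_usd"),
        printed_state_total=craw.get("printed_state_total_usd"),
    )
    return params, inputs


def _parse_sensitivity(raw: dict) -> list[SensitivityRange]:
    _check_keys(raw, {"ranges"}, {"ranges"}, "sensitivity")
    ranges = []
    for i, entry in enumerate(raw["ranges"]):
        _check_keys(
            entry,
            {"parameter", "baseline", "low", "high", "strategy"},
            {"parameter", "baseline", "low", "high"},
            f"sensitivity.ranges[{i}]",
        )
        ranges.append(SensitivityRange(**entry))
    return ranges


def parse_config(raw: dict, name: str = "scenario") -> Scenario:
    """Validate a raw configuration mapping into a :class:`Scenario`."""
    allowed = {"schema_version", "name", "economics", "conventions", "strategies", "sensitivity"}
    _check_keys(raw, allowed, {"strategies"}, "config")
    version = raw.get("schema_version", 1)
    if version != 1:
        raise SchemaError(f"unsupported schema_version {version}")
    economics = _parse_economics(raw.get("economics", {}))
    conventions = Conventions()
    if "conventions" in raw:
        _check_keys(raw["conventions"], {"life_years", "costs"}, set(), "conventions")
        conventions = Conventions(**raw["conventions"])
    strategies: list[StrategyParams] = []
    costs: dict[str, CostInputs] = {}
    for i, sraw in enumerate(raw["strategies"]):
        params, inputs = _parse_strategy(sraw, i)
        strategies.append(params)
        costs[params.name] = inputs
    ranges = _parse_sensitivity(raw["sensitivity"]) if "sensitivity" in raw else []
    return Scenario(
        economics=economics,
        strategies=strategies,
        costs=costs,
        sensitivity_ranges=ranges,
        conventions=conventions,
        name=raw.get("name", name),
    )


def load_config(path: Union[str, Path]) -> Scenario:
    """Load and validate a scenario from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise SchemaError(f"config file is empty: {path}")
    return parse_config(raw, name=path.stem)


def load_base_case() -> Scenario:
    """Load the bundled published base-case scenario."""
    ref = importlib.resources.files("mcrc_cea") / "fixtures" / f"{BASE_CASE_FIXTURE}.yaml"
    raw = yaml.safe_load(ref.read_text())
    return parse_config(raw, name=BASE_CASE_FIXTURE)


def scenario_to_raw(scenario: Scenario) -> dict:
    """Serialize a scenario back to the documented YAML schema."""
    econ = scenario.economics
    raw: dict = {
        "schema_version": 1,
        "name": scenario.name,
        "economics": {
            "cycle_length_years": econ.cycle_length,
            "annual_discount_rate": econ.annual_discount_rate,
            "gdp_per_capita_usd": econ.gdp_per_capita,
            "wtp_threshold_usd_per_ly": econ.wtp_threshold,
            "exchange_rate_brl_per_usd": econ.exchange_rate,
            "horizon_max_cycles": econ.horizon_max_cycles,
            "extinction_tolerance": econ.extinction_tolerance,
        },
        "conventions": {
            "life_years": scenario.conventions.life_years,
            "costs": scenario.conventions.costs,
        },
        "strategies": [],
    }
    for params in scenario.strategies:
        inputs = scenario.costs[params.name]
        trans = {"p_death_bsc": params.p_death_bsc}
        for label in ("p_progress", "p_death_on_tx", "p_dose_reduction"):
            value = getattr(params, label)
            if value is not None:
                trans[label] = value
        craw: dict = {"resources": dict(inputs.resources)}
        if inputs.dose_schedule is not None:
            ds = inputs.dose_schedule
            dsr = {
                "dose_basis": ds.dose_basis,
                "dose_mg": ds.dose,
                "vial_size_mg": ds.vial_size,
                "vial_unit_price_usd": ds.vial_unit_price,
                "administrations_per_cycle": ds.administrations_per_cycle,
            }
            if ds.dose_basis == "per_body_surface":
                dsr["body_surface_m2"] = ds.body_surface
            else:
                dsr["body_weight_kg"] = ds.body_weight
            craw["dose_schedule"] = dsr
        if inputs.adverse_events is not None:
            ae = inputs.adverse_events
            aer: dict = {}
            if ae.average_cycle_cost is not None:
                aer["average_cycle_cost_usd"] = ae.average_cycle_cost
            if ae.events:
                aer["events"] = [
                    {"name": e.name, "probability": e.probability}
                    | ({"unit_cost_usd": e.unit_cost} if e.unit_cost is not None else {})
                    for e in ae.events
                ]
            craw["adverse_events"] = aer
        if inputs.dose_reduction_fraction:
            craw["dose_reduction_fraction"] = inputs.dose_reduction_fraction
        if inputs.printed_moab_cycle_cost is not None:
            craw["printed_moab_cycle_cost_usd"] = inputs.printed_moab_cycle_cost
        if inputs.printed_state_total is not None:
            craw["printed_state_total_usd"] = inputs.printed_state_total
        raw["strategies"].append({"name": params.name, "transitions": trans, "costs": craw})
    if scenario.sensitivity_ranges:
        raw["sensitivity"] = {
            "ranges": [
                {k: v for k, v in asdict(r).items() if v is not None}
                for r in scenario.sensitivity_ranges
            ]
        }
    return raw


def save_config(scenario: Scenario, path: Union[str, Path]) -> None:
    """Write a scenario to YAML such that ``load_config`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_raw(scenario), fh, sort_keys=False)
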