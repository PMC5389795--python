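"""Run orchestration and report writers.

``run_base_case`` executes the full pipeline for every strategy in a
scenario and assembles a cost-effectiveness table (the published table's
shape: cost, incremental cost, effectiveness, incremental effectiveness,
ICER, dominance) plus per-strategy willingness-to-pay verdicts.
``run_sensitivity`` adds the tornado or threshold-price sections.

Human-readable output rounds money to cents and life-years to four
decimals; the JSON report keeps full precision.  Two runs of the same
configuration produce identical reports except for the timestamp field.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__ as _pkg_version
from .cea import CEATable, icer, rank_strategies, threshold_verdict
from .config import Scenario, load_config, scenario_to_raw
from .costs import cost_breakdown_rows
from .errors import ValidationError
from .markov import trace_frame
from .pipeline import evaluate_strategy
from .sensitivity import TornadoEntry, threshold_price, tornado

__all__ = ["RunReport", "run_base_case", "run_sensitivity", "write_report"]


@dataclass
class RunReport:
    """Everything one run computed, plus the configuration that produced it."""

    scenario: Scenario
    cea_table: CEATable
    verdicts: dict[str, dict]
    traces: dict[str, pd.DataFrame] = field(default_factory=dict)
    tornado: Optional[list[TornadoEntry]] = None
    threshold_prices: Optional[dict[str, dict]] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {
            "config_echo": scenario_to_raw(self.scenario),
            "cea_table": [
                {
                    "strategy": r.result.strategy,
                    "cost": r.result.cost,
                    "incremental_cost": r.incremental_cost,
                    "effectiveness": r.result.effectiveness,
                    "incremental_effectiveness": r.incremental_effectiveness,
                    "icer": r.icer,
                    "dominance": r.dominance,
                }
                for r in self.cea_table.rows
            ],
            "verdicts": self.verdicts,
            "provenance": self.provenance,
        }
        if self.tornado is not None:
            out["tornado"] = [
                {
                    "parameter": e.parameter,
                    "strategy": e.strategy,
                    "icer_at_low": e.icer_at_low,
                    "icer_at_high": e.icer_at_high,
                    "span": e.span,
                }
                for e in self.tornado
            ]
        if self.threshold_prices is not None:
            out["threshold_prices"] = self.threshold_prices
        return out

    def summary_text(self) -> str:
        lines = [f"scenario: {self.scenario.name}", ""]
        frame = self.cea_table.to_frame()
        display = frame.copy()
        for col in ("cost", "incremental_cost", "icer"):
            display[col] = display[col].map(
                lambda v: "-" if pd.isna(v) else f"{v:,.2f}"
            )
        for col in ("effectiveness", "incremental_effectiveness"):
            display[col] = display[col].map(
                lambda v: "-" if pd.isna(v) else f"{v:.4f}"
            )
        lines.append(display.to_string(index=False))
        lines.append("")
        for name, verdict in self.verdicts.items():
            flag = "cost-effective" if verdict["cost_effective"] else "NOT cost-effective"
            lines.append(
                f"{name}: ICER vs {verdict['reference']} = "
                f"{verdict['icer_vs_reference']:,.2f} $/LY -> {flag} "
                f"(exceeds threshold by {verdict['exceedance_percent']:.1f}%)"
            )
        if self.tornado:
            lines += ["", "tornado (descending ICER span, $/LY):"]
            for e in self.tornado:
                lines.append(
                    f"  {e.parameter:<35s} [{e.icer_at_low:>12,.2f}, "
                    f"{e.icer_at_high:>12,.2f}]  span {e.span:>12,.2f}"
                )
        if self.threshold_prices:
            lines.append("")
            for name, res in self.threshold_prices.items():
                lines.append(
                    f"{name}: vial price for cost-effectiveness = "
                    f"${res['price']:,.2f} ({res['reduction_percent']:.1f}% below "
                    f"${res['baseline_price']:,.2f})"
                )
        return "\n".join(lines) + "\n"


def _resolve(scenario_or_path: Union[Scenario, str, Path]) -> Scenario:
    if isinstance(scenario_or_path, Scenario):
        return scenario_or_path
    return load_config(scenario_or_path)


def _provenance(scenario: Scenario, seed: Optional[int]) -> dict:
    return {
        "package_version": _pkg_version,
        "scenario": scenario.name,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def run_base_case(
    scenario_or_path: Union[Scenario, str, Path],
    seed: Optional[int] = None,
    keep_traces: bool = True,
) -> RunReport:
    """Execute the full pipeline for every strategy and rank the results."""
    scenario = _resolve(scenario_or_path)
    results = {}
    traces = {}
    for params in scenario.strategies:
        result, trace, _ = evaluate_strategy(scenario, params.name)
        results[params.name] = result
        if keep_traces:
            traces[params.name] = trace_frame(trace, scenario.economics)
    table = rank_strategies(list(results.values()))
    reference = scenario.reference_strategy.name
    verdicts = {}
    for params in scenario.active_strategies:
        value = icer(results[reference], results[params.name])
        ce, exceed = threshold_verdict(value, scenario.economics)
        verdicts[params.name] = {
            "reference": reference,
            "icer_vs_reference": value,
            "cost_effective": ce,
            "exceedance_percent": exceed,
        }
    return RunReport(
        scenario=scenario,
        cea_table=table,
        verdicts=verdicts,
        traces=traces,
        provenance=_provenance(scenario, seed),
    )


def run_sensitivity(
    scenario_or_path: Union[Scenario, str, Path],
    mode: str,
    seed: Optional[int] = None,
) -> RunReport:
    """Base-case report plus the requested sensitivity section.

    ``mode`` is ``tornado`` (one-way analysis over the configured ranges)
    or ``threshold_price`` (vial-price root search for every antibody arm).
    """
    scenario = _resolve(scenario_or_path)
    report = run_base_case(scenario, seed=seed, keep_traces=False)
    if mode == "tornado":
        if not scenario.sensitivity_ranges:
            raise ValidationError("scenario defines no sensitivity ranges")
        report.tornado = tornado(scenario.sensitivity_ranges, scenario)
    elif mode == "threshold_price":
        prices = {}
        for params in scenario.active_strategies:
            schedule = scenario.costs[params.name].dose_schedule
            if schedule is None:
                continue
            price, reduction = threshold_price(params.name, scenario)
            prices[params.name] = {
                "baseline_price": schedule.vial_unit_price,
                "price": price,
                "reduction_percent": reduction,
            }
        if not prices:
            raise ValidationError("no strategy with a dose schedule to reprice")
        report.threshold_prices = prices
    else:
        raise ValidationError(f"unknown sensitivity mode {mode!r}")
    return report


def write_report(report: RunReport, outdir: Union[str, Path]) -> list[Path]:
    """Write delimited tables plus JSON and text reports; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        written.append(path)

    _write("cea_table.tsv", report.cea_table.to_frame().to_csv(sep="\t", index=False))
    breakdown = pd.DataFrame(
        cost_breakdown_rows([report.scenario.costs[s.name] for s in report.scenario.strategies])
    )
    _write("cost_breakdown.tsv", breakdown.to_csv(sep="\t", index=False))
    for name, frame in report.traces.items():
        _write(f"trace_{name}.tsv", frame.to_csv(sep="\t", index=False))
    if report.tornado is not None:
        frame = pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "strategy": e.strategy,
                    "icer_at_low": e.icer_at_low,
                    "icer_at_high": e.icer_at_high,
                    "span": e.span,
                }
                for e in report.tornado
            ]
        )
        _write("tornado.tsv", frame.to_csv(sep="\t", index=False))
    if report.threshold_prices is not None:
        frame = pd.DataFrame(
            [
                {"strategy": name, **res}
                for name, res in report.threshold_prices.items()
            ]
        )
        _write("threshold_prices.tsv", frame.to_csv(sep="\t", index=False))
    _write("report.json", json.dumps(report.to_dict(), indent=2, default=float))
    _write("report.txt", report.summary_text())
    return written
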