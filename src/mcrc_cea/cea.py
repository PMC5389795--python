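"""Cost-effectiveness ranking: ICERs, dominance and the WTP verdict.

Strategies are sorted by ascending discounted cost.  A strategy is
*dominated* when another costs no more and is at least as effective (with
at least one strict inequality); *extended dominance* additionally removes
strategies whose ICER exceeds that of a more effective alternative on the
efficiency frontier.  ICERs are reported for frontier strategies against
the next cheaper frontier strategy, and each strategy's ICER against the
reference (cheapest) arm is compared with the willingness-to-pay
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .config import EconomicConfig
from .errors import UndefinedICERError, ValidationError

__all__ = [
    "CEAResult",
    "CEARow",
    "CEATable",
    "icer",
    "rank_strategies",
    "threshold_verdict",
    "EFFECTIVENESS_TOL",
]

#: Absolute tolerance (life-years) below which two effectiveness values are
#: treated as equal.  The two antibodies are modeled with identical
#: transitions, so their effectiveness is equal by construction.
EFFECTIVENESS_TOL = 1e-9


@dataclass(frozen=True)
class CEAResult:
    """Discounted cost (USD) and effectiveness (life-years) of one strategy."""

    strategy: str
    cost: float
    effectiveness: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.effectiveness < 0:
            raise ValidationError(f"{self.strategy}: cost and effectiveness must be >= 0")


@dataclass(frozen=True)
class CEARow:
    result: CEAResult
    dominance: str = "none"  # none | dominated | extended
    incremental_cost: Optional[float] = None
    incremental_effectiveness: Optional[float] = None
    icer: Optional[float] = None


@dataclass(frozen=True)
class CEATable:
    rows: tuple[CEARow, ...] = field(default_factory=tuple)

    def row(self, strategy: str) -> CEARow:
        for r in self.rows:
            if r.result.strategy == strategy:
                return r
        raise ValidationError(f"unknown strategy {strategy!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": [r.result.strategy for r in self.rows],
                "cost": [r.result.cost for r in self.rows],
                "incremental_cost": [r.incremental_cost for r in self.rows],
                "effectiveness": [r.result.effectiveness for r in self.rows],
                "incremental_effectiveness": [r.incremental_effectiveness for r in self.rows],
                "icer": [r.icer for r in self.rows],
                "dominance": [r.dominance for r in self.rows],
            }
        )


def icer(reference: CEAResult, comparator: CEAResult) -> float:
    """Incremental cost per incremental life-year of comparator vs reference."""
    d_eff = comparator.effectiveness - reference.effectiveness
    if abs(d_eff) < EFFECTIVENESS_TOL:
        raise UndefinedICERError(
            f"{comparator.strategy} vs {reference.strategy}: equal effectiveness; "
            "report dominance or equivalence instead of an ICER"
        )
    return (comparator.cost - reference.cost) / d_eff


def _dominates(a: CEAResult, b: CEAResult) -> bool:
    """True when ``a`` costs no more than ``b`` and is at least as effective."""
    no_worse = a.cost <= b.cost and a.effectiveness >= b.effectiveness - EFFECTIVENESS_TOL
    strictly_better = a.cost < b.cost or a.effectiveness > b.effectiveness + EFFECTIVENESS_TOL
    return no_worse and strictly_better


def rank_strategies(results: Sequence[CEAResult]) -> CEATable:
    """Sort by cost, flag (extended) dominance, and compute frontier ICERs.

    Ties on both cost and effectiveness preserve input order; the later row
    is flagged dominated with a warning.
    """
    if len(results) < 2:
        raise ValidationError("ranking needs at least 2 strategies")
    items = sorted(results, key=lambda r: r.cost)  # stable: ties keep input order

    dominance = ["none"] * len(items)
    for i, a in enumerate(items):
        for j, b in enumerate(items):
            if i == j or dominance[j] != "none":
                continue
            tie = (
                b.cost == a.cost
                and abs(b.effectiveness - a.effectiveness) <= EFFECTIVENESS_TOL
            )
            if _dominates(b, a) or (tie and j < i):
                dominance[i] = "dominated"
                if tie:
                    warnings.warn(
                        f"{a.strategy} and {b.strategy} have identical cost and "
                        f"effectiveness; flagging {a.strategy} as dominated",
                        stacklevel=2,
                    )
                break

    # extended dominance on the surviving frontier: an ICER must not exceed
    # the ICER of the next, more effective frontier member
    changed = True
    while changed:
        changed = False
        frontier = [i for i, d in enumerate(dominance) if d == "none"]
        for a, b, c in zip(frontier, frontier[1:], frontier[2:]):
            icer_ab = icer(items[a], items[b])
            icer_bc = icer(items[b], items[c])
            if icer_ab > icer_bc:
                dominance[b] = "extended"
                changed = True
                break

    rows: list[CEARow] = []
    frontier = [i for i, d in enumerate(dominance) if d == "none"]
    for i, result in enumerate(items):
        if dominance[i] != "none" or i == frontier[0]:
            rows.append(CEARow(result=result, dominance=dominance[i]))
            continue
        prev = items[frontier[frontier.index(i) - 1]]
        rows.append(
            CEARow(
                result=result,
                dominance="none",
                incremental_cost=result.cost - prev.cost,
                incremental_effectiveness=result.effectiveness - prev.effectiveness,
                icer=icer(prev, result),
            )
        )
    return CEATable(rows=tuple(rows))


def threshold_verdict(icer_value: float, econ: EconomicConfig) -> tuple[bool, float]:
    """Compare an ICER with the willingness-to-pay threshold.

    Returns ``(cost_effective, exceedance_percent)`` where the exceedance is
    100 × (ICER / threshold − 1), floored at zero.
    """
    if icer_value < 0:
        raise ValidationError("threshold verdicts apply to non-negative ICERs")
    cost_effective = icer_value <= econ.wtp_threshold
    exceedance = max(0.0, 100.0 * (icer_value / econ.wtp_threshold - 1.0))
    return cost_effective, exceedance
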