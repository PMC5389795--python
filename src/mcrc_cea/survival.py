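"""Synthetic survival-fraction series from exponential hazards.

The calibration stage of the model converts progression-free/overall
survival curves into per-cycle transition probabilities.  The original
trial curves are not machine-readable, so this module generates
Kaplan-Meier-style survival-fraction series from a *known* constant
hazard — exactly the generative model a log-linear fit presumes — either
noiselessly (S(t) = exp(−rate·t)) or with binomial sampling noise from a
finite cohort of seeded exponential failure times.  Censoring is not
modeled: the calibration consumes survival fractions, not subject-level
data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ValidationError

__all__ = [
    "SurvivalSeries",
    "simulate_exponential_survival",
    "write_series",
    "read_series",
]


@dataclass(frozen=True)
class SurvivalSeries:
    """Survival fractions observed at strictly increasing times (years).

    ``at_risk`` carries the simulated number of subjects still event-free
    at each time (when the series is noisy); ``true_rate`` records the
    generating hazard (events/year) when the series is simulated.
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: Optional[tuple[int, ...]] = None
    true_rate: Optional[float] = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        survival = tuple(float(s) for s in self.survival)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "survival", survival)
        if len(times) != len(survival):
            raise ValidationError("times and survival must have equal length")
        if len(times) == 0:
            raise ValidationError("series must contain at least one point")
        if any(t < 0 for t in times):
            raise ValidationError("times must be non-negative")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("times must be strictly increasing")
        if any(not 0.0 <= s <= 1.0 for s in survival):
            raise ValidationError("survival fractions must lie in [0, 1]")
        if any(s1 < s2 for s1, s2 in zip(survival, survival[1:])):
            raise ValidationError("survival must be non-increasing")
        if times[0] == 0.0 and survival[0] != 1.0:
            raise ValidationError("survival at t=0 must be 1")
        if self.at_risk is not None:
            at_risk = tuple(int(n) for n in self.at_risk)
            object.__setattr__(self, "at_risk", at_risk)
            if len(at_risk) != len(times):
                raise ValidationError("at_risk must match times in length")
            if any(n1 < n2 for n1, n2 in zip(at_risk, at_risk[1:])):
                raise ValidationError("at_risk must be non-increasing")

    def __len__(self) -> int:
        return len(self.times)


def simulate_exponential_survival(
    rate: float,
    times: Sequence[float],
    n_subjects: int = 1000,
    seed: int = 0,
    noiseless: bool = False,
) -> SurvivalSeries:
    """Survival fractions at ``times`` under a constant hazard ``rate``.

    With ``noiseless=True`` the fractions are exactly exp(−rate·t).
    Otherwise ``n_subjects`` exponential failure times are drawn from a
    generator fully determined by ``seed`` and the fraction surviving each
    time point is reported (binomial sampling noise around the exact
    curve).
    """
    if rate <= 0:
        raise ValidationError("rate must be positive")
    times = [float(t) for t in times]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("times must be strictly increasing")
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    t = np.asarray(times)
    if noiseless:
        surv = np.exp(-rate * t)
        return SurvivalSeries(times=tuple(times), survival=tuple(surv), true_rate=rate)
    rng = np.random.default_rng(seed)
    failure_times = rng.exponential(scale=1.0 / rate, size=n_subjects)
    counts = (failure_times[None, :] > t[:, None]).sum(axis=1)
    return SurvivalSeries(
        times=tuple(times),
        survival=tuple(counts / n_subjects),
        at_risk=tuple(int(c) for c in counts),
        true_rate=rate,
    )


def write_series(series: SurvivalSeries, path: Union[str, Path, io.TextIOBase]) -> None:
    """Write a two-column (time, survival) tab-delimited file."""
    lines = ["time_years\tsurvival\n"]
    lines += [f"{t:.10g}\t{s:.10g}\n" for t, s in zip(series.times, series.survival)]
    if isinstance(path, io.TextIOBase):
        path.writelines(lines)
    else:
        Path(path).write_text("".join(lines))


def read_series(path: Union[str, Path]) -> SurvivalSeries:
    """Read the two-column format written by :func:`write_series`."""
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise ValidationError(f"empty survival file: {path}")
    body = text[1:] if text[0].lower().startswith("time") else text
    times, surv = [], []
    for line in body:
        fields = line.replace(",", "\t").split()
        if len(fields) < 2:
            raise ValidationError(f"malformed survival line: {line!r}")
        times.append(float(fields[0]))
        surv.append(float(fields[1]))
    return SurvivalSeries(times=tuple(times), survival=tuple(surv))
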