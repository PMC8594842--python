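"""Screening-burden arithmetic: what an error-rate difference means in
false-positive and false-negative cases per day.

Given a daily ECG volume and an AFib prevalence, the expected daily AFib
and non-AFib counts are split, each algorithm's false-positive and
false-negative rates are applied, and each count is rounded half away
from zero *before* differencing.  Per-term rounding is deliberate: the
burden comparison is between two integer daily caseloads, and the
difference of two separately rounded counts is what a screening service
would actually observe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Scenario", "ErrorRates", "WorkloadReport", "daily_errors",
           "compare", "parse_prevalence"]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def parse_prevalence(text) -> float:
    """Prevalence as a fraction; percent requires an explicit '%' suffix.

    '0.5%' -> 0.005, '0.005' -> 0.005.  A bare '0.5' is half, not half a
    percent.
    """
    s = str(text).strip()
    if s.endswith("%"):
        return float(s[:-1]) / 100.0
    return float(s)


@dataclass(frozen=True)
class Scenario:
    """A daily screening scenario; counts split as round(volume x prevalence)."""

    volume_per_day: int
    prevalence: float

    def __post_init__(self):
        if self.volume_per_day <= 0:
            raise ValueError("volume_per_day must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1); "
                             "use parse_prevalence for percent input")

    @property
    def n_positive(self) -> int:
        return _round_half_away(self.volume_per_day * self.prevalence)

    @property
    def n_negative(self) -> int:
        return self.volume_per_day - self.n_positive


@dataclass(frozen=True)
class ErrorRates:
    """One algorithm's false-positive and false-negative rates."""

    fpr: float
    fnr: float

    def __post_init__(self):
        for name in ("fpr", "fnr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class WorkloadReport:
    """Daily error counts for two algorithms and their differences.

    delta_fp / delta_fn are b minus a, computed on the per-algorithm
    rounded integers.
    """

    fp_a: int
    fn_a: int
    fp_b: int
    fn_b: int

    @property
    def delta_fp(self) -> int:
        return self.fp_b - self.fp_a

    @property
    def delta_fn(self) -> int:
        return self.fn_b - self.fn_a

    def as_dict(self) -> dict[str, int]:
        return {
            "fp_per_day_a": self.fp_a, "fn_per_day_a": self.fn_a,
            "fp_per_day_b": self.fp_b, "fn_per_day_b": self.fn_b,
            "delta_fp": self.delta_fp, "delta_fn": self.delta_fn,
        }


def daily_errors(scenario: Scenario, rates: ErrorRates) -> tuple[int, int]:
    """(FP/day, FN/day) for one algorithm under the scenario."""
    fp = _round_half_away(scenario.n_negative * rates.fpr)
    fn = _round_half_away(scenario.n_positive * rates.fnr)
    return fp, fn


def compare(scenario: Scenario, rates_a: ErrorRates,
            rates_b: ErrorRates) -> WorkloadReport:
    """Daily burden of algorithm a vs b (deltas are b - a)."""
    fp_a, fn_a = daily_errors(scenario, rates_a)
    fp_b, fn_b = daily_errors(scenario, rates_b)
    return WorkloadReport(fp_a=fp_a, fn_a=fn_a, fp_b=fp_b, fn_b=fn_b)
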