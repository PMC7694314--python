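"""Benefit/risk metrics for screening workflows.

Three headline quantities per review, all relative to the dual-independent
baseline of two screenings per record:

* proportion missed -- of the final-report studies, the percentage wrongly
  excluded at title-abstract by the workflow;
* workload savings -- screening decisions avoided, as a count and as a
  percentage of the 2N baseline;
* time savings -- the avoided screenings converted to hours and working days
  at a fixed screening rate (default 0.5 min/record, 8 h/day).

Cross-review summaries use median and interquartile range with quantiles at
position 1 + (n - 1)p between order statistics (linear interpolation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from screensim.workflows import WorkflowResult


@dataclass(frozen=True)
class TimeCostModel:
    """Screening-rate assumptions for converting counts to time."""

    minutes_per_record: float = 0.5
    hours_per_day: float = 8.0

    def __post_init__(self) -> None:
        if self.minutes_per_record <= 0 or self.hours_per_day <= 0:
            raise ValueError("time-cost parameters must be positive")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties away from zero (display rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def proportion_missed(n_missed: int, n_final_report: int) -> float:
    """Percentage of final-report studies wrongly excluded at title-abstract."""
    if n_final_report <= 0:
        raise ValueError("proportion missed undefined: empty final report")
    if not 0 <= n_missed <= n_final_report:
        raise ValueError(
            f"n_missed={n_missed} out of range [0, {n_final_report}]"
        )
    return 100.0 * n_missed / n_final_report


def workload_savings(saved: int, n_records: int) -> tuple[int, float]:
    """Savings count and percentage of the dual-screening baseline (2N)."""
    baseline = 2 * n_records
    if not 0 <= saved <= baseline:
        raise ValueError(f"saved={saved} out of range [0, {baseline}]")
    return saved, 100.0 * saved / baseline


def time_savings(
    saved: int, model: TimeCostModel = TimeCostModel()
) -> tuple[float, float]:
    """Hours and working days of screening avoided for `saved` records."""
    if saved < 0:
        raise ValueError("saved must be >= 0")
    hours = saved * model.minutes_per_record / 60.0
    return hours, hours / model.hours_per_day


def format_days(days: float) -> str:
    """Table rendering for day counts: values under one day print '< 1 d'."""
    if days <= 0:
        return "0 d"
    if days < 1:
        return "< 1 d"
    return f"{round_half_up(days)} d"


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) with linear interpolation at 1+(n-1)p."""
    if len(values) == 0:
        raise ValueError("median_iqr of empty collection")
    arr = np.asarray(values, dtype=float)
    med, q25, q75 = np.quantile(arr, [0.5, 0.25, 0.75], method="linear")
    return float(med), float(q25), float(q75)


@dataclass(frozen=True)
class MetricReport:
    """Per-review benefit/risk metrics for one workflow."""

    workflow: str
    n_records: int
    n_final_report: int
    n_missed: int
    proportion_missed_pct: float
    workload_savings_count: int
    workload_savings_pct: float
    time_savings_hours: float
    time_savings_days: float

    def rendered(self) -> dict[str, str]:
        """Display-rounded fields as a results table would print them."""
        return {
            "workflow": self.workflow,
            "missed": (
                f"{self.n_missed} ({round_half_up(self.proportion_missed_pct)})"
                if self.n_final_report
                else f"{self.n_missed} (-)"
            ),
            "workload_savings": (
                f"{self.workload_savings_count} "
                f"({round_half_up(self.workload_savings_pct)})"
            ),
            "time_savings": (
                f"{round_half_up(self.time_savings_hours)} h "
                f"({format_days(self.time_savings_days)})"
            ),
        }


def evaluate_workflow(
    result: WorkflowResult,
    n_final_report: int,
    model: TimeCostModel = TimeCostModel(),
) -> MetricReport:
    """Full metric report for one workflow simulation."""
    ledger = result.ledger
    saved, pct = workload_savings(ledger.workload_savings, ledger.n_records)
    hours, days = time_savings(saved, model)
    n_missed = len(result.missed_ids)
    return MetricReport(
        workflow=result.workflow,
        n_records=ledger.n_records,
        n_final_report=n_final_report,
        n_missed=n_missed,
        proportion_missed_pct=(
            proportion_missed(n_missed, n_final_report) if n_final_report else 0.0
        ),
        workload_savings_count=saved,
        workload_savings_pct=pct,
        time_savings_hours=hours,
        time_savings_days=days,
    )
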