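"""KPI computation and report rendering.

Rates are kept as exact fractions internally and rounded only at the
presentation layer, with halves away from zero at one decimal — the
rule that reproduces the reference deployment table's printed cells.
Summary statistics follow the reference report's conventions: sample
standard deviation (n−1 denominator) and integer presentation by
truncation toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domain import MonthlyLedger, round_half_away, validate_ledger
from .errors import (
    ConfigurationError,
    CorrelationError,
    DegreesOfFreedomError,
    UndefinedRateError,
)

__all__ = [
    "RateRow",
    "SummaryStats",
    "compute_rates",
    "summary_stats",
    "spearman_rho",
    "capacity_utilization",
    "render_table1",
    "table_to_text",
]


@dataclass
class RateRow:
    """Per-month KPI row; percentages presented at one decimal."""

    month_label: str
    realized_pct: float
    canceled_pct: float
    noshow_pct: float
    standby_pct: float
    combined_count: int
    combined_pct: float
    standby_to_web_pct: float


def compute_rates(ledger: MonthlyLedger) -> RateRow:
    """Status-share percentages for one month, at presentation precision."""
    validate_ledger(ledger)
    if ledger.n_total == 0:
        raise UndefinedRateError(f"{ledger.month_label}: rates undefined, empty month")
    n = ledger.n_total
    combined = ledger.n_realized_web + ledger.n_standby_realized
    web_ratio = (
        100.0 * ledger.n_standby_realized / ledger.n_realized_web
        if ledger.n_realized_web
        else 0.0
    )
    return RateRow(
        month_label=ledger.month_label,
        realized_pct=round_half_away(100.0 * ledger.n_realized_web / n),
        canceled_pct=round_half_away(100.0 * ledger.n_canceled / n),
        noshow_pct=round_half_away(100.0 * ledger.n_noshow / n),
        standby_pct=round_half_away(100.0 * ledger.n_standby_realized / n),
        combined_count=combined,
        combined_pct=round_half_away(100.0 * combined / n),
        standby_to_web_pct=round_half_away(web_ratio),
    )


@dataclass
class SummaryStats:
    """Mean / sample SD / median, raw and as presented integers."""

    mean: float
    sd: float
    median: float
    mean_int: int
    sd_int: int
    median_int: int


def summary_stats(series: Sequence[float]) -> SummaryStats:
    """Mean, sample standard deviation (n−1) and median of a count series.

    Presented integers truncate toward zero, matching the reference
    report's printed values.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if x.size < 2:
        raise DegreesOfFreedomError("sample SD requires at least two observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    median = float(np.median(x))
    return SummaryStats(
        mean=mean,
        sd=sd,
        median=median,
        mean_int=int(mean),
        sd_int=int(sd),
        median_int=int(median),
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; two-sided p via the
    t approximation.

    Raises :class:`CorrelationError` for mismatched lengths, n < 3, or a
    constant series (ranks carry no information).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise CorrelationError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise CorrelationError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise CorrelationError("correlation undefined for a constant series")
    res = stats.spearmanr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def capacity_utilization(realized: int, ec_total: int) -> float:
    """Realized visits per capacity slot, as a percentage capped at 100."""
    if ec_total <= 0:
        raise ConfigurationError("capacity must be positive to compute utilization")
    if realized < 0:
        raise ValueError("realized count must be non-negative")
    return min(100.0, 100.0 * realized / ec_total)


_TABLE_ROWS = [
    "total_web",
    "realized_web",
    "canceled_web",
    "noshow_web",
    "realized_standby",
    "realized_combined",
    "standby_to_web_ratio_pct",
]


def render_table1(ledgers: Sequence[MonthlyLedger]) -> pd.DataFrame:
    """Months-as-columns report mirroring the deployment ledger layout.

    Count rows carry ``n`` and ``pct`` sub-rows; the combined count is
    integer-exactly ``realized_web + realized_standby``. All percentages
    are recomputed from the counts (never copied from any source table).
    """
    if not ledgers:
        raise ValueError("at least one month is required")
    cols: dict[str, list] = {}
    for led in ledgers:
        validate_ledger(led)
        r = compute_rates(led) if led.n_total else None
        col = [
            led.n_total,
            100.0,
            led.n_realized_web,
            r.realized_pct if r else 0.0,
            led.n_canceled,
            r.canceled_pct if r else 0.0,
            led.n_noshow,
            r.noshow_pct if r else 0.0,
            led.n_standby_realized,
            r.standby_pct if r else 0.0,
            led.n_realized_web + led.n_standby_realized,
            r.combined_pct if r else 0.0,
            r.standby_to_web_pct if r else 0.0,
        ]
        cols[led.month_label] = col
    index = pd.MultiIndex.from_tuples(
        [
            ("total_web", "n"),
            ("total_web", "pct"),
            ("realized_web", "n"),
            ("realized_web", "pct"),
            ("canceled_web", "n"),
            ("canceled_web", "pct"),
            ("noshow_web", "n"),
            ("noshow_web", "pct"),
            ("realized_standby", "n"),
            ("realized_standby", "pct"),
            ("realized_combined", "n"),
            ("realized_combined", "pct"),
            ("standby_to_web_ratio_pct", "pct"),
        ],
        names=["parameter", "kind"],
    )
    return pd.DataFrame(cols, index=index)


def table_to_text(table: pd.DataFrame) -> str:
    """Aligned-text rendering of :func:`render_table1` output."""
    return table.to_string(float_format=lambda v: f"{v:.1f}")
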