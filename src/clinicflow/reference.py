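"""Reference deployment ledger: seven months of appointment counts.

A validation fixture taken from a large university hospital's monthly
appointment report (June = before the standby policy went live; July =
pilot; August–December = full operation). Each column gives the web
booking stream (total / realized / canceled / no-show) plus the visits
recovered through promoted standby bookings.

The counts are integer-exact and every month satisfies the status
partition. The August–December standby series [2934, 4683, 4556, 5430,
5800] is the basis for the report's summary statistics.
"""

from __future__ import annotations

from .domain import MonthlyLedger, validate_ledger

__all__ = ["REFERENCE_MONTHS", "reference_ledgers", "STANDBY_SERIES_AUG_DEC"]

# month -> (total, realized_web, canceled, no_show, standby_realized)
REFERENCE_MONTHS: dict[str, tuple[int, int, int, int, int]] = {
    "June": (92_527, 52_846, 29_227, 10_454, 0),
    "July": (62_110, 36_008, 18_605, 7_497, 859),
    "August": (77_389, 44_307, 23_341, 9_741, 2_934),
    "September": (78_696, 45_789, 23_043, 9_864, 4_683),
    "October": (75_324, 43_513, 22_544, 9_267, 4_556),
    "November": (81_966, 46_748, 26_321, 8_897, 5_430),
    "December": (80_481, 45_170, 25_797, 9_514, 5_800),
}

#: Standby-realized visits for the five full-operation months.
STANDBY_SERIES_AUG_DEC: tuple[int, ...] = (2_934, 4_683, 4_556, 5_430, 5_800)


def reference_ledgers() -> list[MonthlyLedger]:
    """The reference months as validated :class:`MonthlyLedger` objects."""
    out = []
    for month, (total, realized, canceled, noshow, standby) in REFERENCE_MONTHS.items():
        out.append(
            validate_ledger(
                MonthlyLedger(
                    month_label=month,
                    n_total=total,
                    n_realized_web=realized,
                    n_canceled=canceled,
                    n_noshow=noshow,
                    n_standby_realized=standby,
                )
            )
        )
    return out
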