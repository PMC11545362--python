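"""Core domain types for outpatient appointment bookkeeping.

The vocabulary mirrors how appointment offices talk about a physician's
month: an *examination capacity* (EC) of bookable slots, booked
appointments that end up realized, canceled or as no-shows, and the
derived rates

* ARP — appointment realization probability, ``realized / total``
* ACR — appointment cancellation rate, ``canceled / total``
* NSPR — no-show patient rate, ``no_show / total``

The three statuses partition the booked appointments, so the three rates
sum to one. ``AR`` counts standby (substitute) bookings already promoted
into vacated primary slots during the period.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .errors import ConservationError, UndefinedRateError

__all__ = [
    "AGE_BRACKETS",
    "age_to_bracket",
    "round_half_away",
    "Channel",
    "Role",
    "Status",
    "ParameterSet",
    "AppointmentRecord",
    "PatientProfile",
    "MonthlyLedger",
    "validate_ledger",
    "derive_parameters",
]

#: Age brackets used throughout risk modelling. The deployment analysed
#: brackets up to 61-70; "71+" extends the scheme so every age maps to
#: exactly one bracket.
AGE_BRACKETS: tuple[str, ...] = (
    "0-10",
    "11-20",
    "21-30",
    "31-40",
    "41-50",
    "51-60",
    "61-70",
    "71+",
)

_RATE_TOL = 1e-9


def age_to_bracket(age_years: int) -> str:
    """Map an integer age to its unique bracket label."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    if age_years > 70:
        return "71+"
    if age_years <= 10:
        return "0-10"
    idx = (age_years - 1) // 10
    return AGE_BRACKETS[idx]


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round with halves away from zero (the presentation rule for rates).

    Python's built-in ``round`` is banker's rounding; report tables use
    the conventional half-away rule instead (57.15 -> 57.2).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class Channel(str, enum.Enum):
    WEB = "web"
    CALL_CENTER = "call_center"


class Role(str, enum.Enum):
    PRIMARY = "primary"
    SUBSTITUTE = "substitute"
    COMPLEMENTARY = "complementary"


class Status(str, enum.Enum):
    BOOKED = "booked"
    REALIZED = "realized"
    CANCELED = "canceled"
    NO_SHOW = "no_show"


@dataclass
class ParameterSet:
    """Scheduling parameters for one physician-month.

    Parameters
    ----------
    ec : int
        Examination capacity — bookable slots this month.
    arp, acr, nspr : float
        Realization / cancellation / no-show fractions in [0, 1];
        together they must not exceed 1 (statuses partition bookings).
    ar : int
        Substitute appointments already promoted to primary this period.
    """

    ec: int
    arp: float
    acr: float
    nspr: float
    ar: int = 0

    def __post_init__(self) -> None:
        if self.ec < 0 or int(self.ec) != self.ec:
            raise ValueError(f"ec must be a non-negative integer, got {self.ec}")
        for name in ("arp", "acr", "nspr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.arp + self.acr + self.nspr > 1.0 + _RATE_TOL:
            raise ValueError(
                "arp + acr + nspr must not exceed 1: "
                f"{self.arp} + {self.acr} + {self.nspr}"
            )
        if self.ar < 0:
            raise ValueError(f"ar must be non-negative, got {self.ar}")
        if self.ar > self.ec:
            raise ValueError(f"ar ({self.ar}) cannot exceed ec ({self.ec})")

    def with_promotions(self, ar: int) -> "ParameterSet":
        return replace(self, ar=ar)


@dataclass
class AppointmentRecord:
    """One appointment: who, which slot, how it was booked, how it ended."""

    patient_id: str
    slot_time: datetime
    booking_time: datetime
    channel: Channel = Channel.WEB
    role: Role = Role.PRIMARY
    status: Status = Status.BOOKED
    cancel_lead_min: Optional[float] = None
    physician_id: str = "phys-1"
    branch_id: str = "main"

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        self.role = Role(self.role)
        self.status = Status(self.status)
        if self.booking_time > self.slot_time:
            raise ValueError(
                f"booking_time {self.booking_time} is after slot_time {self.slot_time}"
            )
        if (self.status is Status.CANCELED) != (self.cancel_lead_min is not None):
            raise ValueError(
                "cancel_lead_min must be present iff status is canceled "
                f"(status={self.status.value}, lead={self.cancel_lead_min})"
            )
        if self.cancel_lead_min is not None and self.cancel_lead_min < 0:
            raise ValueError("cancel_lead_min must be non-negative")

    def promoted(self) -> "AppointmentRecord":
        """Promote a substitute booking to primary (the only legal role change)."""
        if self.role is not Role.SUBSTITUTE:
            raise ValueError(f"only substitutes can be promoted, got role={self.role.value}")
        return replace(self, role=Role.PRIMARY)


@dataclass
class PatientProfile:
    """Demographics plus behavioural history feeding the risk model."""

    patient_id: str
    age_years: int
    gender: str
    district: str
    travel_time_min: Optional[float] = None
    n_realized: int = 0
    n_canceled: int = 0
    n_noshow: int = 0
    history: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.travel_time_min is not None and self.travel_time_min < 0:
            raise ValueError("travel_time_min must be non-negative")
        counts = (self.n_realized, self.n_canceled, self.n_noshow)
        if any(c < 0 for c in counts):
            raise ValueError("history counts must be non-negative")
        if self.history and len(self.history) != sum(counts):
            raise ValueError(
                "history length must equal the sum of the status counts: "
                f"{len(self.history)} vs {sum(counts)}"
            )

    @property
    def age_bracket(self) -> str:
        return age_to_bracket(self.age_years)

    @property
    def n_past(self) -> int:
        return self.n_realized + self.n_canceled + self.n_noshow


@dataclass
class MonthlyLedger:
    """Aggregated appointment counts for one month.

    ``n_realized_web + n_canceled + n_noshow`` must equal ``n_total``;
    ``n_standby_realized`` counts visits produced by promoted standby
    bookings and sits outside that partition (it is additional capacity
    recovered, not part of the web booking stream).
    """

    month_label: str
    n_total: int
    n_realized_web: int
    n_canceled: int
    n_noshow: int
    n_standby_realized: int = 0


def validate_ledger(ledger: MonthlyLedger) -> MonthlyLedger:
    """Check the status partition and count signs; return the ledger unchanged.

    Raises
    ------
    ConservationError
        If realized + canceled + no-show != total, naming the month and
        the residual.
    """
    counts = (
        ledger.n_total,
        ledger.n_realized_web,
        ledger.n_canceled,
        ledger.n_noshow,
        ledger.n_standby_realized,
    )
    if any(c < 0 for c in counts):
        raise ConservationError(f"{ledger.month_label}: negative count in {counts}")
    residual = ledger.n_total - (
        ledger.n_realized_web + ledger.n_canceled + ledger.n_noshow
    )
    if residual != 0:
        raise ConservationError(
            f"{ledger.month_label}: conservation violated, "
            f"realized + canceled + no-show differs from total by {residual}"
        )
    return ledger


def derive_parameters(ledger: MonthlyLedger, ec: int) -> ParameterSet:
    """Turn a month's counts into the scheduling rates for capacity ``ec``.

    ``arp = realized/total``, ``acr = canceled/total``,
    ``nspr = no_show/total``; promotions (``ar``) start at zero.
    """
    validate_ledger(ledger)
    if ledger.n_total == 0:
        raise UndefinedRateError(
            f"{ledger.month_label}: rates undefined for an empty month"
        )
    n = ledger.n_total
    return ParameterSet(
        ec=ec,
        arp=ledger.n_realized_web / n,
        acr=ledger.n_canceled / n,
        nspr=ledger.n_noshow / n,
        ar=0,
    )
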