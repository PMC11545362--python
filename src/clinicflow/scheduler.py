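"""Standby-appointment policy engine.

The policy provisions a ranked pool of standby (substitute) bookings
sized from the month's expected losses:

    SA = EC*ACR + EC*NSPR                       (substitute count)
    CA = (EC*ACR - ARP*AR) + EC*NSPR            (complementary count)

EC is examination capacity, ACR/NSPR the cancellation and no-show
rates, ARP the realization probability and AR the promotions already
made this period. Fractional values are ceiled so reserve coverage is
never under-provisioned; CA is clamped at zero once promotions already
cover the expected shortfall.

When a primary booking is canceled, the first-booked standby for that
physician is promoted into the vacated slot (FIFO on booking time) and
the patient is notified — here, an event in the plan's log. The
pre-appointment callback cycle confirms high-risk primaries; a decline
cancels the slot and triggers an immediate promotion, repeating until
there is nothing left to backfill or the pool is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

from .domain import AppointmentRecord, ParameterSet, Role, Status
from .errors import ConfigurationError, PromotionError
from .tree import RiskProfile

__all__ = [
    "substitute_count",
    "complementary_count",
    "ReserveCandidate",
    "SchedulePlan",
    "CallbackOutcome",
    "rank_reserve_pool",
    "build_plan",
    "promote_substitute",
    "run_callback_cycle",
]

#: Latest allowed confirmation call, minutes before the slot.
MIN_CALLBACK_HORIZON_MIN = 60.0


def _ceil9(x: float) -> int:
    # round(x, 9) shields the ceiling from binary float noise
    # (100 * 0.29 = 28.999999999999996 must not ceil to 30... nor 29+11 to 41)
    return math.ceil(round(x, 9))


def substitute_count(params: ParameterSet) -> int:
    """Standby bookings to provision: ceil(EC*ACR + EC*NSPR)."""
    return _ceil9(params.ec * params.acr + params.ec * params.nspr)


def complementary_count(params: ParameterSet) -> int:
    """Additional standby bookings after promotions already made.

    ceil((EC*ACR - ARP*AR) + EC*NSPR), clamped at zero. Equals
    :func:`substitute_count` when AR = 0.
    """
    raw = (params.ec * params.acr - params.arp * params.ar) + params.ec * params.nspr
    return max(0, _ceil9(raw))


@dataclass
class ReserveCandidate:
    """One patient waiting in the standby pool."""

    patient_id: str
    risk: RiskProfile
    travel_time_min: Optional[float]
    booking_order: int
    physician_id: Optional[str] = None


def rank_reserve_pool(
    candidates: Iterable[ReserveCandidate],
) -> list[ReserveCandidate]:
    """Deterministic total order for the standby pool.

    Highest attendance probability first, then shortest self-reported
    travel time (patients who can reach the clinic fastest fill sudden
    vacancies best), then booking order (FIFO). Missing travel times
    sort last within a probability tier.
    """
    return sorted(
        candidates,
        key=lambda c: (
            -c.risk.p_attend,
            c.travel_time_min if c.travel_time_min is not None else math.inf,
            c.booking_order,
        ),
    )


@dataclass
class CallbackOutcome:
    """Result of one confirmation call."""

    patient_id: str
    confirmed: bool
    response_time: datetime
    action: str  # "keep" | "cancel_and_backfill"

    def __post_init__(self) -> None:
        expected = "keep" if self.confirmed else "cancel_and_backfill"
        if self.action != expected:
            raise ValueError(
                f"action {self.action!r} inconsistent with confirmed={self.confirmed}"
            )


@dataclass
class SchedulePlan:
    """A physician-month plan: primaries, ranked standby pool, counters."""

    params: ParameterSet
    primary_slots: list[AppointmentRecord]
    reserve_pool: list[ReserveCandidate]
    n_substitute: int = 0
    n_complementary: int = 0
    risk: dict[str, RiskProfile] = field(default_factory=dict)
    high_risk_threshold: float = 0.6
    events: list[dict] = field(default_factory=list)

    def log(self, kind: str, **payload) -> None:
        self.events.append({"event": kind, **payload})


def build_plan(
    params: ParameterSet,
    primary_slots: Sequence[AppointmentRecord],
    candidates: Iterable[ReserveCandidate],
    risk: Optional[Mapping[str, RiskProfile]] = None,
    pool_size: Optional[int] = None,
    high_risk_threshold: float = 0.6,
) -> SchedulePlan:
    """Assemble a plan: rank the pool and size it from the SA formula.

    The pool is truncated to ``min(pool_size, SA)`` — standby bookings
    beyond the expected shortfall would never be promoted.
    """
    sa = substitute_count(params)
    ca = complementary_count(params)
    ranked = rank_reserve_pool(candidates)
    cap = sa if pool_size is None else min(pool_size, sa)
    plan = SchedulePlan(
        params=params,
        primary_slots=list(primary_slots),
        reserve_pool=ranked[:cap],
        n_substitute=sa,
        n_complementary=ca,
        risk=dict(risk or {}),
        high_risk_threshold=high_risk_threshold,
    )
    plan.log("plan_built", n_primary=len(plan.primary_slots), n_pool=len(plan.reserve_pool), sa=sa, ca=ca)
    return plan


def promote_substitute(
    plan: SchedulePlan, canceled_slot: AppointmentRecord
) -> Optional[AppointmentRecord]:
    """Fill a canceled primary slot from the standby pool.

    The earliest-booked (head-of-pool) standby for the slot's physician
    becomes the primary booking in the vacated slot; the promotion
    counter AR increments and an SMS-notification event is logged. An
    empty (or physician-mismatched) pool leaves the slot vacant with an
    "unfilled_slot" event — a no-op, not an error.

    Returns the new primary record, or None if the slot stayed vacant.
    """
    if canceled_slot.role is not Role.PRIMARY:
        raise PromotionError(f"only primary slots are backfilled, got {canceled_slot.role.value}")
    if canceled_slot.status is not Status.CANCELED:
        raise PromotionError(f"slot must be canceled to backfill, got {canceled_slot.status.value}")
    idx = next(
        (
            i
            for i, c in enumerate(plan.reserve_pool)
            if c.physician_id is None or c.physician_id == canceled_slot.physician_id
        ),
        None,
    )
    if idx is None:
        plan.log("unfilled_slot", slot_time=str(canceled_slot.slot_time), physician_id=canceled_slot.physician_id)
        return None
    cand = plan.reserve_pool.pop(idx)
    promoted = AppointmentRecord(
        patient_id=cand.patient_id,
        slot_time=canceled_slot.slot_time,
        booking_time=canceled_slot.slot_time,  # promotion happens now
        channel=canceled_slot.channel,
        role=Role.PRIMARY,
        status=Status.BOOKED,
        physician_id=canceled_slot.physician_id,
        branch_id=canceled_slot.branch_id,
    )
    plan.primary_slots.append(promoted)
    plan.params = plan.params.with_promotions(plan.params.ar + 1)
    plan.log("promote", patient_id=cand.patient_id, slot_time=str(canceled_slot.slot_time))
    plan.log("notify_sms", patient_id=cand.patient_id)
    return promoted


def run_callback_cycle(
    plan: SchedulePlan,
    horizon_min: float,
    responses: Mapping[str, bool],
    now: Optional[datetime] = None,
) -> tuple[SchedulePlan, list[CallbackOutcome]]:
    """Confirm high-risk primaries; cancel and backfill every decline.

    Patients whose predicted attendance probability falls below the
    plan's threshold are queried (their answer comes from
    ``responses``; patients absent from the mapping are treated as
    confirmed). A decline cancels the slot at ``horizon_min`` minutes
    before it and promotes the pool head into it. Promoted patients are
    themselves queried on the next pass, so the cycle repeats until no
    unconfirmed high-risk primary remains or the pool is exhausted.

    ``horizon_min`` must be at least 60 — calls are never placed later
    than one hour before the slot.
    """
    if horizon_min < MIN_CALLBACK_HORIZON_MIN:
        raise ConfigurationError(
            f"callback horizon must be >= {MIN_CALLBACK_HORIZON_MIN:g} min, got {horizon_min}"
        )
    outcomes: list[CallbackOutcome] = []
    queried: set[str] = set()
    while True:
        pending = [
            s
            for s in plan.primary_slots
            if s.status is Status.BOOKED
            and s.patient_id not in queried
            and s.patient_id in plan.risk
            and plan.risk[s.patient_id].p_attend < plan.high_risk_threshold
        ]
        if not pending:
            break
        progressed = False
        for slot in pending:
            queried.add(slot.patient_id)
            confirmed = bool(responses.get(slot.patient_id, True))
            when = now if now is not None else slot.slot_time
            outcomes.append(
                CallbackOutcome(
                    patient_id=slot.patient_id,
                    confirmed=confirmed,
                    response_time=when,
                    action="keep" if confirmed else "cancel_and_backfill",
                )
            )
            plan.log("callback", patient_id=slot.patient_id, confirmed=confirmed)
            if not confirmed:
                slot.status = Status.CANCELED
                slot.cancel_lead_min = horizon_min
                plan.log("cancel", patient_id=slot.patient_id, lead_min=horizon_min)
                promote_substitute(plan, slot)
                progressed = True
        if not progressed and not plan.reserve_pool:
            break
        if not progressed:
            break
    return plan, outcomes
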