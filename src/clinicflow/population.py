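"""Seeded synthetic outpatient population generator.

Emulates the structure of a large urban outpatient booking stream: a
roughly 60/29/11 realized/canceled/no-show split overall, cancellation
propensity that rises with age bracket, modest gender and district
effects expressed as odds multipliers, lognormal self-reported travel
times, and per-patient behavioural persistence (patients tend to repeat
their previous outcome).

All draws flow from one root seed through numpy's SeedSequence
spawning, so every module-level stream is independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .domain import AGE_BRACKETS, PatientProfile
from .errors import ConfigurationError

__all__ = ["PopulationConfig", "SimulatedPatient", "generate_population"]

_BRACKET_AGE_RANGE = {
    "0-10": (0, 10),
    "11-20": (11, 20),
    "21-30": (21, 30),
    "31-40": (31, 40),
    "41-50": (41, 50),
    "51-60": (51, 60),
    "61-70": (61, 70),
    "71+": (71, 90),
}

STATUSES = ("realized", "canceled", "no_show")


class PopulationConfig(BaseModel):
    """Generator settings; defaults reproduce the 60/29/11 baseline split
    with cancellation propensity rising across the eight age brackets
    (weighted means: cancel 0.294, no-show 0.110)."""

    n_patients: int = 10_000
    bracket_weights: list[float] = Field(
        default=[0.08, 0.10, 0.16, 0.16, 0.15, 0.14, 0.13, 0.08]
    )
    p_cancel_by_bracket: list[float] = Field(
        default=[0.20, 0.23, 0.26, 0.28, 0.30, 0.33, 0.36, 0.38]
    )
    p_noshow_by_bracket: list[float] = Field(
        default=[0.13, 0.12, 0.12, 0.11, 0.11, 0.10, 0.10, 0.09]
    )
    gender_effect: dict[str, float] = Field(default={"F": 1.0, "M": 0.95})
    district_effects: dict[str, float] = Field(
        default={"D1": 0.90, "D2": 1.00, "D3": 1.05, "D4": 1.10, "D5": 1.15}
    )
    persistence: float = 0.2
    mean_history_length: float = 3.0
    travel_time_median_min: float = 30.0
    travel_time_sigma: float = 0.5
    seed: int = 0

    @field_validator("bracket_weights", "p_cancel_by_bracket", "p_noshow_by_bracket")
    @classmethod
    def _length_eight(cls, v: list[float]) -> list[float]:
        if len(v) != len(AGE_BRACKETS):
            raise ValueError(f"expected {len(AGE_BRACKETS)} bracket values, got {len(v)}")
        if any(x < 0 for x in v):
            raise ValueError("bracket values must be non-negative")
        return v

    @field_validator("p_cancel_by_bracket")
    @classmethod
    def _monotone_cancel(cls, v: list[float]) -> list[float]:
        if any(b < a for a, b in zip(v, v[1:])):
            raise ValueError("p_cancel_by_bracket must be non-decreasing across brackets")
        return v

    @model_validator(mode="after")
    def _rates_feasible(self) -> "PopulationConfig":
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must lie in [0, 1]")
        for pc, pn in zip(self.p_cancel_by_bracket, self.p_noshow_by_bracket):
            if pc + pn > 1.0:
                raise ValueError(f"cancel + no-show rates exceed 1 in a bracket: {pc}+{pn}")
        return self


@dataclass
class SimulatedPatient:
    """A profile plus the ground-truth outcome probabilities that
    generated it. The simulator draws outcomes from these; the risk
    model never sees them."""

    profile: PatientProfile
    p_attend: float
    p_cancel: float
    p_noshow: float


def _adjust(p: float, odds_factor: float) -> float:
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    odds = p / (1.0 - p) * odds_factor
    return odds / (1.0 + odds)


def generate_population(config: PopulationConfig) -> list[SimulatedPatient]:
    """Draw a deterministic population for the configured seed.

    Per-patient outcome probabilities start at the age-bracket rates and
    are adjusted on the odds scale by the gender and district factors;
    a configuration whose adjusted probabilities leave no attendance
    mass raises :class:`ConfigurationError`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    n = config.n_patients
    weights = np.asarray(config.bracket_weights, dtype=float)
    weights = weights / weights.sum()
    brackets = rng.choice(len(AGE_BRACKETS), size=n, p=weights)
    genders = rng.choice(sorted(config.gender_effect), size=n)
    districts = rng.choice(sorted(config.district_effects), size=n)
    travel = np.exp(
        np.log(config.travel_time_median_min)
        + config.travel_time_sigma * rng.standard_normal(n)
    )
    n_past = rng.poisson(config.mean_history_length, size=n)

    patients: list[SimulatedPatient] = []
    for i in range(n):
        b = int(brackets[i])
        g, d = str(genders[i]), str(districts[i])
        factor = config.gender_effect[g] * config.district_effects[d]
        pc = _adjust(config.p_cancel_by_bracket[b], factor)
        pn = _adjust(config.p_noshow_by_bracket[b], factor)
        pa = 1.0 - pc - pn
        if pa < 0.0:
            raise ConfigurationError(
                f"adjusted probabilities exceed 1 for bracket {AGE_BRACKETS[b]}, "
                f"gender {g}, district {d}: cancel={pc:.3f}, no_show={pn:.3f}"
            )
        lo, hi = _BRACKET_AGE_RANGE[AGE_BRACKETS[b]]
        age = int(rng.integers(lo, hi + 1))

        # behavioural history: first outcome from the patient's own
        # probabilities, later outcomes repeat the previous one with
        # probability `persistence`
        history: list[str] = []
        probs = np.array([pa, pc, pn])
        for _ in range(int(n_past[i])):
            if history and rng.random() < config.persistence:
                history.append(history[-1])
            else:
                history.append(STATUSES[int(rng.choice(3, p=probs))])
        profile = PatientProfile(
            patient_id=f"p{i:06d}",
            age_years=age,
            gender=g,
            district=d,
            travel_time_min=float(travel[i]),
            n_realized=history.count("realized"),
            n_canceled=history.count("canceled"),
            n_noshow=history.count("no_show"),
            history=tuple(history),
        )
        patients.append(
            SimulatedPatient(profile=profile, p_attend=pa, p_cancel=pc, p_noshow=pn)
        )
    return patients
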