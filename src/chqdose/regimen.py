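"""COVID-19 chloroquine dosing schedules.

A schedule is expressed in mg CHQ base per kg: two loading doses on day 1
(the licensed pediatric loading is 10 + 5 mg/kg, the Dutch CIDC adult
loading 8 + 4 mg/kg) and eight equal maintenance doses twice daily on days
2-5. The total cumulative dose is capped (default 3,300 mg, the 44 mg/kg x
75 kg adult total); adults are dosed for the 75-kg reference individual
irrespective of body weight.

Two distinct roundings appear: per-dose maintenance values are rounded to
one decimal (half away from zero), and the separate clinical
"final advice" rounding is a documented table-driven policy, because no
closed-form rule maps 5.4->5 and 2.5->2.5 simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, NamedTuple

import pandas as pd

__all__ = [
    "DoseEvent",
    "Regimen",
    "LoadingScheme",
    "Schedule",
    "ADULT_LOADING",
    "PEDIATRIC_LOADING",
    "PEDIATRIC_LOADING_LICENSED",
    "ADULT_SCHEDULE",
    "DEFAULT_CAP_MG",
    "DEFAULT_MAINTENANCE_TIMES_H",
    "round_one_decimal",
    "maintenance_per_dose",
    "total_mg_per_kg",
    "build_regimen",
    "round_final_advice",
    "AdvicePolicy",
    "DEFAULT_ADVICE_POLICY",
    "regimen_to_frame",
    "regimen_from_frame",
]

DEFAULT_CAP_MG = 3300.0
#: Twice-daily maintenance on days 2-5, mapped to clock hours from first dose.
DEFAULT_MAINTENANCE_TIMES_H = (24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0, 108.0)
N_MAINTENANCE_DOSES = 8


@dataclass(frozen=True)
class DoseEvent:
    time: float  # hours from first dose
    amount: float  # mg CHQ base

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")


@dataclass(frozen=True)
class LoadingScheme:
    """Day-1 loading: dose_1 at t=0, dose_2 after ``interval`` hours."""

    dose_1: float  # mg/kg
    dose_2: float  # mg/kg
    interval: float = 12.0  # hours

    def __post_init__(self) -> None:
        if min(self.dose_1, self.dose_2, self.interval) <= 0:
            raise ValueError("loading doses and interval must be > 0")


# Table-1 schedules print the 12-h loading interval; the licensed pediatric
# malaria loading (6-h interval) is kept available but is not the default.
ADULT_LOADING = LoadingScheme(8.0, 4.0, 12.0)
PEDIATRIC_LOADING = LoadingScheme(10.0, 5.0, 12.0)
PEDIATRIC_LOADING_LICENSED = LoadingScheme(10.0, 5.0, 6.0)


class Schedule(NamedTuple):
    """Per-dose mg/kg values: (loading_1, loading_2, maintenance)."""

    loading_1: float
    loading_2: float
    maintenance: float


ADULT_SCHEDULE = Schedule(8.0, 4.0, 4.0)  # 44 mg/kg total


@dataclass(frozen=True)
class Regimen:
    """Timed dose events built from an mg/kg schedule."""

    events: tuple[DoseEvent, ...]
    schedule_mg_per_kg: Schedule
    capped: bool = False

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("dose events must be sorted by time")

    @property
    def total_mg_per_kg(self) -> float:
        return total_mg_per_kg(self.schedule_mg_per_kg)

    @property
    def total_mg(self) -> float:
        return sum(e.amount for e in self.events)


def round_one_decimal(x: float) -> float:
    """Round to one decimal, half away from zero, on the decimal
    representation (float noise below 1e-9 is cleared first)."""
    d = Decimal(repr(x)).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def total_mg_per_kg(schedule: Schedule) -> float:
    """Total cumulative dose: loading_1 + loading_2 + 8 x maintenance."""
    schedule = Schedule(*schedule)
    return schedule.loading_1 + schedule.loading_2 + N_MAINTENANCE_DOSES * schedule.maintenance


def maintenance_per_dose(total: float, loading: LoadingScheme) -> float:
    """Per-dose maintenance (mg/kg): the remainder of the total after
    loading, equally divided over 8 twice-daily doses, rounded to one
    decimal (half away from zero)."""
    remainder = total - loading.dose_1 - loading.dose_2
    if remainder <= 0:
        raise ValueError(
            f"total dose {total} mg/kg does not exceed the loading sum "
            f"{loading.dose_1 + loading.dose_2} mg/kg"
        )
    return round_one_decimal(remainder / N_MAINTENANCE_DOSES)


def build_regimen(
    schedule: Schedule,
    weight: float,
    cap: float = DEFAULT_CAP_MG,
    loading_interval: float = 12.0,
    maintenance_times: tuple[float, ...] = DEFAULT_MAINTENANCE_TIMES_H,
    reference_weight: float | None = None,
) -> Regimen:
    """Build the 10-event regimen in absolute mg for one subject.

    ``reference_weight`` (e.g. 75 kg for adults) overrides the subject
    weight for the mg/kg -> mg conversion. If the cumulative total exceeds
    ``cap``, every dose is scaled by cap/total (proportional capping) and
    the ``capped`` flag is set.
    """
    schedule = Schedule(*schedule)
    if min(schedule) < 0:
        raise ValueError("schedule mg/kg values must be >= 0")
    if weight <= 0 or cap <= 0:
        raise ValueError("weight and cap must be > 0")
    w = reference_weight if reference_weight is not None else weight
    times = [0.0, loading_interval, *maintenance_times]
    mg_per_kg = [
        schedule.loading_1,
        schedule.loading_2,
        *([schedule.maintenance] * len(maintenance_times)),
    ]
    amounts = [m * w for m in mg_per_kg]
    total = sum(amounts)
    capped = total > cap
    if capped:
        scale = cap / total
        amounts = [a * scale for a in amounts]
    return Regimen(
        events=tuple(DoseEvent(t, a) for t, a in zip(times, amounts)),
        schedule_mg_per_kg=schedule,
        capped=capped,
    )


def _nearest_half(x: float) -> float:
    """Nearest multiple of 0.5; ties go toward the nearest whole number."""
    down = math.floor(x * 2.0) / 2.0
    up = down + 0.5
    if abs(x - down) < abs(up - x):
        return down
    if abs(up - x) < abs(x - down):
        return up
    # tie: prefer whichever of down/up is a whole number
    return down if float(down).is_integer() else up


@dataclass(frozen=True)
class AdvicePolicy:
    """Clinical rounding policy for the final dose advice.

    ``table`` maps one-decimal maintenance values (mg/kg) to their advised
    value; anything absent falls back to ``fallback`` (default: nearest
    multiple of 0.5, ties toward the nearest whole number).
    """

    table: dict[float, float] = field(default_factory=dict)
    fallback: Callable[[float], float] = _nearest_half

    def apply(self, maintenance: float) -> float:
        key = round_one_decimal(maintenance)
        return self.table.get(key, self.fallback(key))


#: The published clinical mapping: 5.4 -> 5, 5.2 -> 5, 3.7 -> 4, 2.5 -> 2.5.
DEFAULT_ADVICE_POLICY = AdvicePolicy(table={5.4: 5.0, 5.2: 5.0, 3.7: 4.0, 2.5: 2.5})


def round_final_advice(
    maintenance: float, policy: AdvicePolicy = DEFAULT_ADVICE_POLICY
) -> float:
    """Round a per-dose maintenance value for the final clinical advice."""
    if maintenance <= 0:
        raise ValueError("maintenance must be > 0")
    return policy.apply(maintenance)


def regimen_to_frame(regimen: Regimen) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_h": [e.time for e in regimen.events],
         "amount_mg": [e.amount for e in regimen.events]}
    )


def regimen_from_frame(frame: pd.DataFrame, schedule: Schedule, capped: bool = False) -> Regimen:
    events = tuple(
        DoseEvent(t, a) for t, a in zip(frame["time_h"], frame["amount_mg"])
    )
    return Regimen(events=events, schedule_mg_per_kg=Schedule(*schedule), capped=capped)
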