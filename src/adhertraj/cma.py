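"""Continuous medication availability, version 9 (CMA9).

CMA9 measures the fraction of the observation period on which medication
was theoretically available from refill records. Each day is weighted by
the supply ratio of the inter-refill interval it falls in: for the interval
between two consecutive fills, the available supply (the fill's days'
supply plus any carryover from earlier oversupply) is divided by the
interval length and capped at 1; supply exceeding the interval length is
carried into the next interval. The last interval runs from the final fill
to the period end and any supply overflowing the period end is discarded
(end-period exclusion). Days before the first in-period fill count as 0.

The overall CMA9 is the mean daily ratio over the whole period; the
windowed variant averages the same daily ratios over contiguous
non-overlapping windows (default 30 days, i.e. 12 monthly values over a
365-day year, with the 5 residual days contributing only to the overall
value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .cohort import DispensingEvent, ObservationPeriod

__all__ = [
    "SupplyInterval",
    "CmaTrajectory",
    "supply_intervals",
    "daily_ratio_vector",
    "compute_cma9",
    "compute_cma9_windows",
    "assign_refill_durations",
]


@dataclass(frozen=True)
class SupplyInterval:
    """One inter-refill interval with its supply bookkeeping.

    ``ratio = min(1, available_supply / (end - start))`` and
    ``carryover_out = max(0, available_supply - (end - start))``.
    """

    start: int
    end: int
    available_supply: float
    ratio: float
    carryover_out: float


@dataclass
class CmaTrajectory:
    """Per-patient windowed CMA9 values plus the overall CMA9."""

    patient_id: Optional[str]
    window_days: int
    values: np.ndarray
    overall: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _prepare_fills(
    events: Iterable[DispensingEvent], period: ObservationPeriod
) -> tuple[np.ndarray, np.ndarray]:
    """In-period fill days and supplies, sorted, same-day fills merged by summing."""
    days, supplies = [], []
    for ev in events:
        if period.start <= ev.dispense_date < period.end:
            days.append(ev.dispense_date)
            supplies.append(ev.days_supply)
    if not days:
        return np.empty(0, dtype=int), np.empty(0, dtype=float)
    days_arr = np.asarray(days, dtype=int)
    supp_arr = np.asarray(supplies, dtype=float)
    order = np.argsort(days_arr, kind="stable")
    days_arr, supp_arr = days_arr[order], supp_arr[order]
    uniq, inverse = np.unique(days_arr, return_inverse=True)
    merged = np.zeros(len(uniq))
    np.add.at(merged, inverse, supp_arr)
    return uniq, merged


def supply_intervals(
    events: Iterable[DispensingEvent], period: ObservationPeriod
) -> list[SupplyInterval]:
    """Chain carryover left to right across the inter-refill intervals."""
    days, supplies = _prepare_fills(events, period)
    out: list[SupplyInterval] = []
    carry = 0.0
    for i, (day, supply) in enumerate(zip(days, supplies)):
        end = int(days[i + 1]) if i + 1 < len(days) else period.end
        length = end - day
        available = supply + carry
        ratio = min(1.0, available / length)
        carry = max(0.0, available - length)
        out.append(
            SupplyInterval(
                start=int(day),
                end=end,
                available_supply=available,
                ratio=ratio,
                carryover_out=carry,
            )
        )
    return out  # supply carried past period.end is implicitly discarded


def daily_ratio_vector(
    events: Iterable[DispensingEvent], period: ObservationPeriod
) -> np.ndarray:
    """Per-day availability ratios over the observation period.

    Days before the first in-period fill are 0; every other day takes the
    ratio of the interval containing it. With no in-period events the
    vector is all zeros.
    """
    vec = np.zeros(period.length)
    for iv in supply_intervals(events, period):
        vec[iv.start - period.start : iv.end - period.start] = iv.ratio
    return vec


def compute_cma9(events: Iterable[DispensingEvent], period: ObservationPeriod) -> float:
    """Overall CMA9: mean daily availability ratio over the period."""
    return float(daily_ratio_vector(events, period).mean())


def compute_cma9_windows(
    events: Iterable[DispensingEvent],
    period: ObservationPeriod,
    window_days: int = 30,
    patient_id: Optional[str] = None,
) -> CmaTrajectory:
    """CMA9 averaged over contiguous non-overlapping windows.

    With the defaults (365-day period, 30-day windows) this yields 12
    monthly values covering days 0-359; days 360-364 contribute only to
    ``overall``.
    """
    if window_days <= 0:
        raise ValueError(f"window_days must be positive, got {window_days}")
    n_windows = period.length // window_days
    if n_windows < 1:
        raise ValueError(
            f"period of {period.length} d is shorter than one {window_days}-d window"
        )
    daily = daily_ratio_vector(events, period)
    values = daily[: n_windows * window_days].reshape(n_windows, window_days).mean(axis=1)
    return CmaTrajectory(
        patient_id=patient_id,
        window_days=window_days,
        values=values,
        overall=float(daily.mean()),
    )


def assign_refill_durations(
    events: Sequence[DispensingEvent],
    mode: str = "fixed30",
    rng: Optional[np.random.Generator] = None,
    choices: tuple[int, ...] = (30, 60, 90),
) -> list[DispensingEvent]:
    """Override recorded days' supply with analysis refill durations.

    ``fixed30`` sets every fill to 30 days (the primary analysis choice:
    the typical delivery period between successive supplies). ``sampled``
    keeps the first fill at 30 days and draws each subsequent fill's
    duration uniformly from ``choices`` (sensitivity analysis); requires a
    seeded ``rng``.
    """
    if not events:
        raise ValueError("assign_refill_durations requires at least one fill")
    ordered = sorted(events, key=lambda e: e.dispense_date)
    if mode == "fixed30":
        durations = [30] * len(ordered)
    elif mode == "sampled":
        if rng is None:
            raise ValueError("mode='sampled' requires a seeded numpy Generator")
        durations = [30] + [int(rng.choice(choices)) for _ in ordered[1:]]
    else:
        raise ValueError(f"unknown refill-duration mode {mode!r}")
    return [
        DispensingEvent(
            patient_id=e.patient_id,
            dispense_date=e.dispense_date,
            atc_code=e.atc_code,
            days_supply=d,
            dose_tier=e.dose_tier,
        )
        for e, d in zip(ordered, durations)
    ]
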