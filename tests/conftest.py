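"""Shared fixtures: a brute-force daily-supply oracle and random event streams.

The oracle recomputes per-day availability by literally walking the period
one day at a time, carrying a running stock of supply between fills —
deliberately independent of the package's vectorized interval
implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from adhertraj.cohort import SACVAL_ATC, DispensingEvent, ObservationPeriod


def sv_events(fills, patient_id="p"):
    """Shorthand: build sac/val events from (day, supply) pairs."""
    return [
        DispensingEvent(patient_id, int(day), SACVAL_ATC, int(supply))
        for day, supply in fills
    ]


def daily_oracle(events, period: ObservationPeriod) -> np.ndarray:
    """Brute-force per-day supply simulation of the CMA9 daily ratios.

    Walks day by day; at each fill day the stock (supply plus carryover)
    is spread evenly over the days until the next fill (or period end),
    capped at 1/day, and unused stock carries forward. Supply left at the
    period end is discarded.
    """
    fills = {}
    for e in events:
        if period.start <= e.dispense_date < period.end:
            fills[e.dispense_date] = fills.get(e.dispense_date, 0) + e.days_supply
    out = np.zeros(period.length)
    stock = 0.0
    ratio = 0.0
    fill_days = sorted(fills)
    for day in range(period.start, period.end):
        if day in fills:
            stock += fills[day]
            nxt = min((d for d in fill_days if d > day), default=period.end)
            span = nxt - day
            ratio = min(1.0, stock / span)
            stock = max(0.0, stock - span)
        out[day - period.start] = ratio if fill_days and day >= fill_days[0] else 0.0
    return out


def random_event_stream(rng: np.random.Generator, period: ObservationPeriod):
    """A random refill history: random fill days, supplies in 1..90, duplicates allowed."""
    n = int(rng.integers(0, 15))
    days = rng.integers(period.start, period.end, size=n)
    supplies = rng.integers(1, 91, size=n)
    return sv_events(zip(days, supplies))


@pytest.fixture(scope="session")
def default_pipeline_result():
    """One full pipeline run on the default synthetic cohort (n=2000), shared."""
    from adhertraj import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=7, generator={"n_patients": 2000}))
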