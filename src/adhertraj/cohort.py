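"""Incident-user cohort construction from pharmacy dispensing records.

Builds the analysis cohort for a new-user design: the index date is the
first dispensing of the target drug (sacubitril/valsartan, ATC C09DX04)
inside an enrolment window, patients are followed for a fixed observation
period from the index date, and patients who emigrate, die during
follow-up, or lack a full year of follow-up are excluded.

All dates are integer day offsets from an arbitrary study epoch and all
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Optional, Sequence

import pandas as pd

#: ATC code of the index drug (sacubitril/valsartan).
SACVAL_ATC = "C09DX04"

#: ATC-II classes counted as alternative heart-failure treatments when
#: assessing switching: diuretics, beta blockers, renin-angiotensin agents.
HF_ALTERNATIVE_CLASSES = ("C03", "C07", "C09")

#: Exclusion reasons in precedence order (first matching rule wins).
EXCLUSION_ORDER = ("moved", "short_followup", "death")


def iso_to_day(iso_date: str, epoch: str) -> int:
    """Convert an ISO-8601 calendar date to an integer day offset from ``epoch``."""
    return (_date.fromisoformat(iso_date) - _date.fromisoformat(epoch)).days


@dataclass(frozen=True)
class DispensingEvent:
    """One pharmacy fill: who, when, what (ATC), how many days of supply."""

    patient_id: str
    dispense_date: int
    atc_code: str
    days_supply: int
    dose_tier: Optional[str] = None  # {"low", "medium", "high"} when known

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise ValueError(
                f"days_supply must be >= 1, got {self.days_supply!r} "
                f"for patient {self.patient_id!r}"
            )

    @property
    def is_sacval(self) -> bool:
        return self.atc_code == SACVAL_ATC

    @property
    def atc_class(self) -> str:
        """ATC level-II class (first three characters)."""
        return self.atc_code[:3]


@dataclass
class PatientRecord:
    """Demographics, vital status, and baseline clinical burden for one patient.

    ``hospitalizations`` is a list of ``(admission_day, cause)`` pairs with
    cause in ``{"HF", "cardiovascular", "other"}``; admissions in the
    look-back year carry negative day offsets relative to the index date.
    """

    patient_id: str
    sex: str  # {"F", "M"}
    age_at_index: float
    death_date: Optional[int] = None
    region_exit_date: Optional[int] = None
    comorbidity_flags: frozenset = field(default_factory=frozenset)
    n_distinct_drugs: int = 0
    hospitalizations: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_at_index < 0:
            raise ValueError(f"age must be >= 0, got {self.age_at_index}")
        self.comorbidity_flags = frozenset(self.comorbidity_flags)

    @property
    def n_hosp_hf(self) -> int:
        return sum(1 for _, cause in self.hospitalizations if cause == "HF")

    @property
    def n_hosp_other(self) -> int:
        return sum(1 for _, cause in self.hospitalizations if cause != "HF")


@dataclass(frozen=True)
class ObservationPeriod:
    """Fixed follow-up window anchored at the index date, half-open [start, end)."""

    index_date: int
    length: int = 365

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"observation length must be positive, got {self.length}")

    @property
    def start(self) -> int:
        return self.index_date

    @property
    def end(self) -> int:
        return self.index_date + self.length


def find_index_date(
    events: Iterable[DispensingEvent], enrol_window: tuple[int, int]
) -> Optional[int]:
    """Earliest sac/val fill inside the enrolment window, or None.

    Enforces a new-user (incident) design over all supplied history: any
    sac/val fill *before* the window start disqualifies the patient, so a
    patient is indexed only on their first-ever fill.
    """
    lo, hi = enrol_window
    sacval_days = sorted(e.dispense_date for e in events if e.is_sacval)
    if not sacval_days:
        return None
    if sacval_days[0] < lo:  # prevalent user: treated before the window
        return None
    in_window = [d for d in sacval_days if lo <= d < hi]
    return in_window[0] if in_window else None


def apply_exclusions(
    patients: Sequence[PatientRecord],
    index_dates: dict,
    study_end: int,
    observation_days: int = 365,
) -> tuple[list, pd.DataFrame]:
    """Apply cohort exclusion rules; return included ids and an exclusion log.

    Rules, in fixed precedence order (first match wins, one reason per
    exclusion):

    1. ``moved`` — region exit recorded after the index date (follow-up data
       would be incomplete);
    2. ``short_followup`` — fewer than ``observation_days`` of study time
       remain after the index date;
    3. ``death`` — death inside the observation window (trajectory methods
       require complete follow-up, so deaths are excluded rather than
       censored).

    Every candidate either appears in the included list or exactly once in
    the log. Output order is by patient id, independent of input order.
    """
    included: list[str] = []
    log_rows: list[dict] = []
    for rec in sorted(patients, key=lambda r: str(r.patient_id)):
        if rec.patient_id not in index_dates:
            continue
        index = index_dates[rec.patient_id]
        reason = None
        if rec.region_exit_date is not None and rec.region_exit_date > index:
            reason = "moved"
        elif index + observation_days > study_end:
            reason = "short_followup"
        elif rec.death_date is not None and index <= rec.death_date < index + observation_days:
            reason = "death"
        if reason is None:
            included.append(rec.patient_id)
        else:
            log_rows.append(
                {"patient_id": rec.patient_id, "index_date": index, "reason": reason}
            )
    log = pd.DataFrame(log_rows, columns=["patient_id", "index_date", "reason"])
    return included, log


def build_cohort(
    events: Sequence[DispensingEvent],
    patients: Sequence[PatientRecord],
    enrol_window: tuple[int, int],
    study_end: int,
    observation_days: int = 365,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Index all patients and apply exclusions.

    Returns ``(cohort, exclusions)`` where ``cohort`` has columns
    ``patient_id, index_date`` for included patients.
    """
    by_patient: dict[str, list[DispensingEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    index_dates = {}
    for rec in patients:
        idx = find_index_date(by_patient.get(rec.patient_id, []), enrol_window)
        if idx is not None:
            index_dates[rec.patient_id] = idx
    included, log = apply_exclusions(patients, index_dates, study_end, observation_days)
    cohort = pd.DataFrame(
        {"patient_id": included, "index_date": [index_dates[p] for p in included]}
    )
    return cohort, log


# ---------------------------------------------------------------------------
# Delimited-text I/O (schemas shared with the synthetic generator)
# ---------------------------------------------------------------------------

_FLAG_COLUMNS_PREFIX = "flag_"


def events_from_frame(df: pd.DataFrame) -> list[DispensingEvent]:
    """Build events from a dispensing table (patient_id, date, atc, days_supply)."""
    tier = df["dose_tier"] if "dose_tier" in df.columns else None
    return [
        DispensingEvent(
            patient_id=str(row.patient_id),
            dispense_date=int(row.date),
            atc_code=str(row.atc),
            days_supply=int(row.days_supply),
            dose_tier=None if tier is None else str(df["dose_tier"].iloc[i]),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def patients_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Build patient records from a patient table.

    Comorbidity flags are read from ``flag_<condition>`` 0/1 columns;
    hospitalization counts from ``n_hosp_hf`` / ``n_hosp_other`` (synthetic
    admission days are not round-tripped, only counts).
    """
    flag_cols = [c for c in df.columns if c.startswith(_FLAG_COLUMNS_PREFIX)]
    records = []
    for row in df.to_dict("records"):
        flags = frozenset(
            c[len(_FLAG_COLUMNS_PREFIX):] for c in flag_cols if int(row[c]) == 1
        )
        hosp = [(-1, "HF")] * int(row.get("n_hosp_hf", 0)) + [(-1, "other")] * int(
            row.get("n_hosp_other", 0)
        )
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                age_at_index=float(row["age"]),
                death_date=None if pd.isna(row.get("death_date")) else int(row["death_date"]),
                region_exit_date=None
                if pd.isna(row.get("region_exit_date"))
                else int(row["region_exit_date"]),
                comorbidity_flags=flags,
                n_distinct_drugs=int(row.get("n_distinct_drugs", 0)),
                hospitalizations=hosp,
            )
        )
    return records
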