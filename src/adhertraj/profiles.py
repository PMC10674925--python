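"""Patient covariates and treatment-pattern outcomes.

Derives the per-patient baseline profile used to characterize adherence
groups: the age-adjusted Charlson comorbidity index (ACCI) with its three
severity classes, polypharmacy class, hospitalization counts, and
comedication classes — plus the treatment-pattern outcomes computed from
the refill history itself: persistence (days on treatment under a grace
period), discontinuation, and switching to an alternative heart-failure
drug class (diuretics C03, beta blockers C07, renin-angiotensin agents
C09), binned by time from the index date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    HF_ALTERNATIVE_CLASSES,
    DispensingEvent,
    ObservationPeriod,
    PatientRecord,
)

__all__ = [
    "CHARLSON_WEIGHTS",
    "PatientProfile",
    "SwitchRecord",
    "compute_acci",
    "acci_class",
    "classify_polypharmacy",
    "days_on_treatment",
    "discontinuation_day",
    "detect_switch",
    "build_profile",
    "summarize_groups",
]

#: Standard Charlson condition weights (1 / 2 / 3 / 6).
CHARLSON_WEIGHTS = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes": 1,
    "diabetes_with_complications": 2,
    "hemiplegia_paraplegia": 2,
    "renal_disease": 2,
    "malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids_hiv": 6,
}

#: Switch-timing bins measured from the index date (upper edges, inclusive).
SWITCH_BINS = (
    ("within_1_month", 30),
    ("within_2_months", 60),
    ("within_6_months", 180),
)


def compute_acci(comorbidity_flags: Iterable[str], age: float) -> int:
    """Age-adjusted Charlson comorbidity index.

    Sum of standard Charlson condition weights plus age points: one point
    per decade from 50-59 (+1) up to >=80 (+4). Unknown condition names are
    rejected explicitly rather than silently ignored.
    """
    score = 0
    for flag in comorbidity_flags:
        if flag not in CHARLSON_WEIGHTS:
            raise ValueError(
                f"unknown Charlson condition {flag!r}; "
                f"supported: {sorted(CHARLSON_WEIGHTS)}"
            )
        score += CHARLSON_WEIGHTS[flag]
    if age >= 80:
        score += 4
    elif age >= 70:
        score += 3
    elif age >= 60:
        score += 2
    elif age >= 50:
        score += 1
    return score


def acci_class(score: int) -> str:
    """ACCI severity class: low (0-1), mild (2-3), severe (>=4)."""
    if score < 0:
        raise ValueError(f"ACCI score must be >= 0, got {score}")
    if score <= 1:
        return "low"
    if score <= 3:
        return "mild"
    return "severe"


def classify_polypharmacy(n_distinct_drugs: int) -> str:
    """Polypharmacy class: none (<=4 drugs), polypharmacy (5-9), excessive (>=10)."""
    if n_distinct_drugs < 0:
        raise ValueError(f"drug count must be >= 0, got {n_distinct_drugs}")
    if n_distinct_drugs <= 4:
        return "none"
    if n_distinct_drugs <= 9:
        return "polypharmacy"
    return "excessive"


def _coverage_end(
    events: Sequence[DispensingEvent], period: ObservationPeriod, grace_days: int
) -> int:
    """Day supply runs out on the last fill before a gap exceeding the grace period.

    Supply accumulates across fills (early refills stockpile); a refill
    arriving more than ``grace_days`` after supply exhaustion marks
    discontinuation and later fills are ignored.
    """
    fills = sorted(
        (e for e in events if period.start <= e.dispense_date < period.end),
        key=lambda e: e.dispense_date,
    )
    if not fills:
        return period.start
    cover_end = fills[0].dispense_date + fills[0].days_supply
    for ev in fills[1:]:
        if ev.dispense_date > cover_end + grace_days:
            break
        cover_end = max(cover_end, ev.dispense_date) + ev.days_supply
    return cover_end


def days_on_treatment(
    events: Sequence[DispensingEvent], period: ObservationPeriod, grace_days: int = 30
) -> int:
    """Persistence: days from index to end of continuously-covered supply.

    Capped at the observation-period length.
    """
    return min(_coverage_end(events, period, grace_days), period.end) - period.start


def discontinuation_day(
    events: Sequence[DispensingEvent], period: ObservationPeriod, grace_days: int = 30
) -> Optional[int]:
    """Day treatment stopped, or None if supply persists to the period end."""
    cover_end = _coverage_end(events, period, grace_days)
    return None if cover_end >= period.end else cover_end


@dataclass(frozen=True)
class SwitchRecord:
    """Whether (and when) a patient moved to an alternative HF drug class."""

    patient_id: str
    switched: bool
    switch_day: Optional[int] = None  # day offset from the study epoch
    bin: Optional[str] = None
    target_atc_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.switched and (self.switch_day is None or self.target_atc_class is None):
            raise ValueError("a switch requires switch_day and target_atc_class")


def detect_switch(
    all_events: Sequence[DispensingEvent],
    index_date: int,
    discontinuation_day: Optional[int],
    patient_id: Optional[str] = None,
) -> SwitchRecord:
    """First fill of an alternative HF class at or after discontinuation.

    The switch is binned by days from the index date: <=30 within one
    month, <=60 within two, <=180 within six, else later. Patients who
    never discontinued, or discontinued without a qualifying fill, are not
    switchers.
    """
    pid = patient_id if patient_id is not None else (
        all_events[0].patient_id if all_events else ""
    )
    if discontinuation_day is None:
        return SwitchRecord(patient_id=pid, switched=False)
    candidates = sorted(
        (
            e
            for e in all_events
            if not e.is_sacval
            and e.atc_class in HF_ALTERNATIVE_CLASSES
            and e.dispense_date >= discontinuation_day
        ),
        key=lambda e: e.dispense_date,
    )
    if not candidates:
        return SwitchRecord(patient_id=pid, switched=False)
    first = candidates[0]
    delta = first.dispense_date - index_date
    bin_label = "later"
    for name, edge in SWITCH_BINS:
        if delta <= edge:
            bin_label = name
            break
    return SwitchRecord(
        patient_id=pid,
        switched=True,
        switch_day=first.dispense_date,
        bin=bin_label,
        target_atc_class=first.atc_class,
    )


@dataclass
class PatientProfile:
    """Baseline covariates at the index date."""

    patient_id: str
    age_at_index: float
    sex: str
    acci_score: int
    acci_class: str
    polypharmacy_class: str
    n_hosp_hf: int
    n_hosp_other: int
    comorbidity_flags: frozenset = field(default_factory=frozenset)
    comedication_classes: frozenset = field(default_factory=frozenset)


def build_profile(
    record: PatientRecord, events: Optional[Sequence[DispensingEvent]] = None
) -> PatientProfile:
    """Derive the covariate profile from a patient record.

    Comedication classes are the ATC-II classes of any non-index-drug fills
    supplied in ``events`` (empty when only the index drug is recorded).
    """
    score = compute_acci(record.comorbidity_flags, record.age_at_index)
    comeds = frozenset(
        e.atc_class for e in (events or []) if not e.is_sacval
    )
    return PatientProfile(
        patient_id=record.patient_id,
        age_at_index=record.age_at_index,
        sex=record.sex,
        acci_score=score,
        acci_class=acci_class(score),
        polypharmacy_class=classify_polypharmacy(record.n_distinct_drugs),
        n_hosp_hf=record.n_hosp_hf,
        n_hosp_other=record.n_hosp_other,
        comorbidity_flags=record.comorbidity_flags,
        comedication_classes=comeds,
    )


def profiles_to_frame(profiles: Sequence[PatientProfile]) -> pd.DataFrame:
    """Tabular view of profiles with the derived binary model covariates."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age_at_index,
                "sex": p.sex,
                "acci_score": p.acci_score,
                "acci_class": p.acci_class,
                "polypharmacy_class": p.polypharmacy_class,
                "n_hosp_hf": p.n_hosp_hf,
                "n_hosp_other": p.n_hosp_other,
                "sex_male": int(p.sex == "M"),
                "polypharmacy": int(p.polypharmacy_class != "none"),
                "hf_hosp": int(p.n_hosp_hf >= 1),
                "other_hosp": int(p.n_hosp_other >= 2),
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(
    profiles: pd.DataFrame,
    trajectories: pd.DataFrame,
    assignments: pd.DataFrame,
    switches: Optional[pd.DataFrame] = None,
    persistence: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-group descriptive table (one row per labeled adherence group).

    Inputs are patient-level frames keyed on ``patient_id``: ``profiles``
    (from :func:`profiles_to_frame`), ``trajectories`` with an ``overall``
    CMA9 column, ``assignments`` with a ``label`` column, and optionally
    ``switches`` (``switched``, ``bin``) and ``persistence``
    (``days_on_treatment``). Patient sets must coincide.
    """
    for name, frame in (("trajectories", trajectories), ("assignments", assignments)):
        if set(frame["patient_id"]) != set(profiles["patient_id"]):
            raise ValueError(f"patient ids of {name} do not match profiles")
    merged = profiles.merge(
        trajectories[["patient_id", "overall"]], on="patient_id"
    ).merge(assignments[["patient_id", "label"]], on="patient_id")
    if switches is not None:
        merged = merged.merge(switches, on="patient_id", how="left")
    if persistence is not None:
        merged = merged.merge(persistence, on="patient_id", how="left")
    n_total = len(merged)
    rows = []
    label_order = ["high", "partial_drop_off", "moderate", "low", "other"]
    for label in [l for l in label_order if l in set(merged["label"])]:
        grp = merged[merged["label"] == label]
        row = {
            "group": label,
            "n": len(grp),
            "pct": 100.0 * len(grp) / n_total,
            "cma_mean": grp["overall"].mean(),
            "cma_sd": grp["overall"].std(ddof=1) if len(grp) > 1 else 0.0,
            "age_mean": grp["age"].mean(),
            "pct_female": 100.0 * (grp["sex"] == "F").mean(),
            "pct_polypharmacy": 100.0 * grp["polypharmacy"].mean(),
            "pct_excessive_polypharmacy": 100.0
            * (grp["polypharmacy_class"] == "excessive").mean(),
            "acci_mean": grp["acci_score"].mean(),
            "pct_hf_hosp": 100.0 * grp["hf_hosp"].mean(),
            "pct_other_hosp": 100.0 * grp["other_hosp"].mean(),
        }
        if persistence is not None:
            q25, q50, q75 = grp["days_on_treatment"].quantile([0.25, 0.5, 0.75])
            row["days_on_treatment_median"] = q50
            row["days_on_treatment_iqr"] = q75 - q25
        if switches is not None:
            n_sw = int(grp["switched"].fillna(False).sum())
            row["n_switchers"] = n_sw
            row["pct_switchers"] = 100.0 * n_sw / len(grp) if len(grp) else 0.0
            for name, _ in SWITCH_BINS:
                row[f"pct_switch_{name}"] = (
                    100.0 * (grp["bin"] == name).sum() / n_sw if n_sw else 0.0
                )
            row["pct_switch_later"] = (
                100.0 * (grp["bin"] == "later").sum() / n_sw if n_sw else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)
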