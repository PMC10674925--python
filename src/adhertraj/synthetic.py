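"""Synthetic dispensing cohort generator.

Generates seeded pharmacy dispensing histories, baseline covariates, and
hospitalization counts with the statistical structure the downstream
analysis assumes, so the whole pipeline runs and is testable without
access to administrative claims data.

The generating model is a four-component mixture of adherence archetypes —
high, partial drop-off, moderate, and low — each defined by an inter-refill
gap process over a 365-day observation window with 30-day supplies:

* gaps are drawn from a lognormal distribution with a given mean and
  coefficient of variation (default 0.15), rounded to whole days and
  truncated at 1 day (strictly positive, right-skewed refill delays);
* archetypes with a ``stop_month`` issue no regular refill from that month
  on (early discontinuation);
* the partial drop-off archetype additionally receives sparse late refills
  (one per month with probability ``late_refill_prob``) after its regular
  refills stop, producing the high-then-low trajectory shape.

Default gap parameters were calibrated by Monte Carlo so each archetype's
mean overall CMA9 lands on the published group means (0.91 / 0.63 / 0.54 /
0.17); the partial drop-off archetype is calibrated to 0.62, just inside
the 0.03 calibration band, to keep its centroid's late-window mean safely
below the 0.35 labeling boundary.

Group membership follows a multinomial logit on baseline covariates with
configurable log-odds effects; intercepts are calibrated numerically so
the marginal group shares match the requested mixture weights regardless
of the planted effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import SACVAL_ATC, DispensingEvent, PatientRecord

__all__ = [
    "ArchetypeSpec",
    "GeneratorConfig",
    "SyntheticCohort",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_MIXTURE_WEIGHTS",
    "DEFAULT_COEFFICIENT_SPEC",
    "DEFAULT_COVARIATE_PREVALENCES",
    "events_from_archetype",
    "plant_group_membership",
    "calibrate_intercepts",
    "generate_cohort",
    "write_cohort_csvs",
]

#: Days per scheduling month in the gap processes.
MONTH_DAYS = 30

#: Covariate columns the multinomial planting model understands.
MODEL_COVARIATES = ("polypharmacy", "hf_hosp", "other_hosp", "sex_male", "age")


@dataclass(frozen=True)
class ArchetypeSpec:
    """One adherence archetype: a refill-gap process and its calibrated CMA9 target."""

    label: str
    gap_mean_days: float
    target_mean_cma: float
    gap_cv: float = 0.15
    stop_month: Optional[int] = None  # no regular refill at/after stop_month*30 days
    late_refill_prob: float = 0.0  # per-month refill probability after stop_month

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_mean_cma <= 1.0:
            raise ValueError(f"target_mean_cma must be in [0,1], got {self.target_mean_cma}")
        if self.gap_mean_days < 1:
            raise ValueError(f"gap_mean_days must be >= 1, got {self.gap_mean_days}")
        if self.gap_cv < 0:
            raise ValueError(f"gap_cv must be >= 0, got {self.gap_cv}")
        if not 0.0 <= self.late_refill_prob <= 1.0:
            raise ValueError(f"late_refill_prob must be in [0,1], got {self.late_refill_prob}")
        if self.label == "high" and self.stop_month is not None:
            raise ValueError("the high archetype persists all year: no stop_month allowed")
        if self.label == "low" and (self.stop_month is None or self.stop_month > 3):
            raise ValueError("the low archetype must stop by month 3")
        if self.late_refill_prob > 0 and self.stop_month is None:
            raise ValueError("late refills require a stop_month")


#: Calibrated defaults (Monte-Carlo calibration of mean overall CMA9; see
#: the module docstring). Order fixes the canonical group order.
DEFAULT_ARCHETYPES = (
    ArchetypeSpec(label="high", gap_mean_days=33.0, target_mean_cma=0.91),
    ArchetypeSpec(
        label="partial_drop_off",
        gap_mean_days=30.0,
        target_mean_cma=0.63,
        stop_month=6,
        late_refill_prob=0.18,
    ),
    ArchetypeSpec(label="moderate", gap_mean_days=57.8, target_mean_cma=0.54),
    ArchetypeSpec(label="low", gap_mean_days=35.0, target_mean_cma=0.17, stop_month=2),
)

#: Published group sizes 1898/874/862/821 of 4455 as exact fractions.
DEFAULT_MIXTURE_WEIGHTS = (1898 / 4455, 874 / 4455, 862 / 4455, 821 / 4455)

#: Published covariate effects (log odds) on group membership vs high adherence.
DEFAULT_COEFFICIENT_SPEC = {
    ("polypharmacy", "partial_drop_off"): math.log(1.194),
    ("hf_hosp", "low"): math.log(1.165),
    ("other_hosp", "low"): math.log(1.481),
}

#: Marginal covariate distributions (cohort-level prevalences and moments).
DEFAULT_COVARIATE_PREVALENCES = {
    "male": 0.700,
    "age": (69.1, 12.0),  # mean, SD in years
    # polypharmacy class shares (none / 5-9 drugs / >=10 drugs), renormalized
    "polypharmacy_class_probs": (0.306, 0.316, 0.371),
    "hf_hosp": 0.334,  # P(>=1 HF hospitalization in the look-back year)
    "other_hosp_rate": 0.82,  # Poisson rate of other-cause admissions (P(>=2)=0.196)
    # Charlson-coded comorbidity flags
    "diabetes": 0.114,
    "renal_disease": 0.046,
    "chronic_pulmonary_disease": 0.030,
    "myocardial_infarction": 0.077,
}

#: Index dose-tier shares (low / medium / high strength).
DOSE_TIER_PROBS = {"low": 0.660, "medium": 0.293, "high": 0.047}


@dataclass
class GeneratorConfig:
    """Everything the generator needs; deterministic given ``seed``."""

    n_patients: int
    seed: int
    mixture_weights: Sequence[float] = DEFAULT_MIXTURE_WEIGHTS
    coefficient_spec: Mapping = field(default_factory=lambda: dict(DEFAULT_COEFFICIENT_SPEC))
    covariate_prevalences: Mapping = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    observation_days: int = 365
    supply_days: int = 30
    archetypes: Sequence[ArchetypeSpec] = DEFAULT_ARCHETYPES

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != len(self.archetypes):
            raise ValueError(
                f"{len(w)} mixture weights for {len(self.archetypes)} archetypes"
            )
        if (w < 0).any():
            raise ValueError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w.sum()!r}")
        labels = [a.label for a in self.archetypes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"archetype labels must be unique, got {labels}")
        for (cov, grp), beta in self.coefficient_spec.items():
            if not np.isfinite(beta):
                raise ValueError(f"non-finite coefficient for ({cov!r}, {grp!r})")
            if grp not in labels[1:]:
                raise ValueError(
                    f"coefficient group {grp!r} is not a non-reference archetype"
                )
            if cov not in MODEL_COVARIATES:
                raise ValueError(f"unknown planted covariate {cov!r}")
        for key, val in self.covariate_prevalences.items():
            if isinstance(val, (int, float)) and key != "other_hosp_rate":
                if not 0.0 <= float(val) <= 1.0:
                    raise ValueError(f"prevalence {key!r}={val!r} outside [0,1]")

    @property
    def group_labels(self) -> tuple:
        return tuple(a.label for a in self.archetypes)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a JSON or YAML document."""
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if "seed" not in doc:
            raise ValueError(f"config {path} must provide a seed")
        if "coefficient_spec" in doc:  # keys arrive as "covariate:group" strings
            doc["coefficient_spec"] = {
                tuple(k.split(":")): float(v) for k, v in doc["coefficient_spec"].items()
            }
        if "archetypes" in doc:
            doc["archetypes"] = tuple(ArchetypeSpec(**a) for a in doc["archetypes"])
        return cls(**doc)


def events_from_archetype(
    spec: ArchetypeSpec,
    index_day: int,
    observation_days: int,
    rng: np.random.Generator,
    supply_days: int = 30,
    patient_id: str = "p",
    dose_tier: Optional[str] = None,
) -> list[DispensingEvent]:
    """Simulate one patient's refill history from an archetype's gap process.

    The first fill is at the index day; subsequent fill days accumulate
    lognormal gaps (rounded, >= 1 day) until the observation window or the
    archetype's stop month is reached; sparse late refills follow where the
    archetype defines them. All fills lie in ``[index_day, index_day +
    observation_days)``.
    """
    if spec.gap_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.gap_cv**2))
        mu = math.log(spec.gap_mean_days) - sigma**2 / 2.0
    else:
        sigma, mu = 0.0, math.log(spec.gap_mean_days)
    # regular refills follow the monthly schedule: none in the residual
    # partial month at the window end (full-year horizon = 12 x 30 d)
    horizon = (observation_days // MONTH_DAYS) * MONTH_DAYS
    stop_day = horizon if spec.stop_month is None else spec.stop_month * MONTH_DAYS
    offsets = [0]
    day = 0
    while True:
        gap = max(1, round(float(rng.lognormal(mu, sigma))))
        day += gap
        if day >= min(stop_day, observation_days):
            break
        offsets.append(day)
    if spec.late_refill_prob > 0.0 and stop_day is not None:
        for month in range(spec.stop_month, observation_days // MONTH_DAYS):
            if rng.random() < spec.late_refill_prob:
                lo = month * MONTH_DAYS
                hi = min((month + 1) * MONTH_DAYS, observation_days)
                offsets.append(int(rng.integers(lo, hi)))
    return [
        DispensingEvent(
            patient_id=patient_id,
            dispense_date=index_day + off,
            atc_code=SACVAL_ATC,
            days_supply=supply_days,
            dose_tier=dose_tier,
        )
        for off in sorted(set(offsets))
    ]


def _logits(
    X: pd.DataFrame,
    coefficient_spec: Mapping,
    intercepts: np.ndarray,
    groups: Sequence[str],
) -> np.ndarray:
    """n x G matrix of group log-odds (reference group = first, logit 0 + intercept)."""
    n = len(X)
    logits = np.tile(np.asarray(intercepts, dtype=float), (n, 1))
    for (cov, grp), beta in coefficient_spec.items():
        logits[:, list(groups).index(grp)] += beta * X[cov].to_numpy(dtype=float)
    return logits


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def calibrate_intercepts(
    X: pd.DataFrame,
    coefficient_spec: Mapping,
    weights: Sequence[float],
    groups: Sequence[str],
    tol: float = 1e-12,
    max_iter: int = 500,
) -> np.ndarray:
    """Intercepts making the marginal group shares equal ``weights``.

    Fixed-point iteration on log shares: with no planted effects this
    reduces to ``log(weights)`` exactly, so expected group counts equal
    ``n * weights``; with effects it absorbs their marginal shift.
    """
    w = np.asarray(weights, dtype=float)
    alpha = np.zeros(len(groups))
    live = w > 0.0
    alpha[~live] = -np.inf  # zero-weight groups are simply never drawn
    for _ in range(max_iter):
        pbar = _softmax(_logits(X, coefficient_spec, alpha, groups)).mean(axis=0)
        delta = np.zeros_like(alpha)
        delta[live] = np.log(w[live]) - np.log(pbar[live])
        delta[live] -= delta[live][0] if live[0] else 0.0  # pin the reference
        alpha[live] += delta[live]
        if np.abs(delta[live]).max() < tol:
            break
    return alpha


def plant_group_membership(
    covariates: Mapping[str, float],
    coefficient_spec: Mapping,
    rng: np.random.Generator,
    intercepts: Optional[Sequence[float]] = None,
    groups: Sequence[str] = ("high", "partial_drop_off", "moderate", "low"),
) -> str:
    """Draw one patient's group from the multinomial logit.

    P(group g) is proportional to exp(intercept_g + sum_j x_j beta_jg); the
    first group is the reference with all-zero planted coefficients.
    Missing (covariate, group) pairs mean beta = 0.
    """
    for (cov, grp), beta in coefficient_spec.items():
        if not np.isfinite(beta):
            raise ValueError(f"non-finite coefficient for ({cov!r}, {grp!r})")
    X = pd.DataFrame([covariates])
    alpha = np.zeros(len(groups)) if intercepts is None else np.asarray(intercepts, float)
    probs = _softmax(_logits(X, coefficient_spec, alpha, groups))[0]
    return str(groups[int(rng.choice(len(groups), p=probs))])


@dataclass
class SyntheticCohort:
    """A generated cohort: events, patient records, and the planted truth."""

    events: list  # DispensingEvent, all patients, sorted by (patient, day)
    patients: list  # PatientRecord
    true_groups: dict  # patient_id -> archetype label
    config: GeneratorConfig


def _draw_covariates(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    prev = {**DEFAULT_COVARIATE_PREVALENCES, **dict(cfg.covariate_prevalences)}
    n = cfg.n_patients
    age_mean, age_sd = prev["age"]
    age = np.clip(np.round(rng.normal(age_mean, age_sd, n)), 18, 99)
    male = rng.random(n) < prev["male"]
    pp = np.asarray(prev["polypharmacy_class_probs"], dtype=float)
    pp = pp / pp.sum()
    pp_class = rng.choice(3, size=n, p=pp)  # 0 none, 1 polypharmacy, 2 excessive
    low_edges, high_edges = np.array([1, 5, 10]), np.array([5, 10, 16])
    n_drugs = rng.integers(low_edges[pp_class], high_edges[pp_class])
    any_hf_hosp = rng.random(n) < prev["hf_hosp"]
    n_hosp_hf = np.where(any_hf_hosp, 1 + rng.poisson(0.4, n), 0)
    n_hosp_other = rng.poisson(prev["other_hosp_rate"], n)
    frame = pd.DataFrame(
        {
            "age": age,
            "sex_male": male.astype(int),
            "n_distinct_drugs": n_drugs,
            "n_hosp_hf": n_hosp_hf,
            "n_hosp_other": n_hosp_other,
            "polypharmacy": (n_drugs >= 5).astype(int),
            "hf_hosp": (n_hosp_hf >= 1).astype(int),
            "other_hosp": (n_hosp_other >= 2).astype(int),
        }
    )
    for flag in ("diabetes", "renal_disease", "chronic_pulmonary_disease",
                 "myocardial_infarction"):
        frame[f"flag_{flag}"] = (rng.random(n) < prev[flag]).astype(int)
    return frame


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; byte-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_labels)
    arch_by_label = {a.label: a for a in config.archetypes}

    cov = _draw_covariates(config, rng)
    alpha = calibrate_intercepts(
        cov, config.coefficient_spec, config.mixture_weights, groups
    )
    probs = _softmax(_logits(cov, config.coefficient_spec, alpha, groups))
    membership = (rng.random((len(cov), 1)) > probs.cumsum(axis=1)).sum(axis=1)
    tiers = list(DOSE_TIER_PROBS)
    tier_p = np.asarray(list(DOSE_TIER_PROBS.values()))
    tier_p = tier_p / tier_p.sum()

    events: list[DispensingEvent] = []
    patients: list[PatientRecord] = []
    true_groups: dict[str, str] = {}
    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        label = groups[int(membership[i])]
        true_groups[pid] = label
        tier = tiers[int(rng.choice(len(tiers), p=tier_p))]
        events.extend(
            events_from_archetype(
                arch_by_label[label],
                index_day=0,
                observation_days=config.observation_days,
                rng=rng,
                supply_days=config.supply_days,
                patient_id=pid,
                dose_tier=tier,
            )
        )
        row = cov.iloc[i]
        flags = frozenset(
            {"congestive_heart_failure"}  # HF cohort by construction
            | {
                f[len("flag_"):]
                for f in cov.columns
                if f.startswith("flag_") and row[f] == 1
            }
        )
        hosp = [(-30 * (j + 1), "HF") for j in range(int(row["n_hosp_hf"]))] + [
            (-30 * (j + 1), "other") for j in range(int(row["n_hosp_other"]))
        ]
        patients.append(
            PatientRecord(
                patient_id=pid,
                sex="M" if row["sex_male"] == 1 else "F",
                age_at_index=float(row["age"]),
                comorbidity_flags=flags,
                n_distinct_drugs=int(row["n_distinct_drugs"]),
                hospitalizations=hosp,
            )
        )
    return SyntheticCohort(
        events=events, patients=patients, true_groups=true_groups, config=config
    )


def write_cohort_csvs(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write dispensing, patient, and group-truth CSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    disp = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in cohort.events],
            "date": [e.dispense_date for e in cohort.events],
            "atc": [e.atc_code for e in cohort.events],
            "days_supply": [e.days_supply for e in cohort.events],
            "dose_tier": [e.dose_tier for e in cohort.events],
        }
    )
    pats = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort.patients],
            "sex": [p.sex for p in cohort.patients],
            "age": [p.age_at_index for p in cohort.patients],
            "n_distinct_drugs": [p.n_distinct_drugs for p in cohort.patients],
            "n_hosp_hf": [p.n_hosp_hf for p in cohort.patients],
            "n_hosp_other": [p.n_hosp_other for p in cohort.patients],
        }
    )
    flag_names = sorted(
        {f for p in cohort.patients for f in p.comorbidity_flags}
    )
    for name in flag_names:
        pats[f"flag_{name}"] = [
            int(name in p.comorbidity_flags) for p in cohort.patients
        ]
    truth = pd.DataFrame(
        sorted(cohort.true_groups.items()), columns=["patient_id", "true_group"]
    )
    paths = {
        "dispensing": outdir / "dispensing.csv",
        "patients": outdir / "patients.csv",
        "groups_truth": outdir / "groups_truth.csv",
    }
    disp.to_csv(paths["dispensing"], index=False)
    pats.to_csv(paths["patients"], index=False)
    truth.to_csv(paths["groups_truth"], index=False)
    return paths
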