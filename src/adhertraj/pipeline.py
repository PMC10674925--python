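"""End-to-end adherence-trajectory pipeline.

Chains the stages: simulate (or ingest) dispensing data -> build the
incident-user cohort -> compute windowed CMA9 trajectories -> cluster and
label trajectories -> derive covariate profiles and group summaries ->
fit the multinomial group-membership model -> write tabular outputs and a
JSON run manifest.

A single pipeline seed fans out to per-stage seeds derived by hashing the
stage name, so any stochastic stage can be re-run in isolation with the
same stream. All outputs are plain CSV plus one JSON manifest; rerunning
with the same config and seed reproduces them byte for byte (timings go to
the log, never the manifest).
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, cma, cohort as cohort_mod, models, profiles as profiles_mod
from .cohort import DispensingEvent, ObservationPeriod, PatientRecord
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError", "run_pipeline", "stage_seed"]

logger = logging.getLogger("adhertraj")

#: Stage names in execution order.
STAGES = ("simulate", "cohort", "adherence", "cluster", "profile", "model", "report")

#: Default candidate covariates for the group-membership model.
DEFAULT_CANDIDATES = ("age", "sex_male", "polypharmacy", "hf_hosp", "other_hosp")


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: pipeline seed XOR a hash of the stage name, below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run configuration. Exactly one of ``generator`` / ``input_paths`` is set."""

    seed: int
    generator: Optional[Mapping] = None  # GeneratorConfig kwargs (seed derived)
    input_paths: Optional[Mapping] = None  # {"dispensing": ..., "patients": ...}
    observation_days: int = 365
    window_days: int = 30
    grace_days: int = 30
    refill_mode: str = "fixed30"  # {"fixed30", "sampled", "recorded"}
    k_range: Sequence[int] = tuple(range(2, 7))
    n_starts: int = 20
    p_threshold: float = 0.05
    stepwise: bool = True
    candidate_covariates: Sequence[str] = DEFAULT_CANDIDATES
    enrol_window: Optional[tuple] = None  # derived from the data when absent
    study_end: Optional[int] = None
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if (self.generator is None) == (self.input_paths is None):
            raise ValueError("exactly one of generator / input_paths must be given")
        if self.refill_mode not in ("fixed30", "sampled", "recorded"):
            raise ValueError(f"unknown refill_mode {self.refill_mode!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from JSON or YAML; keyword overrides (e.g. CLI flags) win."""
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        doc.update({k: v for k, v in overrides.items() if v is not None})
        if "k_range" in doc:
            doc["k_range"] = tuple(int(k) for k in doc["k_range"])
        return cls(**doc)


@dataclass
class PipelineResult:
    """All stage outputs plus the run manifest."""

    manifest: dict
    cohort: pd.DataFrame
    exclusions: pd.DataFrame
    trajectories: pd.DataFrame
    assignments: pd.DataFrame
    centroids: pd.DataFrame
    profiles: pd.DataFrame
    persistence: pd.DataFrame
    switches: pd.DataFrame
    group_summary: pd.DataFrame
    or_table: pd.DataFrame
    cluster_model: clustering.ClusterModel
    model: Optional[models.MultinomialFit]
    events: list = field(repr=False, default_factory=list)
    patients: list = field(repr=False, default_factory=list)
    true_groups: Optional[dict] = None


def _trajectories_frame(trajs: list[cma.CmaTrajectory]) -> pd.DataFrame:
    n_w = len(trajs[0].values)
    data = {"patient_id": [t.patient_id for t in trajs]}
    for k in range(n_w):
        data[f"w{k + 1}"] = [float(t.values[k]) for t in trajs]
    data["overall"] = [t.overall for t in trajs]
    return pd.DataFrame(data)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order; deterministic given config + seed."""
    manifest: dict = {
        "pipeline": "adhertraj",
        "seed": int(config.seed),
        "stages": {},
    }
    t_all = time.perf_counter()

    def _stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                if exc is None:
                    logger.info("stage %s: done in %.2fs", name, dt)
                else:
                    manifest["stages"].setdefault(name, {})["status"] = "failed"
                    logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    # --- simulate / ingest ------------------------------------------------
    true_groups = None
    with _stage("simulate"):
        if config.generator is not None:
            gen_kwargs = dict(config.generator)
            gen_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
            gen_kwargs.setdefault("observation_days", config.observation_days)
            gen_cfg = GeneratorConfig(**gen_kwargs)
            syn = generate_cohort(gen_cfg)
            events, patients, true_groups = syn.events, syn.patients, syn.true_groups
            manifest["stages"]["simulate"] = {
                "seed": gen_cfg.seed,
                "n_patients": gen_cfg.n_patients,
                "n_events": len(events),
            }
        else:
            paths = dict(config.input_paths)
            for key in ("dispensing", "patients"):
                if key not in paths or not Path(paths[key]).exists():
                    raise FileNotFoundError(
                        f"missing input file for {key!r}: {paths.get(key)}"
                    )
            events = cohort_mod.events_from_frame(pd.read_csv(paths["dispensing"]))
            patients = cohort_mod.patients_from_frame(pd.read_csv(paths["patients"]))
            manifest["stages"]["simulate"] = {
                "ingested": {k: str(v) for k, v in paths.items()},
                "n_events": len(events),
                "n_patients": len(patients),
            }

    # --- cohort -----------------------------------------------------------
    with _stage("cohort"):
        sacval_days = [e.dispense_date for e in events if e.is_sacval]
        enrol = config.enrol_window or (min(sacval_days), max(sacval_days) + 1)
        study_end = (
            config.study_end
            if config.study_end is not None
            else max(sacval_days) + config.observation_days
        )
        cohort_df, exclusions = cohort_mod.build_cohort(
            events, patients, enrol, study_end, config.observation_days
        )
        if cohort_df.empty:
            raise ValueError("no patients remain after cohort exclusions")
        manifest["stages"]["cohort"] = {
            "n_included": int(len(cohort_df)),
            "n_excluded": int(len(exclusions)),
            "enrol_window": list(enrol),
            "study_end": int(study_end),
        }

    events_by_pid: dict[str, list[DispensingEvent]] = {}
    for ev in events:
        events_by_pid.setdefault(ev.patient_id, []).append(ev)
    index_by_pid = dict(zip(cohort_df["patient_id"], cohort_df["index_date"]))

    # --- adherence ---------------------------------------------------------
    with _stage("adherence"):
        rng = np.random.default_rng(stage_seed(config.seed, "adherence"))
        trajs = []
        sacval_by_pid = {}
        for pid, index in index_by_pid.items():
            period = ObservationPeriod(int(index), config.observation_days)
            sv = [e for e in events_by_pid[pid] if e.is_sacval]
            if config.refill_mode != "recorded":
                sv = cma.assign_refill_durations(sv, mode=config.refill_mode, rng=rng)
            sacval_by_pid[pid] = (sv, period)
            trajs.append(
                cma.compute_cma9_windows(sv, period, config.window_days, patient_id=pid)
            )
        traj_df = _trajectories_frame(trajs)
        manifest["stages"]["adherence"] = {
            "seed": stage_seed(config.seed, "adherence"),
            "n_trajectories": int(len(traj_df)),
            "window_days": config.window_days,
            "refill_mode": config.refill_mode,
        }

    # --- cluster ------------------------------------------------------------
    with _stage("cluster"):
        window_cols = [c for c in traj_df.columns if c.startswith("w")]
        X = traj_df[window_cols].to_numpy()
        model = clustering.select_k(
            X,
            k_range=config.k_range,
            n_starts=config.n_starts,
            seed=stage_seed(config.seed, "cluster"),
            patient_ids=traj_df["patient_id"].to_numpy(),
        )
        model = clustering.label_clusters(model)
        assignments = pd.DataFrame(
            {
                "patient_id": traj_df["patient_id"],
                "cluster": model.assignments,
                "label": [model.labels[int(c)] for c in model.assignments],
            }
        )
        centroids = pd.DataFrame(model.centroids, columns=window_cols)
        centroids.insert(0, "cluster", range(model.k))
        centroids["label"] = [model.labels[j] for j in range(model.k)]
        manifest["stages"]["cluster"] = {
            "seed": stage_seed(config.seed, "cluster"),
            "selected_k": int(model.k),
            "ch_by_k": {str(k): float(v) for k, v in model.ch_by_k.items()},
            "labels": {str(j): model.labels[j] for j in range(model.k)},
        }

    # --- profile -------------------------------------------------------------
    with _stage("profile"):
        pats_by_pid = {p.patient_id: p for p in patients}
        prof_list, pers_rows, switch_rows = [], [], []
        for pid, index in index_by_pid.items():
            rec = pats_by_pid[pid]
            all_ev = events_by_pid[pid]
            prof_list.append(profiles_mod.build_profile(rec, all_ev))
            sv, period = sacval_by_pid[pid]
            dot = profiles_mod.days_on_treatment(sv, period, config.grace_days)
            disc = profiles_mod.discontinuation_day(sv, period, config.grace_days)
            pers_rows.append({"patient_id": pid, "days_on_treatment": dot})
            sw = profiles_mod.detect_switch(all_ev, int(index), disc, patient_id=pid)
            switch_rows.append(
                {
                    "patient_id": pid,
                    "switched": sw.switched,
                    "switch_day": sw.switch_day,
                    "bin": sw.bin,
                    "target_atc_class": sw.target_atc_class,
                }
            )
        prof_df = profiles_mod.profiles_to_frame(prof_list)
        pers_df = pd.DataFrame(pers_rows)
        switch_df = pd.DataFrame(switch_rows)
        summary = profiles_mod.summarize_groups(
            prof_df, traj_df, assignments, switches=switch_df, persistence=pers_df
        )
        manifest["stages"]["profile"] = {
            "n_profiles": int(len(prof_df)),
            "groups": {r["group"]: int(r["n"]) for _, r in summary.iterrows()},
        }

    # --- model ----------------------------------------------------------------
    with _stage("model"):
        merged = prof_df.merge(assignments[["patient_id", "label"]], on="patient_id")
        design = merged[list(config.candidate_covariates)].astype(float)
        groups = merged["label"]
        reference = "high" if "high" in set(groups) else sorted(set(groups))[0]
        if config.stepwise:
            selected, fit = models.stepwise_select(
                design, groups, p_threshold=config.p_threshold, reference=reference
            )
        else:
            selected, fit = list(design.columns), models.fit_multinomial(
                design, groups, reference=reference
            )
        or_table = models.report_effects(fit)
        manifest["stages"]["model"] = {
            "reference_group": reference,
            "selected_covariates": list(selected),
            "log_likelihood": float(fit.log_likelihood),
            "n_obs": int(fit.n_obs),
        }

    # --- report -----------------------------------------------------------------
    result = PipelineResult(
        manifest=manifest,
        cohort=cohort_df,
        exclusions=exclusions,
        trajectories=traj_df,
        assignments=assignments,
        centroids=centroids,
        profiles=prof_df,
        persistence=pers_df,
        switches=switch_df,
        group_summary=summary,
        or_table=or_table,
        cluster_model=model,
        model=fit,
        events=events,
        patients=patients,
        true_groups=true_groups,
    )
    with _stage("report"):
        manifest["stages"]["report"] = {"outputs": []}
        if config.outdir is not None:
            written = write_outputs(result, config.outdir)
            manifest["stages"]["report"]["outputs"] = [str(p) for p in written]
    logger.info("pipeline done in %.2fs", time.perf_counter() - t_all)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write every stage's table as CSV plus the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {
        "cohort.csv": result.cohort,
        "exclusions.csv": result.exclusions,
        "trajectories.csv": result.trajectories,
        "assignments.csv": result.assignments,
        "centroids.csv": result.centroids,
        "profiles.csv": result.profiles,
        "persistence.csv": result.persistence,
        "switches.csv": result.switches,
        "group_summary.csv": result.group_summary,
        "or_table.csv": result.or_table,
    }
    written = []
    for name, frame in frames.items():
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)
    if result.true_groups is not None:
        path = outdir / "groups_truth.csv"
        pd.DataFrame(
            sorted(result.true_groups.items()), columns=["patient_id", "true_group"]
        ).to_csv(path, index=False)
        written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written
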