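"""Synthetic cohort generator: determinism, calibration, planted structure."""

import math

import numpy as np
import pandas as pd
import pytest

from adhertraj import (
    DEFAULT_ARCHETYPES,
    DEFAULT_MIXTURE_WEIGHTS,
    ArchetypeSpec,
    GeneratorConfig,
    ObservationPeriod,
    calibrate_intercepts,
    compute_cma9,
    events_from_archetype,
    generate_cohort,
    plant_group_membership,
    write_cohort_csvs,
)


def archetype(label):
    return next(a for a in DEFAULT_ARCHETYPES if a.label == label)


def mean_cma_of(spec, n, seed):
    rng = np.random.default_rng(seed)
    period = ObservationPeriod(0, 365)
    return float(
        np.mean(
            [
                compute_cma9(events_from_archetype(spec, 0, 365, rng), period)
                for _ in range(n)
            ]
        )
    )


class TestEventsFromArchetype:
    def test_zero_dispersion_monthly_fills(self):
        spec = ArchetypeSpec(label="high", gap_mean_days=30.0, target_mean_cma=0.9,
                             gap_cv=0.0)
        events = events_from_archetype(spec, 0, 365, np.random.default_rng(0))
        assert [e.dispense_date for e in events] == list(range(0, 360, 30))
        assert all(e.days_supply == 30 for e in events)

    def test_low_archetype_stops_by_month_two(self):
        spec = archetype("low")
        for seed in range(50):
            events = events_from_archetype(spec, 0, 365, np.random.default_rng(seed))
            assert 1 <= len(events) <= 3
            assert all(e.dispense_date < 60 for e in events)

    def test_all_fills_inside_observation_window(self):
        rng = np.random.default_rng(1)
        for spec in DEFAULT_ARCHETYPES:
            for _ in range(20):
                events = events_from_archetype(spec, 0, 365, rng)
                assert events[0].dispense_date == 0
                assert all(0 <= e.dispense_date < 365 for e in events)
                days = [e.dispense_date for e in events]
                assert days == sorted(set(days))

    def test_moderate_gap_process_mean_cma(self):
        # mean gap of ~56 d with 30-d supplies: expected CMA about 30/56
        # (slightly above because the initial fill is a free renewal epoch)
        spec = ArchetypeSpec(label="moderate", gap_mean_days=56.0, target_mean_cma=0.54)
        assert mean_cma_of(spec, 1500, seed=2) == pytest.approx(30 / 56, abs=0.025)

    def test_archetype_calibration_within_band(self):
        # each default archetype's mean overall CMA9 within 0.03 of target
        for spec in DEFAULT_ARCHETYPES:
            m = mean_cma_of(spec, 1200, seed=3)
            assert m == pytest.approx(spec.target_mean_cma, abs=0.03), spec.label


class TestArchetypeInvariants:
    def test_high_cannot_stop(self):
        with pytest.raises(ValueError, match="stop_month"):
            ArchetypeSpec(label="high", gap_mean_days=33, target_mean_cma=0.9,
                          stop_month=6)

    def test_low_must_stop_early(self):
        with pytest.raises(ValueError, match="month 3"):
            ArchetypeSpec(label="low", gap_mean_days=35, target_mean_cma=0.17,
                          stop_month=5)

    def test_target_in_unit_interval(self):
        with pytest.raises(ValueError, match="target"):
            ArchetypeSpec(label="moderate", gap_mean_days=50, target_mean_cma=1.2)


class TestPlantGroupMembership:
    def test_zero_coefficients_uniform(self):
        rng = np.random.default_rng(4)
        draws = [
            plant_group_membership({"x": 1.0}, {}, rng) for _ in range(4000)
        ]
        freqs = pd.Series(draws).value_counts(normalize=True)
        assert np.allclose(freqs, 0.25, atol=0.03)

    def test_single_binary_covariate_or_exact_by_construction(self):
        # with beta = ln 2 on group low, the odds ratio across strata is 2
        from adhertraj.synthetic import _logits, _softmax

        beta = {("polypharmacy", "low"): math.log(2)}
        groups = ("high", "partial_drop_off", "moderate", "low")
        X = pd.DataFrame({"polypharmacy": [0.0, 1.0]})
        p = _softmax(_logits(X, beta, np.zeros(4), groups))
        odds0 = p[0, 3] / p[0, 0]
        odds1 = p[1, 3] / p[1, 0]
        assert odds1 / odds0 == pytest.approx(2.0, rel=1e-12)

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            plant_group_membership({"x": 1.0}, {("x", "low"): np.inf},
                                   np.random.default_rng(0))


class TestCalibrateIntercepts:
    def test_null_spec_gives_log_weights(self):
        X = pd.DataFrame({"polypharmacy": np.zeros(100)})
        w = np.asarray(DEFAULT_MIXTURE_WEIGHTS)
        alpha = calibrate_intercepts(X, {}, w, ("high", "partial_drop_off",
                                                "moderate", "low"))
        expected = np.log(w) - np.log(w[0])
        np.testing.assert_allclose(alpha - alpha[0], expected, atol=1e-10)

    def test_marginal_shares_match_weights_with_effects(self):
        from adhertraj.synthetic import _logits, _softmax

        rng = np.random.default_rng(5)
        X = pd.DataFrame({"polypharmacy": rng.integers(0, 2, 3000).astype(float),
                          "other_hosp": rng.integers(0, 2, 3000).astype(float)})
        spec = {("polypharmacy", "partial_drop_off"): 0.6, ("other_hosp", "low"): 0.9}
        groups = ("high", "partial_drop_off", "moderate", "low")
        w = np.asarray(DEFAULT_MIXTURE_WEIGHTS)
        alpha = calibrate_intercepts(X, spec, w, groups)
        pbar = _softmax(_logits(X, spec, alpha, groups)).mean(axis=0)
        np.testing.assert_allclose(pbar, w, atol=1e-9)


class TestGenerateCohort:
    def test_seeded_runs_are_identical(self):
        cfg = GeneratorConfig(n_patients=100, seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.events == b.events
        assert a.true_groups == b.true_groups
        assert [p.__dict__ for p in a.patients] == [p.__dict__ for p in b.patients]

    def test_every_patient_fills_at_index(self):
        syn = generate_cohort(GeneratorConfig(n_patients=50, seed=1))
        first_fill = {}
        for e in syn.events:
            first_fill.setdefault(e.patient_id, e.dispense_date)
        assert len(first_fill) == 50
        assert all(d == 0 for d in first_fill.values())

    def test_pure_high_mixture_hits_target_band(self):
        cfg = GeneratorConfig(n_patients=400, seed=2, mixture_weights=(1, 0, 0, 0),
                              coefficient_spec={})
        syn = generate_cohort(cfg)
        period = ObservationPeriod(0, 365)
        by_pid = {}
        for e in syn.events:
            by_pid.setdefault(e.patient_id, []).append(e)
        cmas = np.array([compute_cma9(ev, period) for ev in by_pid.values()])
        target = DEFAULT_ARCHETYPES[0].target_mean_cma
        se = cmas.std(ddof=1) / np.sqrt(len(cmas))
        assert abs(cmas.mean() - target) <= max(3 * se, 0.01)

    def test_group_fractions_match_planted_weights(self):
        cfg = GeneratorConfig(n_patients=2000, seed=3)
        syn = generate_cohort(cfg)
        counts = pd.Series(syn.true_groups).value_counts(normalize=True)
        for w, label in zip(DEFAULT_MIXTURE_WEIGHTS,
                            ("high", "partial_drop_off", "moderate", "low")):
            se = math.sqrt(w * (1 - w) / 2000)
            assert abs(counts[label] - w) <= 3 * se, label

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(n_patients=10, seed=0, mixture_weights=(0.5, 0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="positive"):
            GeneratorConfig(n_patients=0, seed=0)
        with pytest.raises(ValueError, match="nonnegative"):
            GeneratorConfig(n_patients=10, seed=0,
                            mixture_weights=(1.2, -0.2, 0.0, 0.0))
        with pytest.raises(ValueError, match="non-finite"):
            GeneratorConfig(n_patients=10, seed=0,
                            coefficient_spec={("polypharmacy", "low"): np.nan})
        with pytest.raises(ValueError, match="prevalence"):
            GeneratorConfig(n_patients=10, seed=0,
                            covariate_prevalences={"male": 1.4})

    def test_csv_round_trip(self, tmp_path):
        syn = generate_cohort(GeneratorConfig(n_patients=30, seed=4))
        paths = write_cohort_csvs(syn, tmp_path)
        disp = pd.read_csv(paths["dispensing"])
        pats = pd.read_csv(paths["patients"])
        truth = pd.read_csv(paths["groups_truth"])
        assert set(disp.columns) >= {"patient_id", "date", "atc", "days_supply"}
        assert len(pats) == 30 and len(truth) == 30
        assert (disp["atc"] == "C09DX04").all()

    def test_config_from_yaml(self, tmp_path):
        doc = tmp_path / "gen.yaml"
        doc.write_text(
            "n_patients: 25\nseed: 9\n"
            "coefficient_spec:\n  'polypharmacy:low': 0.4\n"
        )
        cfg = GeneratorConfig.from_file(doc)
        assert cfg.n_patients == 25
        assert cfg.coefficient_spec == {("polypharmacy", "low"): 0.4}
        doc2 = tmp_path / "bad.yaml"
        doc2.write_text("n_patients: 25\n")
        with pytest.raises(ValueError, match="seed"):
            GeneratorConfig.from_file(doc2)
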