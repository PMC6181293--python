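import dataclasses

import numpy as np
import pandas as pd
import pytest

from crowdvoc.evaluate import ModelConfig, enumerate_splits, evaluate_compound
from crowdvoc.features import feature_names
from crowdvoc.io import (build_study, read_compound_table, read_screenings,
                         slice_screening)
from crowdvoc.preprocess import (PreprocessConfig, RoomParams,
                                 preprocess_screening, trim_tail)
from crowdvoc.synthetic import (ClassProfile, CompoundSpec, StudySpec,
                                draw_film_schedule, generate_study,
                                generate_study_files, make_separable_spec,
                                simulate_screening)

from conftest import pipeline_features


def quiet_spec(**overrides) -> StudySpec:
    """A noise-free, event-free single-compound study for exactness checks."""
    base = dict(
        profiles=(
            ClassProfile(0, n_films=1, screenings_per_film=(1, 1),
                         event_rate_per_h=0.0, event_amplitude=0.0),
            ClassProfile(6, n_films=1, screenings_per_film=(1, 1),
                         event_rate_per_h=0.0, event_amplitude=0.0),
        ),
        compounds=(CompoundSpec("m69.0699", noise_sigma=0.0, inflow=0.0),),
        exit_spike=False,
        entry_ramp_min=0.0,
        seed=5,
    )
    base.update(overrides)
    return StudySpec(**base)


class TestGeneration:
    def test_record_counting(self):
        spec = make_separable_spec(seed=2, n_films=(2, 2, 2, 2),
                                   screenings_per_film=10)
        records, _ = generate_study(spec)
        assert len(records) == 80
        assert len({r.film_title for r in records}) == 8

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        spec = quiet_spec()
        m1, c1 = generate_study_files(spec, tmp_path / "a")
        m2, c2 = generate_study_files(spec, tmp_path / "b")
        assert m1.read_bytes() == m2.read_bytes()
        assert c1.read_bytes() == c2.read_bytes()

    def test_files_round_trip_through_the_readers(self, tmp_path):
        spec = make_separable_spec(seed=3, n_films=(1, 1, 1, 1),
                                   screenings_per_film=2)
        meta, comp = generate_study_files(spec, tmp_path)
        records = read_screenings(meta)
        tables = read_compound_table(comp)
        study = build_study(records, tables)
        assert len(study.active_screenings()) == 8
        assert study.compounds == ["m69.0699"]

    def test_campaign_shaped_study_enumerates_24_combos(self):
        profiles = (
            ClassProfile(0, 2, (1, 40), screening_counts=(18, 33)),
            ClassProfile(6, 3, (1, 40), screening_counts=(10, 12, 13)),
            ClassProfile(12, 3, (1, 40), screening_counts=(2, 8, 34)),
            ClassProfile(16, 3, (1, 40), screening_counts=(1, 1, 3)),
        )
        spec = StudySpec(profiles=profiles,
                         compounds=(CompoundSpec("m69.0699"),), seed=4)
        records, _ = generate_study(spec)
        assert len(records) == 135
        together = frozenset({"fsk16-film1", "fsk16-film2"})
        plan = enumerate_splits(records, 8, together)
        assert plan.n_combos == 24


class TestForwardModel:
    def test_null_film_reduces_to_pure_box_model(self):
        spec = quiet_spec()
        feats, plan, fits = pipeline_features(spec, min_test_screenings=1)
        # no events, no noise: residuals vanish (up to the one-sample
        # occupancy discretization at entry) and no peaks are found
        assert feats["std"].max() < 1e-5
        assert (feats["n_peaks_robust_per_min"] == 0).all()

    def test_baseline_emission_recovered_from_noise_free_screening(self):
        spec = quiet_spec()
        profile = spec.profiles[0]
        rng = np.random.default_rng(0)
        sched = draw_film_schedule(profile, "f", 100.0, rng, spec)
        record, traces = simulate_screening(profile, sched, spec, rng,
                                            viewer_count=100)
        full = traces["m69.0699"]
        window = slice_screening(full, record)
        _, fit = preprocess_screening(window, record, spec.room,
                                      PreprocessConfig(), full_series=full)
        assert fit.emission_rate == pytest.approx(profile.baseline_emission,
                                                  rel=1e-3)

    def test_per_person_traces_match_across_audience_sizes(self):
        spec = quiet_spec()
        profile = spec.profiles[0]
        rng = np.random.default_rng(1)
        sched = draw_film_schedule(profile, "f", 100.0, rng, spec)
        traces = {}
        for n in (50, 150):
            record, t = simulate_screening(profile, sched, spec,
                                           np.random.default_rng(2),
                                           viewer_count=n)
            window = slice_screening(t["m69.0699"], record)
            traces[n] = window.values / n
        np.testing.assert_allclose(traces[50], traces[150], atol=1e-12)

    def test_final_trim_removes_the_exit_spike_apex(self):
        spec = quiet_spec(
            exit_spike=True, entry_ramp_min=5.0,
            compounds=(CompoundSpec("m69.0699", noise_sigma=0.0, inflow=0.0,
                                    exit_spike=True),))
        profile = spec.profiles[0]
        rng = np.random.default_rng(3)
        sched = draw_film_schedule(profile, "f", 100.0, rng, spec)
        record, traces = simulate_screening(profile, sched, spec, rng,
                                            viewer_count=100)
        window = slice_screening(traces["m69.0699"], record)
        apex_ts = window.timestamps[np.argmax(window.values)]
        cutoff = np.datetime64(record.end_time.to_datetime64(), "s") \
            - np.timedelta64(300, "s")
        assert apex_ts > cutoff  # the spike tops out in the last 5 minutes
        trimmed = trim_tail(window, 5.0)
        assert trimmed.timestamps[-1] <= cutoff
        assert trimmed.values.max() < window.values.max() * 0.8

    def test_event_schedule_shared_across_screenings_of_a_film(self):
        spec = quiet_spec()
        profiles = tuple(
            dataclasses.replace(p, event_rate_per_h=10.0,
                                event_amplitude=5000.0,
                                screenings_per_film=(2, 2))
            for p in spec.profiles)
        spec = dataclasses.replace(spec, profiles=profiles, seed=9)
        records, tables = generate_study(spec)
        study = build_study(records, tables)
        by_film = {}
        for rec in study.active_screenings():
            window = slice_screening(tables["m69.0699"], rec)
            res, _ = preprocess_screening(window, rec, spec.room,
                                          full_series=tables["m69.0699"])
            minute_of_max = np.argmax(res.residuals) * res.step_minutes
            by_film.setdefault(rec.film_title, []).append(minute_of_max)
        for film, apexes in by_film.items():
            assert len(apexes) == 2
            assert abs(apexes[0] - apexes[1]) <= 1.0  # same scene, same time


class TestNoiseDegradesPerformance:
    def test_mean_auc_decreases_with_noise(self):
        names = feature_names()
        means = []
        for sigma in (0.05, 1.0, 20.0):
            spec = make_separable_spec(seed=6)
            spec = dataclasses.replace(
                spec, compounds=(dataclasses.replace(
                    spec.compounds[0], noise_sigma=sigma),))
            feats, plan, _ = pipeline_features(spec)
            res = evaluate_compound(feats, plan,
                                    ModelConfig(n_trees=60, seed=6), names)
            means.append(np.mean([res.auc_mean(c) for c in plan.classes]))
        assert means[0] > means[1] > means[2]
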