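import dataclasses

import numpy as np
import pytest

from thermadiff import (
    ConfigError,
    GeneratorConfig,
    InjurySpec,
    generate_cohorts,
    minute_differentials,
    read_registry,
    simulate_patient_stream,
    write_registry,
)
from thermadiff.stream_io import LOCATION_INDEX
from thermadiff.synthetic import default_injury_presets, sample_null_patient_stats

from conftest import make_patient


class TestConfigValidation:
    def test_ambient_must_be_below_baseline(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(ambient_temp=90.0, baseline_temp_mean=85.0)

    @pytest.mark.parametrize("field", ["bilateral_noise_sd", "drift_sd", "baseline_temp_sd"])
    def test_negative_sd_rejected(self, field):
        with pytest.raises(ConfigError):
            GeneratorConfig(**{field: -0.1})

    def test_nonpositive_span_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(days=0)


class TestInjurySpec:
    def test_diffuse_must_cover_all_locations(self):
        with pytest.raises(ConfigError, match="diffuse"):
            InjurySpec("osteomyelitis", "right", ("hallux",), 10, 20, 5.0, 3)

    def test_focal_limited_to_two_locations(self):
        with pytest.raises(ConfigError, match="focal"):
            InjurySpec("ulcer", "right", ("hallux", "heel", "arch"), 10, 20, 5.0, 3)

    def test_onset_before_diagnosis(self):
        with pytest.raises(ConfigError):
            InjurySpec("ulcer", "right", ("hallux",), 20, 20, 5.0, 3)

    def test_peak_positive(self):
        with pytest.raises(ConfigError):
            InjurySpec("ulcer", "right", ("hallux",), 10, 20, 0.0, 3)

    def test_injury_outside_span_rejected(self):
        cfg = GeneratorConfig(days=50)
        patient = make_patient()  # diagnosis day 100
        with pytest.raises(ConfigError, match="outside"):
            simulate_patient_stream(patient, cfg)

    def test_ramp_values(self):
        spec = InjurySpec("ulcer", "right", ("hallux",), 10, 30, 6.0, 3)
        assert spec.offset_on_day(9) == 0.0
        assert spec.offset_on_day(10) == 0.0
        assert spec.offset_on_day(11) == pytest.approx(2.0)
        assert spec.offset_on_day(13) == 6.0
        assert spec.offset_on_day(29) == 6.0
        step = InjurySpec("ulcer", "right", ("hallux",), 10, 30, 6.0, 0)
        assert step.offset_on_day(10) == 6.0


class TestStreamStructure:
    def test_determinism(self, small_config):
        p = make_patient("S01")
        a = simulate_patient_stream(p, small_config)
        b = simulate_patient_stream(p, small_config)
        np.testing.assert_array_equal(a.temps, b.temps)
        np.testing.assert_array_equal(a.worn, b.worn)

    def test_different_seed_differs(self, small_config):
        p = make_patient("S01")
        a = simulate_patient_stream(p, small_config)
        b = simulate_patient_stream(p, dataclasses.replace(small_config, seed=6))
        assert not np.array_equal(a.temps, b.temps)

    def test_full_span_one_record_per_minute(self, noiseless_config):
        p = make_patient("C01", cohort="control", injury=None)
        stream = simulate_patient_stream(p, noiseless_config)
        assert len(stream) == noiseless_config.days * 1440

    def test_ambient_when_not_worn(self, noiseless_config):
        p = make_patient("C01", cohort="control", injury=None)
        stream = simulate_patient_stream(p, noiseless_config)
        off = ~stream.worn.any(axis=1)
        assert np.all(stream.temps[off] == noiseless_config.ambient_temp)

    def test_noiseless_differential_exactly_zero(self, noiseless_config):
        p = make_patient("C01", cohort="control", injury=None)
        stream = simulate_patient_stream(p, noiseless_config)
        diffs = minute_differentials(stream)
        assert (diffs["delta"] == 0.0).all()

    def test_step_injury_differential_exactly_peak(self, noiseless_config):
        injury = InjurySpec("ulcer", "right", ("mts5",), 5, 10, 5.0, 0)
        cfg = dataclasses.replace(noiseless_config, n_study=1, n_control=0)
        p = make_patient("S01", injury=injury)
        stream = simulate_patient_stream(p, cfg)
        diffs = minute_differentials(stream)
        at_loc = diffs[diffs["location"] == "mts5"]
        assert (at_loc[at_loc["day"] >= 5]["delta"] == 5.0).all()
        assert (at_loc[at_loc["day"] < 5]["delta"] == 0.0).all()
        # other locations untouched
        assert (diffs[diffs["location"] != "mts5"]["delta"] == 0.0).all()


class TestStatisticalStructure:
    def _many_minutes_stream(self, noise_sd, injury=None, days=30):
        cfg = GeneratorConfig(
            n_study=1 if injury else 0, n_control=0 if injury else 1, days=days,
            wear_minutes_per_day_mean=600, wear_minutes_per_day_sd=0,
            bilateral_noise_sd=noise_sd, patient_noise_cv=0.0, seed=21,
        )
        cohort = "study" if injury else "control"
        p = make_patient("X01", cohort=cohort, injury=injury)
        return simulate_patient_stream(p, cfg)

    def test_noise_sd_of_differential(self):
        """Per-minute single-location differential SD ~= noise_sd * sqrt(2)."""
        stream = self._many_minutes_stream(noise_sd=0.5)
        diffs = minute_differentials(stream)
        one_loc = diffs[diffs["location"] == "hallux"]["delta"].to_numpy()
        assert len(one_loc) >= 10_000
        expected = 0.5 * np.sqrt(2)
        assert abs(one_loc.std(ddof=1) - expected) / expected < 0.05

    def test_null_mean_within_4_se(self):
        stream = self._many_minutes_stream(noise_sd=0.5)
        diffs = minute_differentials(stream)
        one_loc = diffs[diffs["location"] == "hallux"]["delta"].to_numpy()
        se = 0.5 * np.sqrt(2) / np.sqrt(len(one_loc))
        assert abs(one_loc.mean()) < 4 * se

    def test_injected_offset_recovery(self):
        sigma, peak = 0.5, 3.0
        injury = InjurySpec("ulcer", "right", ("heel",), 5, 25, peak, 5)
        stream = self._many_minutes_stream(noise_sd=sigma, injury=injury)
        diffs = minute_differentials(stream)
        post_peak = diffs[(diffs["location"] == "heel") & (diffs["day"] >= 10)]
        n = len(post_peak)
        tol = 4 * sigma * np.sqrt(2) / np.sqrt(n)
        assert abs(post_peak["delta"].mean() - peak) < tol

    def test_wear_budget(self):
        cfg = GeneratorConfig(
            n_study=0, n_control=1, days=120,
            wear_minutes_per_day_mean=400, wear_minutes_per_day_sd=60, seed=9,
        )
        p = make_patient("C01", cohort="control", injury=None)
        stream = simulate_patient_stream(p, cfg)
        per_day = np.bincount(stream.day[stream.bilateral_worn], minlength=cfg.days)
        assert abs(per_day.mean() - 400) / 400 < 0.05

    def test_null_sampler_matches_pipeline_distribution(self):
        """The fast null patient-stat sampler agrees with the stream pipeline."""
        cfg = GeneratorConfig(
            n_study=0, n_control=1, days=3,
            wear_minutes_per_day_mean=320, wear_minutes_per_day_sd=0,
            bilateral_noise_sd=1.2, patient_noise_cv=0.0, seed=2,
        )
        stats = []
        for i in range(40):
            p = make_patient(f"C{i:02d}", cohort="control", injury=None)
            diffs = minute_differentials(simulate_patient_stream(p, cfg))
            stats.append(diffs["abs_delta"].head(900 * 6).mean())
        rng = np.random.default_rng(0)
        ref = sample_null_patient_stats(4000, cfg, rng, n_minutes=900)
        # mean of |N(0, 2 sd^2)| = sd * sqrt(2) * sqrt(2/pi)
        expected = 1.2 * np.sqrt(2) * np.sqrt(2 / np.pi)
        assert abs(np.mean(stats) - expected) < 0.05
        assert abs(ref.mean() - expected) < 0.02


@pytest.fixture(scope="module")
def default_registry():
    registry, _ = generate_cohorts(GeneratorConfig(seed=4), simulate_streams=False)
    return registry


class TestCohorts:
    def test_default_sizes(self, default_registry):
        assert sum(p.cohort == "study" for p in default_registry) == 5
        assert sum(p.cohort == "control" for p in default_registry) == 26

    def test_control_diabetes_count(self, default_registry):
        controls = [p for p in default_registry if p.cohort == "control"]
        diabetic = [
            p for p in controls if p.diagnoses & {"diabetes_t1", "diabetes_t2"}
        ]
        assert len(diabetic) == 24

    def test_control_margins(self, default_registry):
        controls = [p for p in default_registry if p.cohort == "control"]
        assert sum(p.sex == "female" for p in controls) == 9
        assert sum("peripheral_artery_disease" in p.diagnoses for p in controls) == 5
        assert round(np.mean([p.age for p in controls]), 1) == 70.4

    def test_study_profiles(self, default_registry):
        study = [p for p in default_registry if p.cohort == "study"]
        assert [p.age for p in study] == [68, 75, 61, 48, 76]
        assert sum(p.sex == "female" for p in study) == 1
        assert all(p.injury is not None for p in study)
        types = [p.injury.injury_type for p in study]
        assert types == ["charcot", "blister", "osteomyelitis", "ulcer", "dvt"]

    def test_everyone_has_neuropathy(self, default_registry):
        assert all("neuropathy" in p.diagnoses for p in default_registry)

    def test_empty_study_cohort(self):
        registry, _ = generate_cohorts(
            GeneratorConfig(n_study=0, n_control=3, days=60, seed=1),
            simulate_streams=False,
        )
        assert all(p.cohort == "control" for p in registry)
        assert len(registry) == 3

    def test_registry_determinism(self):
        cfg = GeneratorConfig(seed=8)
        a, _ = generate_cohorts(cfg, simulate_streams=False)
        b, _ = generate_cohorts(cfg, simulate_streams=False)
        assert a == b

    def test_registry_roundtrip(self, default_registry, tmp_path):
        path = tmp_path / "registry.csv"
        write_registry(default_registry, path)
        assert read_registry(path) == default_registry

    def test_presets_recycled_beyond_five(self):
        registry, _ = generate_cohorts(
            GeneratorConfig(n_study=7, n_control=0, seed=2), simulate_streams=False
        )
        types = [p.injury.injury_type for p in registry]
        assert types[5] == types[0] and types[6] == types[1]


def test_default_presets_valid():
    presets = default_injury_presets()
    assert len(presets) == 5
    for spec in presets:
        assert spec.onset_day < spec.diagnosis_day
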