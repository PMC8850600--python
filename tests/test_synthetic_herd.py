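"""Generator behavior: composition convergence, signal structure, gaps,
scan sampling and the performance-generating linear model."""

import numpy as np
import pandas as pd
import pytest

import grazemetrics as gm
from grazemetrics.synthetic_herd import (
    SECONDS_PER_DAY,
    BehaviorTimeline,
    CircadianProfile,
    PerformanceGenConfig,
    ScheduleConfig,
    SignalConfig,
    StudyScenario,
    default_animals,
    sample_performance_design,
)


def constant_timeline(behavior="grazing", span_s=3600.0, animal_id="A01"):
    return BehaviorTimeline(
        animal_id=animal_id,
        start=pd.Timestamp("2020-01-01", tz="UTC"),
        bounds_s=np.array([0.0]),
        labels=np.array([behavior], dtype=object),
        span_s=span_s,
    )


class TestSchedule:
    def test_single_class_config_is_that_class_everywhere(self):
        config = ScheduleConfig(
            target_proportions={"grazing": 1.0},
            circadian={},
            animals=default_animals()[:2],
        )
        for timeline in gm.simulate_schedule(config, seed=0).values():
            assert set(timeline.labels) == {"grazing"}

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScheduleConfig(target_proportions={"grazing": 0.5, "eating": 0.4})

    def test_empirical_proportions_converge_to_targets(self):
        """22 animals x 10 days land within 2 points of the target shares."""
        config = ScheduleConfig(day_span=10)
        timelines = gm.simulate_schedule(config, seed=1)
        pooled = {b: 0.0 for b in gm.BEHAVIORS}
        for timeline in timelines.values():
            for b, frac in timeline.proportions().items():
                pooled[b] += frac / len(timelines)
        for b, target in config.target_proportions.items():
            assert pooled[b] == pytest.approx(target, abs=0.02)

    def test_gated_behavior_starts_only_inside_its_windows(self):
        config = ScheduleConfig(
            circadian={
                "eating": CircadianProfile(
                    baseline=0.0,
                    windows=(
                        ("10:00", "10:30", 5.0),
                        ("12:00", "12:30", 5.0),
                        ("16:00", "16:30", 5.0),
                    ),
                )
            },
            day_span=3,
            animals=default_animals()[:4],
        )
        windows = [(10 * 3600, 10.5 * 3600), (12 * 3600, 12.5 * 3600), (16 * 3600, 16.5 * 3600)]
        for timeline in gm.simulate_schedule(config, seed=3).values():
            starts = timeline.bounds_s[timeline.labels == "eating"] % SECONDS_PER_DAY
            for s in starts:
                assert any(lo <= s < hi for lo, hi in windows)


class TestSignal:
    def test_no_noise_no_oscillation_reproduces_the_mean_vector(self):
        cfg = SignalConfig(
            behaviors={"grazing": gm.BehaviorSignal((0.3, 0.2, 0.9), 0.0, 1.0, 0.0)}
        )
        rec = gm.simulate_signal(constant_timeline(), cfg, seed=0)
        assert np.allclose(rec[["x_g", "y_g", "z_g"]], [0.3, 0.2, 0.9])

    def test_one_hour_at_six_seconds_gives_600_records(self):
        rec = gm.simulate_signal(constant_timeline(span_s=3600.0), SignalConfig(), seed=0)
        assert len(rec) == 600

    def test_resting_has_the_lowest_mean_svm(self, small_bundle):
        records = small_bundle.records
        svm = np.sqrt(
            records.x_g**2 + records.y_g**2 + records.z_g**2
        ).groupby(small_bundle.true_record_labels()).mean()
        assert svm.idxmin() == "lying_standing"

    def test_resting_must_be_quieter_than_every_other_behavior(self):
        noisy_rest = dict(gm.SignalConfig().behaviors)
        noisy_rest["lying_standing"] = gm.BehaviorSignal((0.1, 0.1, 1.0), 0.5, 1.0, 0.5)
        with pytest.raises(ValueError, match="lying_standing"):
            SignalConfig(behaviors=noisy_rest)


class TestScanSampling:
    def test_default_window_yields_73_scans_per_animal_day(self):
        timelines = {"A01": constant_timeline(span_s=float(SECONDS_PER_DAY))}
        obs = gm.observe_scan_sampling(timelines)
        assert len(obs) == 73
        assert obs["behavior"].eq("grazing").all()

    def test_720_minute_interval_keeps_only_the_endpoints(self):
        timelines = {"A01": constant_timeline(span_s=float(SECONDS_PER_DAY))}
        obs = gm.observe_scan_sampling(timelines, scan_interval_min=720)
        assert list(obs["timestamp"].dt.strftime("%H:%M")) == ["06:00", "18:00"]

    def test_observations_match_the_timeline_at_scan_instants(self, small_bundle):
        for animal_id, group in small_bundle.observations.groupby("animal_id"):
            timeline = small_bundle.timelines[animal_id]
            offs = (group["timestamp"] - timeline.start).dt.total_seconds().to_numpy()
            assert (timeline.label_at(offs) == group["behavior"].to_numpy()).all()

    def test_window_beyond_span_raises(self):
        timelines = {"A01": constant_timeline(span_s=3600.0)}
        with pytest.raises(ValueError, match="span"):
            gm.observe_scan_sampling(timelines)


class TestGaps:
    def test_zero_rate_is_identity(self, small_bundle):
        out = gm.inject_gaps(small_bundle.records, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, small_bundle.records)

    def test_removed_fraction_tracks_the_rate(self):
        ts = pd.date_range("2020-01-01", periods=20000, freq="6s", tz="UTC")
        rec = pd.DataFrame(
            {
                "sensor_id": "S001",
                "animal_id": "A01",
                "timestamp": ts,
                "x_g": 0.1,
                "y_g": 0.1,
                "z_g": 0.9,
            }
        )
        out = gm.inject_gaps(rec, 0.5, burst_length_mean=5.0, seed=3)
        removed = 1.0 - len(out) / len(rec)
        assert removed == pytest.approx(0.5, abs=0.05)
        # ordering and content of survivors are untouched
        assert out["timestamp"].is_monotonic_increasing

    def test_rate_one_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            gm.inject_gaps(small_bundle.records, 1.0)


class TestPerformance:
    def test_intercept_only_model_is_constant(self):
        cfg = PerformanceGenConfig(
            intercept=1.0, coefficients={}, group_offsets={"nellore_dry": 0.0},
            noise_sd=0.0,
        )
        design = pd.DataFrame(
            {"genetic_group": ["nellore_dry"] * 3, "start_weight_kg": [300.0] * 3}
        )
        out = gm.simulate_performance(design, cfg, seed=0)
        assert (out["iadg_observed"] == 1.0).all()
        assert np.allclose(out["end_weight_kg"], 300.0 + 28.0)

    def test_noiseless_iadg_equals_the_hand_computed_linear_predictor(self):
        cfg = PerformanceGenConfig(noise_sd=0.0)
        row = {
            "intake_frequency": 20.0,
            "supplement_level": 2.0,
            "cp_pct": 16.5,
            "ndf_pct": 51.5,
            "adf_pct": 24.9,
            "forage_mass_kg_ha": 5020.0,
            "leaf_pct": 14.5,
            "stem_pct": 9.1,
            "day": 28.0,
            "genetic_group": "nellore_dry",
            "start_weight_kg": 343.0,
        }
        expected = cfg.intercept + sum(
            coef * row[name] for name, coef in cfg.coefficients.items()
        )
        out = gm.simulate_performance(pd.DataFrame([row]), cfg, seed=0)
        assert out["iadg_observed"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_missing_covariate_is_named(self):
        design = pd.DataFrame(
            {"genetic_group": ["nellore_dry"], "start_weight_kg": [300.0]}
        )
        with pytest.raises(ValueError, match="intake_frequency"):
            gm.simulate_performance(design, PerformanceGenConfig(), seed=0)

    def test_defaults_stay_inside_the_plausibility_band(self):
        design = sample_performance_design(300, seed=4)
        out = gm.simulate_performance(design, PerformanceGenConfig(), seed=5)
        assert out["iadg_observed"].between(0.0, 2.0).all()


class TestStudyBundle:
    def test_same_seed_reproduces_the_bundle_exactly(self):
        scenario = StudyScenario(
            schedule=ScheduleConfig(day_span=1, animals=default_animals()[:3]),
            dropout_rate=0.01,
        )
        a = gm.generate_study(scenario, seed=7)
        b = gm.generate_study(scenario, seed=7)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        pd.testing.assert_frame_equal(a.performance, b.performance)

    def test_default_study_monitors_22_animals(self, default_bundle):
        assert len(default_bundle.animals) == 22
        sizes = pd.Series([a.genetic_group for a in default_bundle.animals]).value_counts()
        assert sizes.to_dict() == {"nellore_dry": 10, "nellore_wet": 5, "crossbred_wet": 7}

    def test_dry_season_covariates_match_the_printed_values(self, default_bundle):
        from grazemetrics.synthetic_herd import SEASON_COVARIATES

        dry = SEASON_COVARIATES["dry"]
        assert dry["cp_pct"] == 16.5
        assert dry["ndf_pct"] == 51.5
        assert dry["adf_pct"] == 24.9
        assert dry["forage_mass_kg_ha"] == 5020.0
        covs = default_bundle.covariates.query("season == 'dry'")
        assert covs["cp_pct"].mean() == pytest.approx(16.5, rel=0.06)

    def test_record_timestamps_strictly_increase_per_animal(self, small_bundle):
        for _, group in small_bundle.records.groupby("animal_id"):
            assert group["timestamp"].is_monotonic_increasing
            assert not group["timestamp"].duplicated().any()
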