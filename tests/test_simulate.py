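import dataclasses
import math

import numpy as np
import pytest

from gazemetrics import (
    BehaviorProfile,
    CohortSpec,
    classify_events,
    compute_metrics,
    default_profiles,
    generate_cohort,
    generate_stream,
    pixels_to_degrees,
    profile_expectations,
)


class TestDefaultProfiles:
    def test_profiles_encode_the_calibration_targets(self):
        female, male = default_profiles()
        ef = profile_expectations(female)
        em = profile_expectations(male)
        assert ef["mean_fixation_ms"] == pytest.approx(197.6)
        assert em["mean_fixation_ms"] == pytest.approx(226.0)
        assert ef["saccades_per_min"] == pytest.approx(347.0)
        assert em["saccades_per_min"] == pytest.approx(288.0)
        assert ef["mean_saccade_ms"] == pytest.approx(63.1)
        assert em["mean_saccade_ms"] == pytest.approx(56.4)
        assert ef["saccade_px_per_min"] == pytest.approx(35_026.0)
        assert em["saccade_px_per_min"] == pytest.approx(33_542.0)
        assert ef["screen_time_fraction"] == pytest.approx(0.447)
        assert em["screen_time_fraction"] == pytest.approx(0.551)

    def test_scan_budget_identity(self):
        # per cycle, saccade + microfixation time must equal the scan-time
        # budget implied by the profile's own (realized) Gaze Index
        for prof in default_profiles():
            e = profile_expectations(prof)
            scan_frac = 1.0 / (1.0 + e["gaze_index"])
            assert prof.scan_bout_fraction == pytest.approx(scan_frac, rel=1e-12)

    def test_saccade_speed_exceeds_threshold(self):
        for prof in default_profiles():
            assert prof.saccade_speed_deg_s > 30.0

    def test_profile_invariants_enforced(self):
        female, _ = default_profiles()
        with pytest.raises(ValueError):
            dataclasses.replace(female, fixation_ms_mean=50.0)
        with pytest.raises(ValueError):
            dataclasses.replace(female, microfix_ms_mean=80.0)
        with pytest.raises(ValueError):
            dataclasses.replace(female, saccade_speed_deg_s=20.0)
        with pytest.raises(ValueError):
            dataclasses.replace(female, onscreen_fraction=1.5)


class TestGenerateStream:
    def test_fixed_seed_is_bit_identical(self):
        female, _ = default_profiles()
        a = generate_stream(female, seed=123)
        b = generate_stream(female, seed=123)
        assert np.array_equal(a.t_ms, b.t_ms)
        assert np.array_equal(a.x_px, b.x_px, equal_nan=True)
        assert np.array_equal(a.y_px, b.y_px, equal_nan=True)
        assert np.array_equal(a.valid, b.valid)

    def test_ten_minute_stream_has_about_18000_samples(self):
        female, _ = default_profiles()
        s = generate_stream(female, seed=0)
        assert len(s) == 18_000
        assert s.t_ms[-1] == pytest.approx(17_999 * 1000.0 / 30.0)

    def test_near_zero_scan_profile_is_almost_all_fixation(self):
        female, _ = default_profiles()
        # enormous stare bouts with the minimum one relocating saccade per
        # cycle starve the scan chains
        prof = dataclasses.replace(
            female,
            fixation_ms_mean=50_000.0,
            saccade_rate_per_min=1.0,
            scan_bout_fraction=1e-3,
            onscreen_fraction=0.95,
        )
        s = generate_stream(prof, seed=4)
        seq = classify_events(s)
        dur = seq.durations_ms
        on = dur[seq.kinds != 3].sum()
        fix = dur[seq.kinds == 0].sum()
        assert fix / on >= 0.99

    def test_saccade_intervals_exceed_threshold_and_stare_jitter_never_does(self):
        # construction check on >= 1e4 intervals of one default stream
        female, _ = default_profiles()
        s = generate_stream(female, seed=11)
        assert len(s) - 1 >= 10_000
        t, x, y, v = s.t_ms, s.x_px, s.y_px, s.valid
        both = v[:-1] & v[1:]
        disp = np.hypot(np.where(both, np.diff(x), 0), np.where(both, np.diff(y), 0))
        vel = pixels_to_degrees(disp, s.geometry) / (np.diff(t) / 1000.0)
        sep = np.sort(vel[both])
        # velocities are cleanly separated around the 30 deg/s threshold:
        # no generated interval falls in the ambiguous band
        assert not ((sep > 10.0) & (sep < 33.0)).any()

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            BehaviorProfile(
                label="bad", fixation_ms_mean=40.0, saccade_ms_mean=60.0,
                saccade_rate_per_min=300.0, scan_bout_fraction=0.4,
                onscreen_fraction=0.5,
            )


class TestGenerateCohort:
    def test_default_spec_yields_93_matched_streams(self):
        streams, records = generate_cohort(CohortSpec(seed=0, task_duration_ms=60_000.0))
        assert len(streams) == 93 and len(records) == 93
        assert sum(r.sex_label == "female" for r in records) == 46
        assert sum(r.sex_label == "male" for r in records) == 47
        assert {s.participant_id for s in streams} == {r.participant_id for r in records}
        assert all(r.performance_pct is not None for r in records)

    def test_zero_cv_gives_identical_expected_profiles(self):
        spec = CohortSpec(n_female=3, n_male=3, between_participant_cv=0.0,
                          task_duration_ms=120_000.0, seed=1)
        streams, _ = generate_cohort(spec)
        # same-sex participants share generative parameters; their realized
        # metrics differ only through sampling noise
        ms = [compute_metrics(classify_events(s), s) for s in streams[:3]]
        fix = [m.mean_fixation_ms for m in ms]
        assert np.std(fix) < 15.0  # sampling noise only, not the 22% cv spread

    def test_swapping_profiles_swaps_every_mean_difference(self):
        female, male = default_profiles()
        base = CohortSpec(n_female=10, n_male=10, task_duration_ms=120_000.0, seed=5)
        swapped = dataclasses.replace(base, profiles=(male, female))

        def group_means(spec):
            streams, records = generate_cohort(spec)
            sex = {r.participant_id: r.sex_label for r in records}
            out = {"female": [], "male": []}
            for s in streams:
                out[sex[s.participant_id]].append(
                    compute_metrics(classify_events(s), s)
                )
            return out

        g1 = group_means(base)
        g2 = group_means(swapped)
        for name in ("mean_fixation_ms", "saccades_per_min", "screen_time_fraction"):
            d1 = np.mean([getattr(m, name) for m in g1["female"]]) - np.mean(
                [getattr(m, name) for m in g1["male"]]
            )
            d2 = np.mean([getattr(m, name) for m in g2["female"]]) - np.mean(
                [getattr(m, name) for m in g2["male"]]
            )
            assert np.sign(d1) == -np.sign(d2)

    def test_cohort_seed_reproducibility(self):
        a, _ = generate_cohort(CohortSpec(n_female=2, n_male=2, seed=9,
                                          task_duration_ms=60_000.0))
        b, _ = generate_cohort(CohortSpec(n_female=2, n_male=2, seed=9,
                                          task_duration_ms=60_000.0))
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.x_px, s2.x_px, equal_nan=True)


class TestCalibration:
    def test_cohort_means_match_analytic_expectations(self, default_cohort_frame):
        # end-to-end recovery at 2 SEM for each profile's analytic expectation
        for sex in ("female", "male"):
            exp = profile_expectations(default_profiles()[sex == "male"])
            grp = default_cohort_frame[default_cohort_frame["sex"] == sex]
            for name in ("mean_fixation_ms", "mean_saccade_ms", "saccades_per_min",
                         "saccade_px_per_min", "screen_time_fraction"):
                mean = grp[name].mean()
                sem = grp[name].std(ddof=1) / math.sqrt(len(grp))
                assert abs(mean - exp[name]) <= 2.0 * sem + 0.01 * exp[name], (
                    f"{sex} {name}: {mean:.4g} vs expected {exp[name]:.4g}"
                )

    def test_between_participant_cv_reproduces_fixation_sems(self, default_cohort_frame):
        # the dispersion knob is calibrated to the fixation-duration group
        # SEMs (7.2 ms female, 6.6 ms male at n=46/47); tolerance 30%
        targets = {"female": 7.2, "male": 6.6}
        for sex, target in targets.items():
            grp = default_cohort_frame[default_cohort_frame["sex"] == sex]
            sems = grp.groupby("seed")["mean_fixation_ms"].apply(
                lambda v: v.std(ddof=1) / math.sqrt(len(v))
            )
            assert abs(sems.mean() - target) / target <= 0.30
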