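import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazemetrics import (
    ClassificationError,
    ClassifierParams,
    EventSequence,
    GazeEvent,
    GazeSample,
    angular_velocity,
    classify_events,
    degrees_to_pixels,
    pixels_to_degrees,
)
from conftest import make_stream, random_stream
from reference import oracle_classify


class TestVisualAngle:
    def test_zero_displacement_is_zero_degrees(self, geometry):
        assert pixels_to_degrees(0.0, geometry) == 0.0

    def test_one_degree_worked_example(self, geometry):
        # a displacement whose physical size is 1.1349 cm at 65 cm subtends
        # 2*atan(1.1349/130) = 1.0003 degrees
        px = 1.1349 / geometry.pitch_cm
        assert pixels_to_degrees(px, geometry) == pytest.approx(1.0003, abs=5e-4)

    def test_small_angle_regime_is_nearly_linear(self, geometry):
        px = degrees_to_pixels(2.0, geometry)
        ratio = pixels_to_degrees(2 * px, geometry) / pixels_to_degrees(px, geometry)
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_inverse_round_trip(self, geometry):
        for deg in (0.1, 1.0, 5.0, 20.0):
            assert pixels_to_degrees(degrees_to_pixels(deg, geometry), geometry) == \
                pytest.approx(deg, rel=1e-12)

    def test_negative_displacement_rejected(self, geometry):
        with pytest.raises(ValueError):
            pixels_to_degrees(-1.0, geometry)

    @given(st.floats(0.0, 2000.0), st.floats(0.0, 2000.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_displacement(self, a, b):
        from gazemetrics import EXAMPLE_GEOMETRY
        lo, hi = sorted((a, b))
        assert pixels_to_degrees(lo, EXAMPLE_GEOMETRY) <= pixels_to_degrees(hi, EXAMPLE_GEOMETRY)


class TestAngularVelocity:
    def test_stationary_gaze_has_zero_velocity(self, geometry):
        v = angular_velocity(GazeSample(0, 100, 100), GazeSample(33, 100, 100), geometry)
        assert v == 0.0

    def test_one_degree_in_a_thirtieth_of_a_second_is_30_deg_s(self, geometry):
        px = degrees_to_pixels(1.0, geometry)
        v = angular_velocity(GazeSample(0, 100, 100), GazeSample(100 / 3, 100 + px, 100), geometry)
        assert v == pytest.approx(30.0, rel=1e-9)

    def test_one_degree_in_100ms_is_10_deg_s(self, geometry):
        px = degrees_to_pixels(1.0, geometry)
        v = angular_velocity(GazeSample(0, 100, 100), GazeSample(100, 100, 100 + px), geometry)
        assert v == pytest.approx(10.0, rel=1e-9)

    def test_rejects_bad_intervals(self, geometry):
        with pytest.raises(ValueError):
            angular_velocity(GazeSample(33, 1, 1), GazeSample(0, 1, 1), geometry)
        with pytest.raises(ValueError):
            angular_velocity(GazeSample(0, 1, 1, valid=False), GazeSample(33, 1, 1), geometry)


def _constant(t0, n, xy, dt=100 / 3):
    return [(t0 + i * dt, xy[0], xy[1]) for i in range(n)]


class TestClassifyEvents:
    def test_constant_position_yields_one_fixation(self, geometry):
        s = make_stream(_constant(0.0, 7, (400, 300)))  # 6 intervals = 200 ms
        ev = classify_events(s).events
        assert len(ev) == 1
        e = ev[0]
        assert e.kind == "fixation"
        assert e.duration_ms == pytest.approx(200.0)
        assert e.centroid_x_px == pytest.approx(400) and e.centroid_y_px == pytest.approx(300)

    def test_micro_saccade_micro_pattern(self, geometry):
        # 40 ms dwell, one supra-threshold jump, 40 ms dwell
        dt = 20.0
        pts = [(0, 100, 100), (20, 100, 100), (40, 100, 100),
               (60, 600, 600),
               (80, 600, 600), (100, 600, 600)]
        kinds = [e.kind for e in classify_events(make_stream(pts)).events]
        assert kinds == ["microfixation", "saccade", "microfixation"]

    def test_offscreen_gap_splits_fixation_runs(self, geometry):
        # 10-sample stream with a 3-sample invalid block in the middle:
        # the flanking sub-threshold runs are evaluated independently
        pts = (_constant(0.0, 4, (200, 200))
               + [(400 / 3 + i * 100 / 3, np.nan, np.nan, False) for i in range(3)]
               + _constant(700 / 3, 3, (210, 205)))
        ev = classify_events(make_stream(pts)).events
        assert [e.kind for e in ev] == ["fixation", "offscreen", "fixation"]
        # oracle agreement on the same stream
        ora = oracle_classify(make_stream(pts))
        assert [e["kind"] for e in ora] == ["fixation", "offscreen", "fixation"]

    def test_interval_exactly_at_threshold_is_not_a_saccade(self, geometry):
        # the rule is "exceeding": an interval exactly AT the threshold stays
        # non-saccadic; pin the threshold to the interval's computed velocity
        # so the equality is exact in floating point
        px = degrees_to_pixels(1.0, geometry)
        a, b = GazeSample(0, 100, 100), GazeSample(100 / 3, 100 + px, 100)
        v = angular_velocity(a, b, geometry)
        pts = [(0, 100, 100), (100 / 3, 100 + px, 100), (200 / 3, 100 + px, 100),
               (100, 100 + px, 100)]
        params = ClassifierParams(velocity_threshold_deg_s=v)
        ev = classify_events(make_stream(pts), params).events
        assert all(e.kind != "saccade" for e in ev)

    def test_sub_threshold_run_of_exactly_60ms_is_a_microfixation(self, geometry):
        pts = [(0, 100, 100), (30, 100, 100), (60, 100, 100), (61, 700, 700)]
        ev = classify_events(make_stream(pts)).events
        assert ev[0].kind == "microfixation" and ev[0].duration_ms == 60.0

    def test_all_invalid_stream_is_one_offscreen_event(self, geometry):
        pts = [(i * 100 / 3, np.nan, np.nan, False) for i in range(5)]
        ev = classify_events(make_stream(pts)).events
        assert len(ev) == 1 and ev[0].kind == "offscreen"

    def test_fewer_than_two_samples_rejected(self, geometry):
        with pytest.raises(ClassificationError):
            classify_events(make_stream([(0, 100, 100)]))

    def test_saccade_path_at_least_straight_line_displacement(self, geometry):
        rng = np.random.default_rng(5)
        s = random_stream(rng, n=150)
        seq = classify_events(s)
        for i in np.flatnonzero(seq.kinds == 2):
            a = np.searchsorted(s.t_ms, seq.start_ms[i])
            b = np.searchsorted(s.t_ms, seq.end_ms[i])
            chord = math.hypot(s.x_px[b] - s.x_px[a], s.y_px[b] - s.y_px[a])
            assert seq.path_length_px[i] >= chord - 1e-9


class TestClassifierInvariants:
    def test_time_conservation(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            s = random_stream(rng)
            seq = classify_events(s)
            assert seq.durations_ms.sum() == pytest.approx(
                s.t_ms[-1] - s.t_ms[0], rel=1e-12
            )
            assert seq.start_ms[0] == s.t_ms[0] and seq.end_ms[-1] == s.t_ms[-1]

    def test_determinism_bit_for_bit(self):
        s = random_stream(np.random.default_rng(3), n=180)
        a = classify_events(s)
        b = classify_events(s)
        assert np.array_equal(a.kinds, b.kinds)
        assert np.array_equal(a.start_ms, b.start_ms)
        assert np.array_equal(a.path_length_px, b.path_length_px, equal_nan=True)

    def test_raising_threshold_never_decreases_stationary_time(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = random_stream(rng, p_invalid=0.05)
            sub_time = {}
            for thr in (20.0, 30.0, 60.0):
                seq = classify_events(s, ClassifierParams(velocity_threshold_deg_s=thr))
                mask = (seq.kinds == 0) | (seq.kinds == 1)
                sub_time[thr] = seq.durations_ms[mask].sum()
            assert sub_time[20.0] <= sub_time[30.0] + 1e-9 <= sub_time[60.0] + 2e-9

    def test_no_adjacent_events_of_equal_kind(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            seq = classify_events(random_stream(rng))
            assert (np.diff(seq.kinds) != 0).all()

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            s = random_stream(rng)
            seq = classify_events(s)
            ora = oracle_classify(s)
            assert [e["kind"] for e in ora] == [
                ("fixation", "microfixation", "saccade", "offscreen")[k] for k in seq.kinds
            ]
            assert np.allclose([e["start"] for e in ora], seq.start_ms)
            assert np.allclose([e["end"] for e in ora], seq.end_ms)


class TestEventSequenceContainer:
    def test_rejects_non_contiguous_events(self):
        with pytest.raises(ValueError):
            EventSequence.from_events("p", [
                GazeEvent("fixation", 0, 100, 1, 1),
                GazeEvent("saccade", 150, 200, path_length_px=50),
            ])

    def test_rejects_adjacent_equal_kinds(self):
        with pytest.raises(ValueError):
            EventSequence.from_events("p", [
                GazeEvent("saccade", 0, 50, path_length_px=10),
                GazeEvent("saccade", 50, 100, path_length_px=10),
            ])

    def test_event_table_export_columns(self):
        s = make_stream(_constant(0.0, 7, (400, 300)))
        df = classify_events(s).to_frame()
        assert list(df.columns) == [
            "participant_id", "kind", "start_ms", "end_ms", "duration_ms",
            "centroid_x_px", "centroid_y_px", "path_length_px",
        ]
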