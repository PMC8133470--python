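"""Event detection: geometry, velocity, saccade/fixation/pursuit segmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gazexpert.events import (
    assemble_fixations,
    deg_to_px,
    detect_gaps,
    detect_saccades,
    dispersion,
    px_to_deg,
    sample_velocity,
    segment_trial,
    split_smooth_pursuits,
)
from gazexpert.simulate import (
    ClassProfile,
    MeasureSpec,
    SimConfig,
    default_class_profiles,
    generate_trial,
)

from .conftest import make_trial


class TestPxToDeg:
    @pytest.mark.parametrize(
        "dx, dy, expected",
        [
            ((2400, 0), None, (225.0, 0.0)),
            ((0, 1000), None, (0.0, 187.5)),
            ((0, 0), None, (0.0, 0.0)),
        ],
    )
    def test_worked_figures(self, dx, dy, expected):
        ax, ay = px_to_deg(dx[0], dx[1])
        assert (float(ax), float(ay)) == expected

    @given(st.integers(-5000, 5000), st.integers(-5000, 5000))
    def test_roundtrip_integer_pixels(self, dx, dy):
        ax, ay = px_to_deg(dx, dy)
        rx, ry = deg_to_px(ax, ay)
        assert abs(float(rx) - dx) < 1e-9 and abs(float(ry) - dy) < 1e-9

    def test_linearity(self):
        a1 = px_to_deg(100, 50)
        a2 = px_to_deg(300, 150)
        assert np.allclose(np.asarray(a2), 3 * np.asarray(a1))

    def test_wrap_folds_across_seam(self):
        ax, _ = px_to_deg(3800, 0, wrap_x=True)
        assert float(ax) == pytest.approx(-40 * 360 / 3840)

    def test_bad_frame_rejected(self):
        with pytest.raises(ValueError):
            px_to_deg(1, 1, frame=(0, 1920))


class TestSampleVelocity:
    def test_stationary_trace_is_zero(self):
        tr = make_trial(np.full(50, 500.0), np.full(50, 400.0))
        assert np.all(sample_velocity(tr) == 0.0)

    def test_device_error_jump_speed(self):
        # 2400 px in one 4 ms step: 225 deg / 0.004 s
        tr = make_trial([1000.0, 3400.0], [500.0, 500.0])
        assert sample_velocity(tr)[0] == pytest.approx(56250.0)

    @given(st.integers(1, 12), st.integers(5, 60))
    def test_uniform_drift_matches_brute_force(self, k, n):
        x = 100.0 + k * np.arange(n)
        y = np.full(n, 300.0)
        tr = make_trial(x, y)
        speeds = sample_velocity(tr)
        # independent two-point oracle
        expect = [
            np.hypot((x[i + 1] - x[i]) * 360 / 3840, 0.0) / 0.004
            for i in range(n - 1)
        ]
        assert np.allclose(speeds, expect)
        assert np.allclose(speeds, speeds[0])

    def test_invalid_pairs_flagged_not_numeric(self):
        valid = [True, False, True, True]
        tr = make_trial([0, 0, 8, 9.0], [0, 0, 8, 9.0], valid=valid)
        speeds = sample_velocity(tr)
        assert np.isnan(speeds[0]) and np.isnan(speeds[1]) and np.isfinite(speeds[2])

    def test_single_sample_rejected(self):
        tr = make_trial([1.0], [1.0])
        with pytest.raises(ValueError):
            sample_velocity(tr)


class TestDetectSaccades:
    def test_all_subthreshold(self):
        assert detect_saccades(np.full(100, 25.0)) == []

    def test_single_supra_run_boundaries(self):
        speeds = np.full(60, 10.0)
        speeds[20:29] = 300.0
        assert detect_saccades(speeds) == [(20, 28)]

    def test_two_jumps_separated_by_hold(self):
        speeds = np.full(200, 10.0)
        speeds[10:16] = 200.0
        speeds[100:107] = 200.0  # 84-pair (336 ms) hold between
        assert detect_saccades(speeds) == [(10, 15), (100, 106)]

    def test_single_sample_flicker_merged(self):
        speeds = np.full(40, 10.0)
        speeds[10:14] = 100.0
        speeds[14] = 30.0
        speeds[15:19] = 100.0
        assert detect_saccades(speeds) == [(10, 18)]

    def test_short_runs_discarded(self):
        speeds = np.full(30, 10.0)
        speeds[5:7] = 500.0
        assert detect_saccades(speeds, min_samples=3) == []

    def test_bridges_short_invalid_runs(self):
        speeds = np.full(60, 10.0)
        speeds[10:15] = 200.0
        speeds[15:20] = np.nan
        speeds[20:25] = 200.0
        assert detect_saccades(speeds) == [(10, 24)]

    def test_does_not_bridge_blink_length_gaps(self):
        speeds = np.full(120, 10.0)
        speeds[10:15] = 200.0
        speeds[15:45] = np.nan  # 30 pairs: blink-scale
        speeds[45:50] = 200.0
        assert detect_saccades(speeds) == [(10, 14), (45, 49)]


class TestDispersion:
    def test_identical_points(self):
        assert dispersion([5, 5, 5], [7, 7, 7]) == 0.0

    def test_bounding_box_sum(self):
        assert dispersion([0, 30, 0], [0, 0, 40]) == 70.0

    @given(
        st.lists(st.tuples(st.integers(0, 100), st.integers(0, 100)), min_size=2, max_size=20)
    )
    def test_interior_point_never_changes_value(self, pts):
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        d0 = dispersion(xs, ys)
        # any point inside the bounding box leaves the extrema untouched
        xi = (min(xs) + max(xs)) / 2
        yi = (min(ys) + max(ys)) / 2
        assert dispersion(xs + [xi], ys + [yi]) == d0

    def test_no_valid_samples_rejected(self):
        with pytest.raises(ValueError):
            dispersion([1.0], [1.0], valid=[False])


class TestFixationAssembly:
    def test_no_saccades_one_fixation(self):
        kept, discarded = assemble_fixations(500, [], [], dt_ms=4.0)
        assert kept == [(0, 499)] and discarded == []

    def test_forty_ms_interval_rejected(self):
        # 10-pair (40 ms) gap between two saccades
        kept, discarded = assemble_fixations(40, [(0, 9), (20, 29)], [], dt_ms=4.0)
        assert (10, 19) in discarded
        assert all(run != (10, 19) for run in kept)

    def test_constructed_200ms_hold(self):
        # 50 pairs at 4 ms = 200 ms between two jumps
        kept, _ = assemble_fixations(120, [(0, 9), (60, 69)], [], dt_ms=4.0)
        assert (10, 59) in kept


class TestPursuitSplit:
    def test_boundary_values(self):
        lo = make_fix(99.9)
        hi = make_fix(100.1)
        fix, pursuits = split_smooth_pursuits([lo, hi])
        assert [f.dispersion_px for f in fix] == [99.9]
        assert [p.dispersion_px for p in pursuits] == [100.1]

    def test_empty_input(self):
        assert split_smooth_pursuits([]) == ([], [])


def make_fix(disp):
    from gazexpert.events import Fixation

    return Fixation(0.0, 100.0, 100.0, (0.0, 0.0), disp, 0, 25)


class TestGaps:
    def test_fully_valid_no_gaps(self):
        tr = make_trial(np.zeros(100) + 5, np.zeros(100) + 5)
        assert detect_gaps(tr) == []

    def test_150ms_invalid_run_is_gap(self):
        valid = np.ones(200, dtype=bool)
        valid[50:88] = False  # 38 samples = 152 ms
        tr = make_trial(np.full(200, 5.0), np.full(200, 5.0), valid=valid)
        assert detect_gaps(tr) == [(50, 87)]

    def test_8ms_invalid_run_not_a_gap(self):
        valid = np.ones(100, dtype=bool)
        valid[50:52] = False
        tr = make_trial(np.full(100, 5.0), np.full(100, 5.0), valid=valid)
        assert detect_gaps(tr) == []


def _programmed_trace():
    """Six holds separated by five large jumps, all hand-positioned."""
    rng = np.random.default_rng(0)
    xs, ys = [], []
    x = 1000.0
    for hold in range(6):
        n = 60  # 240 ms
        xs.append(x + rng.normal(0, 1.0, n).cumsum() * 0.05)
        ys.append(np.full(n, 900.0) + rng.normal(0, 0.3, n))
        if hold < 5:
            jump = np.linspace(0, 200, 8)[1:]  # ~18.8 deg in 28 ms
            xs.append(x + jump)
            ys.append(np.full(7, 900.0))
            x += 200.0
    return np.concatenate(xs), np.concatenate(ys)


class TestSegmentTrial:
    def test_programmed_counts_recovered(self):
        x, y = _programmed_trace()
        stream = segment_trial(make_trial(x, y))
        assert len(stream.saccades) == 5
        assert len(stream.fixations) + len(stream.pursuits) == 6

    def test_pure_drift_single_pursuit(self):
        n = 400
        x = 1000 + np.linspace(0, 180, n)  # 180 px over 1.6 s: slow drift
        stream = segment_trial(make_trial(x, np.full(n, 900.0)))
        assert len(stream.pursuits) == 1
        assert len(stream.saccades) == 0 and len(stream.fixations) == 0

    def test_partition_tiles_the_timeline(self):
        profiles = default_class_profiles()
        cfg = SimConfig(trial_duration_s=6.0, dropout_rate=0.01, spike_rate=0.001,
                        low_track_fraction=0.0)
        for seed in range(5):
            tr = generate_trial(profiles["novice"], cfg, np.random.default_rng(seed))
            stream = segment_trial(tr)
            assert stream.span_accounting() == pytest.approx(tr.duration_ms)
            events = stream.all_events()
            for a, b in zip(events, events[1:]):
                assert a.end_ms <= b.start_ms + 1e-9

    def test_emitted_event_invariants(self):
        profiles = default_class_profiles()
        cfg = SimConfig(trial_duration_s=8.0, dropout_rate=0.01, spike_rate=0.0005,
                        low_track_fraction=0.0)
        tr = generate_trial(profiles["expert"], cfg, np.random.default_rng(11))
        stream = segment_trial(tr)
        assert stream.fixations and stream.saccades
        for f in stream.fixations:
            assert f.duration_ms >= 50.0
            assert f.dispersion_px <= 100.0
        for p in stream.pursuits:
            assert p.dispersion_px > 100.0
        for s in stream.saccades:
            assert s.duration_ms > 0
            assert s.peak_velocity >= s.mean_velocity


class TestRecovery:
    def test_well_separated_events_recovered(self):
        """Event counts recovered in >= 99% of randomized trials."""
        measures = dict(default_class_profiles()["novice"].measures)
        measures["saccade_amplitude_deg"] = MeasureSpec(12.0, 5.0, 5.0, 30.0)
        measures["fixation_duration_ms"] = MeasureSpec(260.0, 60.0, 120.0, 500.0)
        measures["fixation_dispersion_px"] = MeasureSpec(45.0, 15.0, 10.0, 80.0)
        profile = ClassProfile("novice", measures, pursuit_fraction=0.2)
        cfg = SimConfig(trial_duration_s=3.0, dropout_rate=0.0, spike_rate=0.0,
                        low_track_fraction=0.0)
        failures = 0
        n_trials = 1000
        for seed in range(n_trials):
            tr = generate_trial(profile, cfg, np.random.default_rng(seed))
            stream = segment_trial(tr)
            want_sacc = sum(
                1 for e in tr.truth if e["kind"] == "saccade" and not e.get("truncated")
            )
            want_holds = sum(
                1 for e in tr.truth
                if e["kind"] in ("fixation", "pursuit") and e["n_pairs"] * 4.0 >= 50.0
            )
            got_holds = len(stream.fixations) + len(stream.pursuits)
            if len(stream.saccades) != want_sacc or got_holds != want_holds:
                failures += 1
        assert failures <= 0.01 * n_trials
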