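import numpy as np
import pytest

from gazeperim.geometry import StimulusLocation
from gazeperim.scheduler import StimulusEvent
from gazeperim.gaze import (
    BLINK_GAP,
    NO_MOVEMENT,
    SACCADE_TOWARD,
    GazeTrace,
    ResponseRecord,
    classify_response,
    classify_schedule,
    detect_saccades,
    response_accuracy_vs_duration,
    tally_errors,
)

RATE = 60.0
H35 = StimulusLocation("horizontal", 35.0, 129)


def step_trace(step_at, target_az, duration=3.0, target_el=0.0, valid=None):
    t = np.arange(0.0, duration, 1.0 / RATE)
    az = np.where(t >= step_at, target_az, 0.0)
    el = np.where(t >= step_at, target_el, 0.0)
    return GazeTrace(t, az, el, valid, rate=RATE)


def stim(event_id=0, angle=35.0, onset=1.0, duration=0.2, attenuation=0.0):
    loc = StimulusLocation("horizontal", angle, 129)
    return StimulusEvent(event_id, loc, "red", 700.0, attenuation, onset, duration)


class TestDetectSaccades:
    def test_constant_trace_has_none(self):
        t = np.arange(0, 2, 1 / RATE)
        tr = GazeTrace(t, np.full_like(t, 3.0), np.zeros_like(t), rate=RATE)
        assert detect_saccades(tr) == []

    def test_single_step_yields_one_saccade_with_full_amplitude(self):
        tr = step_trace(1.25, 35.0)
        sacs = detect_saccades(tr)
        assert len(sacs) == 1
        assert sacs[0].amplitude == pytest.approx(35.0, abs=0.1)
        assert sacs[0].t_start == pytest.approx(1.25, abs=2.5 / RATE)
        assert sacs[0].peak_velocity >= 30.0

    def test_two_separated_steps_yield_two_saccades(self):
        t = np.arange(0, 4, 1 / RATE)
        az = np.zeros_like(t)
        az[t >= 1.0] = 20.0
        az[t >= 2.5] = -15.0
        tr = GazeTrace(t, az, np.zeros_like(t), rate=RATE)
        assert len(detect_saccades(tr)) == 2

    def test_sub_amplitude_step_ignored(self):
        tr = step_trace(1.0, 1.0)  # 1 deg < 2 deg minimum
        assert detect_saccades(tr) == []

    def test_all_invalid_trace_rejected(self):
        t = np.arange(0, 1, 1 / RATE)
        tr = GazeTrace(t, np.zeros_like(t), np.zeros_like(t),
                       np.zeros_like(t, dtype=bool), rate=RATE)
        with pytest.raises(ValueError):
            detect_saccades(tr)


class TestClassifyResponse:
    def test_saccade_toward_stimulus_is_seen(self):
        tr = step_trace(1.25, 35.0)
        rec = classify_response(stim(onset=1.0), detect_saccades(tr), tr)
        assert rec.seen and rec.verdict_basis == SACCADE_TOWARD
        assert rec.latency == pytest.approx(0.25, abs=2.5 / RATE)
        assert rec.landing_error == pytest.approx(0.0, abs=1e-9)

    def test_flat_trace_is_not_seen(self):
        t = np.arange(0, 3, 1 / RATE)
        tr = GazeTrace(t, np.zeros_like(t), np.zeros_like(t), rate=RATE)
        rec = classify_response(stim(onset=1.0), [], tr)
        assert not rec.seen and rec.verdict_basis == NO_MOVEMENT

    def test_wrong_direction_saccade_is_not_seen(self):
        tr = step_trace(1.25, -35.0)
        rec = classify_response(stim(onset=1.0), detect_saccades(tr), tr)
        assert not rec.seen

    def test_landing_outside_tolerance_is_not_seen(self):
        tr = step_trace(1.25, 25.0)  # 10 deg short of the 35 deg target
        rec = classify_response(stim(onset=1.0), detect_saccades(tr), tr, tolerance=5.0)
        assert not rec.seen

    def test_saccade_outside_window_is_not_seen(self):
        tr = step_trace(2.8, 35.0)  # 1.8 s after onset > 1.5 s window end
        rec = classify_response(stim(onset=1.0), detect_saccades(tr), tr)
        assert not rec.seen

    def test_blink_gap_flags_event_for_repeat(self):
        t = np.arange(0, 3, 1 / RATE)
        valid = np.ones_like(t, dtype=bool)
        valid[(t >= 1.1) & (t <= 2.0)] = False  # covers most of the window
        tr = GazeTrace(t, np.zeros_like(t), np.zeros_like(t), valid, rate=RATE)
        rec = classify_response(stim(onset=1.0), [], tr)
        assert rec.verdict_basis == BLINK_GAP and rec.needs_repeat and not rec.seen

    def test_verdict_invariant_to_blinks_outside_window(self):
        tr_clean = step_trace(1.25, 35.0)
        valid = np.ones(len(tr_clean), dtype=bool)
        valid[(tr_clean.t >= 2.7) & (tr_clean.t <= 2.9)] = False
        tr_blink = GazeTrace(tr_clean.t, tr_clean.azimuth, tr_clean.elevation,
                             valid, rate=RATE)
        for tr in (tr_clean, tr_blink):
            rec = classify_response(stim(onset=1.0), detect_saccades(tr), tr)
            assert rec.seen and rec.latency == pytest.approx(0.25, abs=2.5 / RATE)

    def test_seen_latency_always_inside_window(self):
        for onset in (0.5, 1.0, 1.3):
            tr = step_trace(onset + 0.3, 35.0, duration=4.0)
            rec = classify_response(stim(onset=onset), detect_saccades(tr), tr)
            if rec.seen:
                assert 0.15 <= rec.latency <= 1.5

    def test_verdicts_depend_on_times_not_event_order(self):
        t = np.arange(0, 8, 1 / RATE)
        az = np.zeros_like(t)
        az[(t >= 1.25) & (t < 1.7)] = 35.0
        az[(t >= 4.3) & (t < 4.8)] = -20.0
        tr = GazeTrace(t, az, np.zeros_like(t), rate=RATE)
        ev1 = stim(event_id=0, angle=35.0, onset=1.0)
        loc2 = StimulusLocation("horizontal", -20.0, 75)
        ev2 = StimulusEvent(1, loc2, "red", 700.0, 0.0, 4.0, 0.2)
        fwd = classify_schedule([ev1, ev2], tr)
        rev = classify_schedule([ev2, ev1], tr)
        assert {r.event_id: r.seen for r in fwd} == {r.event_id: r.seen for r in rev}
        assert all(r.seen for r in fwd)


class TestTallyErrors:
    def test_perfect_responder_no_catch_trials(self):
        sched = [stim(event_id=i, onset=1.0 + 3 * i) for i in range(3)]
        recs = [
            ResponseRecord(i, True, latency=0.25, landing_angle=35.0,
                           landing_error=0.0, verdict_basis=SACCADE_TOWARD)
            for i in range(3)
        ]
        assert tally_errors(recs, sched) == (0, 0)

    def test_phantom_misses_every_suprathreshold_stimulus(self):
        sched = [stim(event_id=i, onset=1.0 + 3 * i) for i in range(5)]
        recs = [ResponseRecord(i, False, verdict_basis=NO_MOVEMENT) for i in range(5)]
        assert tally_errors(recs, sched) == (0, 5)

    def test_dim_stimulus_miss_is_not_a_false_negative(self):
        sched = [stim(event_id=0, onset=1.0, attenuation=10.0)]
        recs = [ResponseRecord(0, False, verdict_basis=NO_MOVEMENT)]
        assert tally_errors(recs, sched) == (0, 0)

    def test_stray_saccade_in_silent_gap_counts_once(self):
        # excursion away and back: only the fixation-departing sweep counts
        t = np.arange(0, 10, 1 / RATE)
        az = np.zeros_like(t)
        az[(t >= 5.0) & (t < 5.4)] = 25.0
        tr = GazeTrace(t, az, np.zeros_like(t), rate=RATE)
        sacs = detect_saccades(tr)
        assert len(sacs) == 2
        sched = [stim(event_id=0, onset=1.0)]
        recs = [ResponseRecord(0, False, verdict_basis=NO_MOVEMENT)]
        fp, fn = tally_errors(recs, sched, saccades=sacs)
        assert fp == 1 and fn == 1

    def test_record_for_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            tally_errors([ResponseRecord(9, False)], [stim(event_id=0)])


class TestAccuracyVsDuration:
    def _sched_recs(self, groups):
        sched, recs, eid = [], [], 0
        for duration, errors in groups.items():
            for err in errors:
                sched.append(stim(event_id=eid, onset=1.0 + 3 * eid, duration=duration))
                recs.append(
                    ResponseRecord(eid, True, latency=0.25, landing_angle=35.0 + err,
                                   landing_error=err, verdict_basis=SACCADE_TOWARD)
                )
                eid += 1
        return sched, recs

    def test_two_point_line(self):
        sched, recs = self._sched_recs({0.1: [2.0], 0.3: [1.0]})
        slope, intercept = response_accuracy_vs_duration(recs, sched)
        assert slope == pytest.approx(-5.0)
        assert intercept == pytest.approx(2.5)

    def test_identical_groups_give_zero_slope(self):
        sched, recs = self._sched_recs({0.1: [1.5, 1.5], 0.3: [1.5, 1.5]})
        slope, _ = response_accuracy_vs_duration(recs, sched)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        sched, recs = self._sched_recs({0.2: [1.0, 2.0]})
        with pytest.raises(ValueError):
            response_accuracy_vs_duration(recs, sched)


def test_trace_csv_round_trip(tmp_path):
    tr = step_trace(1.25, 35.0)
    path = tmp_path / "trace.csv"
    tr.to_csv(path)
    back = GazeTrace.from_csv(path)
    assert np.allclose(back.t, tr.t)
    assert np.allclose(back.azimuth, tr.azimuth)
    assert np.array_equal(back.valid, tr.valid)


def test_trace_validation():
    with pytest.raises(ValueError):
        GazeTrace([0.0, 0.0], [0, 0], [0, 0], rate=RATE)  # non-increasing t
    with pytest.raises(ValueError):
        GazeTrace([0.0, 0.1], [0, np.nan], [0, 0], rate=RATE)  # invalid angle
    with pytest.raises(ValueError):
        GazeTrace([0.0, 0.1], [0, 0], [0, 0], rate=-1.0)
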