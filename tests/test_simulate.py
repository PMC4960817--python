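import numpy as np
import pytest
from scipy import stats

from gazeperim.geometry import StimulusLocation
from gazeperim.scheduler import Protocol, StimulusEvent, generate_schedule
from gazeperim.gaze import detect_saccades, tally_errors
from gazeperim.mapping import DB_CEILING, compare_maps, run_exam
from gazeperim.simulate import (
    GroundTruthDefect,
    PatientModel,
    RenderConfig,
    generate_trace,
    make_defect_map,
    make_responder,
    render_frame,
    respond,
)

H35 = StimulusLocation("horizontal", 35.0, 129)


def stim(attenuation=0.0, angle=35.0, onset=1.0, event_id=0, duration=0.2):
    loc = StimulusLocation("horizontal", angle, 129)
    return StimulusEvent(event_id, loc, "red", 700.0, attenuation, onset, duration)


class TestRespond:
    def _prob(self, pm, ev, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        return np.mean([respond(pm, ev, rng) for _ in range(n)])

    def test_far_above_threshold_always_seen(self):
        pm = PatientModel.uniform(25.0, lapse_rate=0.0)
        assert self._prob(pm, stim(attenuation=0.0), n=500) == 1.0

    def test_far_below_threshold_never_seen(self):
        pm = PatientModel(true_map=make_defect_map(0.0, []), lapse_rate=0.0)
        assert self._prob(pm, stim(attenuation=10.0), n=500) == 0.0

    def test_at_threshold_probability_is_half(self):
        pm = PatientModel.uniform(10.0, lapse_rate=0.0)
        p = self._prob(pm, stim(attenuation=10.0))
        assert p == pytest.approx(0.5, abs=0.03)

    def test_lapse_rate_caps_asymptote(self):
        pm = PatientModel.uniform(25.0, lapse_rate=0.2)
        p = self._prob(pm, stim(attenuation=0.0))
        assert p == pytest.approx(0.8, abs=0.03)

    def test_catch_trials_never_seen_through_perception(self):
        pm = PatientModel.uniform(25.0)
        catch = StimulusEvent(0, None, "red", 0.0, 0.0, 1.0, 0.2)
        rng = np.random.default_rng(0)
        assert not any(respond(pm, catch, rng) for _ in range(100))

    def test_unknown_location_rejected(self):
        pm = PatientModel.uniform(25.0)
        bad = StimulusEvent(0, StimulusLocation("horizontal", 200.0, 0), "red",
                            700.0, 0.0, 1.0, 0.2)
        with pytest.raises(KeyError):
            respond(pm, bad, np.random.default_rng(0))


class TestGenerateTrace:
    def test_static_eye_stays_at_fixation(self):
        pm = PatientModel.static(seed=1)
        tr = generate_trace(pm, [stim()], responses={0: False})
        assert np.all(tr.azimuth == 0.0) and np.all(tr.elevation == 0.0)
        assert tr.valid.all()

    def test_noiseless_seen_stimulus_reaches_target_exactly(self):
        pm = PatientModel.static(seed=2)
        tr = generate_trace(pm, [stim(angle=35.0)], responses={0: True})
        assert tr.azimuth.max() == pytest.approx(35.0)
        # out and back: a single contiguous excursion
        at_target = np.flatnonzero(tr.azimuth == 35.0)
        assert np.array_equal(at_target, np.arange(at_target[0], at_target[-1] + 1))

    def test_habitual_saccade_count_is_poisson(self):
        pm = PatientModel.static(habit_rate=0.05, seed=3)
        tr = generate_trace(pm, [], duration=1000.0)
        sacs = detect_saccades(tr)
        # out + back per excursion
        n_excursions = len(sacs) / 2
        assert abs(n_excursions - 50) <= 3 * np.sqrt(50)

    def test_blinks_appear_as_invalid_runs(self):
        pm = PatientModel.static(blink_rate=0.5, blink_duration=0.15, seed=4)
        tr = generate_trace(pm, [], duration=60.0)
        assert (~tr.valid).sum() > 0
        assert tr.valid.sum() > 0

    def test_seed_determinism(self):
        sched = generate_schedule(Protocol(mode="fast", seed=5))
        pm = PatientModel.uniform(25.0, habit_rate=0.02, blink_rate=0.1, seed=5)
        a = generate_trace(pm, sched)
        b = generate_trace(pm, sched)
        assert a.to_csv() == b.to_csv()

    def test_empty_schedule_needs_duration(self):
        with pytest.raises(ValueError):
            generate_trace(PatientModel.static(), [])

    def test_landing_noise_shrinks_with_duration(self):
        pm = PatientModel.uniform(25.0)
        assert pm.landing_sd(0.1) == pytest.approx(2.0)
        assert pm.landing_sd(0.3) == pytest.approx(1.0)
        assert pm.landing_sd(10.0) == 0.1  # floored


class TestResponderAccuracyDuration:
    def test_longer_stimuli_are_localized_better(self):
        # simulated patient, durations 100 vs 300 ms: negative OLS slope
        from gazeperim.gaze import response_accuracy_vs_duration

        pm = PatientModel.uniform(25.0, seed=6)
        responder = make_responder(pm)
        sched, recs = [], []
        eid = 0
        for duration in (0.1, 0.3):
            for _ in range(200):
                ev = stim(event_id=eid, onset=1.0 + 3 * eid, duration=duration)
                sched.append(ev)
                recs.append(responder(ev))
                eid += 1
        slope, _ = response_accuracy_vs_duration(recs, sched)
        assert slope < 0

class TestRenderFrame:
    def test_centred_gaze_puts_pupil_at_reference(self):
        cfg = RenderConfig(head_texture_sd=0.0)
        from gazeperim.frames import detect_eye

        f = render_frame((0.0, 0.0), cfg)
        (row, col), _ = detect_eye(f)
        assert row == pytest.approx(cfg.ref_row, abs=0.2)
        assert col == pytest.approx(cfg.ref_col, abs=0.2)

    def test_pupil_displaces_linearly_with_gain(self):
        cfg = RenderConfig(gain_px_per_deg=2.0, head_texture_sd=0.0)
        from gazeperim.frames import detect_eye

        f = render_frame((10.0, 0.0), cfg)
        (row, col), _ = detect_eye(f)
        assert col == pytest.approx(cfg.ref_col + 20.0, abs=0.2)
        assert row == pytest.approx(cfg.ref_row, abs=0.2)

    def test_gaze_outside_range_rejected(self):
        with pytest.raises(ValueError):
            render_frame((200.0, 0.0), RenderConfig())


class TestDefectMap:
    def test_uniform_base(self):
        m = make_defect_map(25.0, [])
        assert len(m.thresholds) == 325
        assert set(m.thresholds.values()) == {25.0}

    def test_defect_interval_covers_expected_locations(self):
        m = make_defect_map(
            25.0, [GroundTruthDefect("horizontal", (-40.0, -20.0), 20.0)]
        )
        low = [k for k, v in m.thresholds.items() if v == 5.0]
        assert len(low) == 21
        assert all(arm == "horizontal" and -40 <= ang <= -20 for arm, ang in low)
        assert sum(1 for v in m.thresholds.values() if v == 25.0) == 325 - 21

    def test_depth_clips_at_zero(self):
        m = make_defect_map(25.0, [GroundTruthDefect("vertical", (-30.0, -10.0), 30.0)])
        assert m.thresholds[("vertical", -20.0)] == 0.0

    def test_out_of_range_defect_rejected(self):
        with pytest.raises(ValueError):
            make_defect_map(25.0, [GroundTruthDefect("vertical", (-80.0, -70.0), 5.0)])


def test_full_pipeline_noiseless_patient_reproduces_own_map():
    # deterministic responder through the exam: every estimate within the
    # staircase quantization of its true value
    from gazeperim.simulate import deterministic_responder

    ref = make_defect_map(25.0, [GroundTruthDefect("horizontal", (-40.0, -20.0), 12.0)])
    m = run_exam(Protocol(mode="accurate", seed=9), deterministic_responder(ref))
    for key, est in m.determined().items():
        true = ref.thresholds[key]
        assert abs(est - true) <= 2.0
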