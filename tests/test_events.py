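"""Event detection: parameter recovery, false-positive and edge behaviour."""
import numpy as np
import pytest

from stepramp.config import AnalysisConfig
from stepramp.events import (
    SaccadeEvent,
    compute_ex,
    detect_pursuit_onset,
    detect_saccades,
    detect_tap,
)
from stepramp.preprocessing import KinematicTrace, Recording, compute_kinematics
from stepramp.synthetic import (
    GazeSimParams,
    HandSimParams,
    SaccadePlan,
    simulate_gaze,
    simulate_hand,
)
from stepramp.trial_design import (
    CROSSING_TIMES,
    DIRECTIONS,
    VELOCITIES,
    TrialDesign,
)


def recover_saccades(design, plan, n, seed=0, config=AnalysisConfig()):
    rng = np.random.default_rng(seed)
    events = []
    for _ in range(n):
        rec, _ = simulate_gaze(design, GazeSimParams(saccade=plan), rng)
        kt = compute_kinematics(rec, config=config)
        events.append(detect_saccades(kt, design, config=config))
    return events


class TestDetectSaccades:
    @pytest.mark.parametrize(
        "amplitude,duration,expected_class",
        [(1.5, 0.04, "forward"), (-1.2, 0.037, "backward"), (2.0, 0.045, "forward")],
    )
    def test_injected_saccade_recovered(self, amplitude, duration, expected_class):
        design = TrialDesign(
            velocity=15.0, tx=0.1 if amplitude > 0 else 0.24, direction=1, duration=0.65
        )
        plan = SaccadePlan(onset=0.30, amplitude=amplitude, duration=duration)
        all_events = recover_saccades(design, plan, n=30)
        assert all(len(ev) == 1 for ev in all_events)
        onsets = np.array([ev[0].onset for ev in all_events])
        amps = np.array([ev[0].amplitude for ev in all_events])
        assert np.mean(np.abs(onsets - plan.onset)) < 0.006
        assert np.mean(np.abs(amps - amplitude)) < 0.1
        assert all(ev[0].direction_class == expected_class for ev in all_events)

    def test_no_false_positives_on_clean_pursuit_grid(self):
        """Noise-free pure pursuit never trips the thresholds anywhere in
        the factorial design."""
        params = GazeSimParams(pursuit_gain=1.0, fixation_noise_sd=0.0)
        for v in VELOCITIES:
            for tx in CROSSING_TIMES:
                for direction in DIRECTIONS:
                    d = TrialDesign(velocity=v, tx=tx, direction=direction, duration=0.7)
                    rec, _ = simulate_gaze(d, params, seed=0)
                    kt = compute_kinematics(rec)
                    assert detect_saccades(kt, d) == []

    def test_time_translation_invariance(self, design):
        plan = SaccadePlan(onset=0.30, amplitude=1.5, duration=0.04)
        rec, _ = simulate_gaze(design, GazeSimParams(saccade=plan), seed=7)
        kt = compute_kinematics(rec)
        base = detect_saccades(kt, design)
        shift = 0.05
        shifted_design = TrialDesign(
            velocity=design.velocity, tx=design.tx,
            direction=design.direction, duration=design.duration,
        )
        rec2 = Recording(
            times=rec.times + shift, pos=rec.pos, rate=rec.rate, missing=rec.missing
        )
        kt2 = compute_kinematics(rec2)
        # the saccade sits at 0.35 now; the epoch window still contains it
        moved = detect_saccades(kt2, shifted_design)
        assert len(base) == len(moved) == 1
        assert moved[0].onset - base[0].onset == pytest.approx(shift, abs=1e-9)


class TestDetectPursuitOnset:
    def test_latency_recovered(self, design):
        rng = np.random.default_rng(3)
        errors = []
        for _ in range(100):
            rec, _ = simulate_gaze(design, GazeSimParams(pursuit_latency=0.14), rng)
            onset = detect_pursuit_onset(compute_kinematics(rec), design)
            assert onset is not None
            errors.append(onset.latency - 0.14)
        assert np.mean(np.abs(errors)) < 0.02

    def test_no_onset_when_eye_never_moves(self, design):
        # pursuit latency beyond the recording: the eye just fixates
        rec, _ = simulate_gaze(design, GazeSimParams(pursuit_latency=5.0), seed=0)
        assert detect_pursuit_onset(compute_kinematics(rec), design) is None

    def test_anticipatory_latency_detected_early(self, design, config):
        rec, _ = simulate_gaze(design, GazeSimParams(pursuit_latency=0.04), seed=0)
        onset = detect_pursuit_onset(compute_kinematics(rec), design)
        assert onset is not None
        assert onset.latency < config.min_pursuit_latency_s


class TestComputeEx:
    def _trace(self, pos_err, slip, design):
        # constant-velocity trace engineered to hit the requested position
        # error and retinal slip at the evaluation point (0.2 s)
        rate = 500.0
        times = np.arange(-0.65, 0.65, 1 / rate)
        gaze_vel = design.signed_velocity + slip
        t_eval = 0.2
        target_at = design.step + design.signed_velocity * t_eval
        pos = (times - t_eval) * gaze_vel + target_at + pos_err
        return KinematicTrace(
            times=times, pos=pos, vel=np.full_like(times, gaze_vel),
            acc=np.zeros_like(times), rate=rate,
            vel_interp=np.full_like(times, gaze_vel),
        )

    def test_ratio_examples(self, design):
        sac = SaccadeEvent(onset=0.3, offset=0.34, amplitude=1.0,
                           direction_class="forward", latency=0.3)
        assert compute_ex(sac, self._trace(-1.0, 5.0, design), design) == pytest.approx(-0.2, abs=1e-6)
        assert compute_ex(sac, self._trace(0.0, 3.0, design), design) == pytest.approx(0.0, abs=1e-6)

    def test_small_slip_undefined(self, design):
        sac = SaccadeEvent(onset=0.3, offset=0.34, amplitude=1.0,
                           direction_class="forward", latency=0.3)
        assert compute_ex(sac, self._trace(-1.0, 0.1, design), design) is None

    def test_pre_onset_evaluation_point_required(self, design):
        sac = SaccadeEvent(onset=0.05, offset=0.09, amplitude=1.0,
                           direction_class="forward", latency=0.05)
        assert compute_ex(sac, self._trace(-1.0, 5.0, design), design) is None


class TestDetectTap:
    def test_tap_time_recovered(self, interception_design):
        rng = np.random.default_rng(5)
        errors = []
        for _ in range(50):
            rec, truth = simulate_hand(interception_design, HandSimParams(), rng)
            tap = detect_tap(compute_kinematics(rec), "online")
            assert tap is not None
            errors.append(tap.time - truth.tap_time)
        assert np.mean(np.abs(errors)) < 0.008

    def test_gentle_contact_found_only_offline(self, interception_design):
        rec, truth = simulate_hand(
            interception_design, HandSimParams(contact_decel=30.0), seed=4
        )
        kt = compute_kinematics(rec)
        assert detect_tap(kt, "online") is None
        offline = detect_tap(kt, "offline")
        assert offline is not None
        assert offline.time == pytest.approx(truth.tap_time, abs=0.03)

    def test_no_tap_when_finger_stays_high(self, interception_design):
        rec, truth = simulate_hand(
            interception_design, HandSimParams(reaction_time=0.45, movement_time=0.45),
            seed=0,
        )
        kt = compute_kinematics(rec)
        assert truth.tap_time is None
        assert detect_tap(kt, "online") is None
        assert detect_tap(kt, "offline") is None

    def test_threshold_monotonicity(self, interception_design, config):
        """Lowering the deceleration threshold never loses a detected tap."""
        rng = np.random.default_rng(9)
        for decel in (110.0, 60.0, 35.0):
            rec, _ = simulate_hand(
                interception_design, HandSimParams(contact_decel=decel), rng
            )
            kt = compute_kinematics(rec)
            found = False
            for thr in (120.0, 80.0, 50.0, 25.0, 10.0):
                tap = detect_tap(kt, "online", config.replace(tap_decel_online=thr))
                if found:
                    assert tap is not None
                found = found or tap is not None

    def test_time_translation_invariance(self, interception_design):
        rec, _ = simulate_hand(interception_design, HandSimParams(), seed=11)
        kt = compute_kinematics(rec)
        base = detect_tap(kt, "online")
        rec2 = Recording(times=rec.times + 0.2, pos=rec.pos, rate=rec.rate,
                         source="hand", missing=rec.missing)
        moved = detect_tap(compute_kinematics(rec2), "online")
        assert moved.time - base.time == pytest.approx(0.2, abs=1e-9)

    def test_requires_three_columns(self, design):
        rec, _ = simulate_gaze(design, GazeSimParams(), seed=0)
        with pytest.raises(ValueError):
            detect_tap(compute_kinematics(rec), "online")
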