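"""Per-trial measures, classification and exclusion rules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepramp.config import AnalysisConfig
from stepramp.events import SaccadeEvent
from stepramp.measures import (
    TrialResult,
    analyze_trial,
    apply_exclusions,
    classify_trial,
    exclusion_counts,
    interception_error,
    pre_tap_mean,
    predicted_endpoint_error,
    results_to_frame,
)
from stepramp.preprocessing import KinematicTrace
from stepramp.events import PursuitOnset
from stepramp.synthetic import (
    BlinkPlan,
    GazeSimParams,
    HandSimParams,
    SaccadePlan,
    simulate_gaze,
    simulate_hand,
)
from stepramp.trial_design import TrialDesign


def _saccade(direction_class, onset=0.3):
    return SaccadeEvent(onset=onset, offset=onset + 0.04, amplitude=1.0,
                        direction_class=direction_class, latency=onset)


class TestClassifyTrial:
    def test_classes(self):
        assert classify_trial([]) == "pure_pursuit"
        assert classify_trial([_saccade("forward")]) == "forward"
        assert classify_trial([_saccade("backward")]) == "backward"
        assert classify_trial([_saccade("backward")] * 2) == "backward"
        assert classify_trial([_saccade("forward"), _saccade("backward")]) == "mixed"


class TestInterceptionError:
    @pytest.mark.parametrize(
        "tap,target,direction,expected",
        [(5.5, 5.0, 1, 0.5), (-5.5, -5.0, -1, 0.5), (5.0, 5.0, 1, 0.0),
         (4.2, 5.0, 1, -0.8)],
    )
    def test_examples(self, tap, target, direction, expected):
        assert interception_error(tap, target, direction) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None)
    @given(
        tap=st.floats(-10, 10), target=st.floats(-10, 10),
        direction=st.sampled_from([-1, 1]),
    )
    def test_mirror_invariance(self, tap, target, direction):
        assert interception_error(tap, target, direction) == pytest.approx(
            interception_error(-tap, -target, -direction), abs=1e-9
        )


def _kin(vel_fn, rate=500.0, t0=-0.65, t1=0.65):
    times = np.arange(t0, t1, 1 / rate)
    vel = vel_fn(times)
    return KinematicTrace(
        times=times, pos=np.cumsum(vel) / rate, vel=vel,
        acc=np.zeros_like(times), rate=rate,
    )


class TestPreTapMean:
    def test_constant_and_ramp(self, config):
        trace = _kin(lambda t: np.full_like(t, 20.0))
        val, trunc = pre_tap_mean(trace, trace.vel, 0.48, config)
        assert val == pytest.approx(20.0) and not trunc
        ramp = _kin(lambda t: 10.0 + 30.0 * t)
        val, _ = pre_tap_mean(ramp, ramp.vel, 0.48, config)
        # mean of a linear signal over the window = value at its midpoint
        assert val == pytest.approx(10.0 + 30.0 * 0.38, abs=0.05)

    def test_equals_bruteforce_average(self, config, rng):
        noise = rng.normal(0, 5, 650)
        trace = _kin(lambda t: np.zeros_like(t))
        trace = KinematicTrace(times=trace.times, pos=trace.pos, vel=noise,
                               acc=trace.acc, rate=trace.rate)
        val, _ = pre_tap_mean(trace, trace.vel, 0.48, config)
        sel = (trace.times >= 0.36) & (trace.times <= 0.40)
        assert val == pytest.approx(noise[sel].mean(), abs=1e-12)

    def test_truncated_window_flagged(self, config):
        trace = _kin(lambda t: np.full_like(t, 1.0), t0=0.40, t1=0.65)
        val, trunc = pre_tap_mean(trace, trace.vel, 0.48, config)
        assert trunc


class TestPredictedEndpointError:
    @pytest.mark.parametrize(
        "gaze_vel,target_vel,expected",
        [(15.0, 15.0, 0.0), (17.0, 15.0, 0.2), (10.0, 15.0, -0.5)],
    )
    def test_examples(self, gaze_vel, target_vel, expected, config):
        assert predicted_endpoint_error(gaze_vel, target_vel, config) == pytest.approx(expected)


class TestApplyExclusions:
    def _result(self, design, **kw):
        base = dict(trial_id="t0", participant=0, task=design.task,
                    velocity=design.velocity, tx=design.tx,
                    direction=design.direction, duration=design.duration)
        base.update(kw)
        return TrialResult(**base)

    def _tracking_trace(self, design):
        # eye follows the target exactly: no post-saccadic position error
        return _kin(lambda t: np.where(t >= 0, design.signed_velocity, 0.0))

    def _tracking_trace_offset(self, design, offset):
        trace = self._tracking_trace(design)
        # shift so that pos(t) = target(t) + offset during motion
        i0 = trace.index_of(0.0)
        shift = design.step + offset - trace.pos[i0]
        return KinematicTrace(times=trace.times, pos=trace.pos + shift,
                              vel=trace.vel, acc=trace.acc, rate=trace.rate)

    def test_anticipatory_pursuit_excluded(self, design, config):
        res = apply_exclusions(
            self._result(design), PursuitOnset(0.04, 1.0), [],
            self._tracking_trace(design), design, blink=False, config=config,
        )
        assert res.excluded and res.exclusion_reason == "anticipatory_pursuit"

    def test_missing_pursuit_onset_excluded(self, design, config):
        res = apply_exclusions(
            self._result(design), None, [], self._tracking_trace(design),
            design, blink=False, config=config,
        )
        assert res.exclusion_reason == "no_pursuit_onset"

    def test_post_saccade_error_excluded(self, design, config):
        trace = self._tracking_trace_offset(design, offset=6.0)
        res = apply_exclusions(
            self._result(design), PursuitOnset(0.14, 1.0), [_saccade("forward")],
            trace, design, blink=False, config=config,
        )
        assert res.exclusion_reason == "post_saccade_error"
        ok = apply_exclusions(
            self._result(design), PursuitOnset(0.14, 1.0), [_saccade("forward")],
            self._tracking_trace_offset(design, offset=1.0),
            design, blink=False, config=config,
        )
        assert not ok.excluded

    def test_interception_rules(self, interception_design, config):
        d = interception_design
        no_tap = apply_exclusions(
            self._result(d), PursuitOnset(0.14, 1.0), [],
            self._tracking_trace(d), d, blink=False, config=config,
        )
        assert no_tap.exclusion_reason == "no_tap"
        far = apply_exclusions(
            self._result(d, tap_time=0.48, interception_error=3.5, error_y=0.0),
            PursuitOnset(0.14, 1.0), [], self._tracking_trace(d), d,
            blink=False, config=config,
        )
        assert far.exclusion_reason == "tap_far"

    def test_multiple_reasons_all_recorded(self, interception_design, config):
        d = interception_design
        res = apply_exclusions(
            self._result(d), PursuitOnset(0.02, 1.0), [],
            self._tracking_trace(d), d, blink=True, config=config,
        )
        assert set(res.exclusion_reason.split(";")) == {
            "anticipatory_pursuit", "blink", "no_tap",
        }

    def test_clean_trial_retained(self, design, config):
        res = apply_exclusions(
            self._result(design), PursuitOnset(0.14, 1.0), [],
            self._tracking_trace(design), design, blink=False, config=config,
        )
        assert not res.excluded and res.exclusion_reason == ""


class TestAnalyzeTrial:
    def test_clean_interception_trial(self, interception_design):
        d = interception_design
        gaze, _ = simulate_gaze(d, GazeSimParams(
            saccade=SaccadePlan(onset=0.30, amplitude=1.5, duration=0.04)), seed=2)
        hand, truth = simulate_hand(d, HandSimParams(velocity_bias=1.1), seed=2)
        res = analyze_trial("t1", d, gaze, hand, participant=3)
        assert not res.excluded
        assert res.oculomotor_class == "forward"
        assert res.tap_mode == "online"
        assert res.interception_error == pytest.approx(0.15, abs=0.25)
        assert res.time_to_tap == pytest.approx(truth.tap_time, abs=0.01)
        assert res.gaze_vel_pre_tap is not None
        assert res.predicted_endpoint_error == pytest.approx(
            (res.gaze_vel_pre_tap - d.velocity) * 0.1
        )

    def test_blink_trial_excluded(self, design):
        gaze, _ = simulate_gaze(
            design, GazeSimParams(blink=BlinkPlan(onset=0.3, duration=0.06)), seed=1
        )
        res = analyze_trial("t2", design, gaze, judgment="fast")
        assert res.excluded and "blink" in res.exclusion_reason

    def test_results_frame_and_counts(self, design):
        gaze, _ = simulate_gaze(design, GazeSimParams(), seed=0)
        res = [analyze_trial(f"t{i}", design, gaze) for i in range(3)]
        res[0].excluded, res[0].exclusion_reason = True, "blink"
        frame = results_to_frame(res)
        counts = exclusion_counts(frame)
        assert counts["total"] == 3
        assert counts["blink"] == 1
        assert counts["retained"] == 2
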