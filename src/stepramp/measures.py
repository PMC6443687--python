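"""Per-trial derived measures, oculomotor classification and exclusions.

The interception error is the signed horizontal distance between the tap
and the target centre at the moment of the tap, normalised by motion
direction so that tapping ahead of the target is positive irrespective of
whether it moved left or right.  Pre-tap estimates (hand velocity, gaze
velocity, gaze position error) are means over the 120-80 ms window before
the tap, the standard estimate of the value 100 ms before the tap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .events import (
    PursuitOnset,
    SaccadeEvent,
    TapEvent,
    compute_ex,
    detect_pursuit_onset,
    detect_saccades,
    detect_tap,
)
from .preprocessing import (
    KinematicTrace,
    Recording,
    compute_kinematics,
    saccade_interpolated_velocity,
)
from .trial_design import TrialDesign, target_position

#: Controlled vocabulary of exclusion reasons.
EXCLUSION_REASONS = (
    "no_pursuit_onset",
    "anticipatory_pursuit",
    "blink",
    "post_saccade_error",
    "no_tap",
    "tap_far",
)

OCULOMOTOR_CLASSES = ("pure_pursuit", "forward", "backward", "mixed")


@dataclass
class TrialResult:
    """Everything the statistics stage needs about one trial."""

    trial_id: str
    participant: int
    task: str
    velocity: float
    tx: float
    direction: int
    duration: float
    oculomotor_class: str = "pure_pursuit"
    pursuit_latency: Optional[float] = None
    n_saccades: int = 0
    saccade_onset: Optional[float] = None
    saccade_offset: Optional[float] = None
    saccade_amplitude: Optional[float] = None
    saccade_ex: Optional[float] = None
    tap_time: Optional[float] = None
    tap_x: Optional[float] = None
    tap_y: Optional[float] = None
    tap_mode: Optional[str] = None
    interception_error: Optional[float] = None   # cm, ahead positive
    error_y: Optional[float] = None              # cm, vertical tap error
    time_to_tap: Optional[float] = None          # s from target onset
    hand_vel_pre_tap: Optional[float] = None     # cm/s
    gaze_vel_pre_tap: Optional[float] = None     # cm/s, direction-aligned
    gaze_pos_error_pre_tap: Optional[float] = None  # cm, direction-aligned
    predicted_endpoint_error: Optional[float] = None  # cm
    judgment: Optional[str] = None               # "fast" | "slow"
    excluded: bool = False
    exclusion_reason: str = ""


def classify_trial(saccades: Sequence[SaccadeEvent]) -> str:
    """Oculomotor class from the trial's detected saccades.

    Trials with saccades of both direction classes are 'mixed' and are left
    out of the saccade-vs-pursuit contrasts downstream.
    """
    classes = {s.direction_class for s in saccades}
    if not classes:
        return "pure_pursuit"
    if classes == {"forward"}:
        return "forward"
    if classes == {"backward"}:
        return "backward"
    return "mixed"


def interception_error(
    tap_x: float, target_x: float, direction: int
) -> float:
    """Signed horizontal tap error, positive = ahead of the target."""
    return direction * (tap_x - target_x)


def pre_tap_mean(
    trace: KinematicTrace,
    channel: np.ndarray,
    tap_time: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[Optional[float], bool]:
    """Mean of ``channel`` over the pre-tap window; (value, truncated)."""
    near, far = config.pre_tap_window_s
    lo, hi = tap_time - far, tap_time - near
    sel = (trace.times >= lo) & (trace.times <= hi)
    truncated = trace.times[0] > lo or trace.times[-1] < hi
    if not sel.any():
        return None, True
    vals = channel[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return None, True
    return float(vals.mean()), truncated


def predicted_endpoint_error(
    gaze_vel_pre_tap: float,
    target_velocity: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> float:
    """Endpoint error expected from pursuit error alone.

    (eye velocity - target velocity) x the 0.1 s extrapolation span, both
    direction-aligned; the prediction an interceptor relying purely on the
    current eye velocity would make.
    """
    return (gaze_vel_pre_tap - target_velocity) * config.extrapolation_span_s


def apply_exclusions(
    result: TrialResult,
    pursuit: Optional[PursuitOnset],
    saccades: Sequence[SaccadeEvent],
    gaze: KinematicTrace,
    design: TrialDesign,
    blink: bool,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> TrialResult:
    """Set the exclusion flag and reason set on a trial result.

    Rules (order-independent; all violated rules are recorded):
    no/anticipatory pursuit onset, blink during target presentation,
    post-saccadic gaze position error above 5 cm, and for interception
    trials a missing tap or a tap further than 3 cm from the target.
    """
    reasons = set()
    if pursuit is None:
        reasons.add("no_pursuit_onset")
    elif pursuit.latency < config.min_pursuit_latency_s:
        reasons.add("anticipatory_pursuit")
    if blink:
        reasons.add("blink")
    for s in saccades:
        t_eval = min(s.offset + config.post_saccade_eval_delay_s, design.duration)
        err = gaze.sample(gaze.pos, t_eval) - target_position(design, t_eval)
        if abs(err) > config.post_saccade_error_max_cm:
            reasons.add("post_saccade_error")
    if design.task == "interception":
        if result.tap_time is None:
            reasons.add("no_tap")
        elif result.interception_error is not None:
            dist = np.hypot(
                result.interception_error, result.error_y or 0.0
            )
            if dist > config.tap_distance_max_cm:
                reasons.add("tap_far")
    result.excluded = bool(reasons)
    result.exclusion_reason = ";".join(sorted(reasons))
    return result


def analyze_trial(
    trial_id: str,
    design: TrialDesign,
    gaze_rec: Recording,
    hand_rec: Optional[Recording] = None,
    judgment: Optional[str] = None,
    participant: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> TrialResult:
    """Full per-trial analysis: events, derived measures, exclusions."""
    gaze = compute_kinematics(gaze_rec, config=config, drift_target=0.0)
    saccades = detect_saccades(gaze, design, config=config)
    pursuit = detect_pursuit_onset(gaze, design, config=config)
    gaze.vel_interp = saccade_interpolated_velocity(
        gaze, [(s.onset, s.offset) for s in saccades], config=config
    )
    for s in saccades:
        s.ex = compute_ex(s, gaze, design, config=config)

    result = TrialResult(
        trial_id=trial_id,
        participant=participant,
        task=design.task,
        velocity=design.velocity,
        tx=design.tx,
        direction=design.direction,
        duration=design.duration,
        oculomotor_class=classify_trial(saccades),
        pursuit_latency=None if pursuit is None else pursuit.latency,
        n_saccades=len(saccades),
        judgment=judgment,
    )
    if saccades:
        first = saccades[0]
        result.saccade_onset = first.onset
        result.saccade_offset = first.offset
        result.saccade_amplitude = first.amplitude
        result.saccade_ex = first.ex

    tap: Optional[TapEvent] = None
    hand: Optional[KinematicTrace] = None
    if design.task == "interception" and hand_rec is not None:
        hand = compute_kinematics(hand_rec, config=config)
        tap = detect_tap(hand, "online", config=config)
        if tap is None:
            tap = detect_tap(hand, "offline", config=config)

    if tap is not None:
        result.tap_time = tap.time
        result.tap_x, result.tap_y = tap.pos
        result.tap_mode = tap.mode
        result.time_to_tap = tap.time
        t_target = float(np.clip(tap.time, 0.0, design.duration))
        target_x = target_position(design, t_target)
        result.interception_error = interception_error(
            tap.pos[0], target_x, design.direction
        )
        result.error_y = tap.pos[1]
        speed = np.linalg.norm(hand.vel[:, :2], axis=1)
        result.hand_vel_pre_tap, _ = pre_tap_mean(hand, speed, tap.time, config)

    # pre-tap gaze state: at the trial's own tap for interception; the
    # judgment-task counterpart (aligned on the participant's mean tap time)
    # is computed in the statistics stage where that mean is known
    if tap is not None:
        gv, _ = pre_tap_mean(gaze, design.direction * gaze.vel_interp, tap.time, config)
        result.gaze_vel_pre_tap = gv
        t_eval = float(np.clip(tap.time - config.extrapolation_span_s, 0.0, design.duration))
        err = gaze.sample(gaze.pos, t_eval) - target_position(design, t_eval)
        result.gaze_pos_error_pre_tap = design.direction * err
        if gv is not None:
            result.predicted_endpoint_error = predicted_endpoint_error(
                gv, design.velocity, config
            )

    blink = bool(
        gaze_rec.missing[(gaze_rec.times >= 0) & (gaze_rec.times <= design.duration)].any()
    )
    return apply_exclusions(result, pursuit, saccades, gaze, design, blink, config)


def results_to_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    """Tabulate trial results (one row per trial)."""
    return pd.DataFrame([vars(r) for r in results])


def exclusion_counts(frame: pd.DataFrame) -> pd.Series:
    """Trial counts per exclusion reason plus retained/total accounting."""
    counts = {reason: 0 for reason in EXCLUSION_REASONS}
    for reasons in frame.loc[frame["excluded"], "exclusion_reason"]:
        for r in reasons.split(";"):
            if r:
                counts[r] += 1
    counts["excluded"] = int(frame["excluded"].sum())
    counts["retained"] = int((~frame["excluded"]).sum())
    counts["total"] = len(frame)
    return pd.Series(counts)
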