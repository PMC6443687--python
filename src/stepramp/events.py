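"""Oculomotor and manual event detection.

Saccades are detected from velocity and acceleration criteria: a candidate
sample must have a direction-aligned eye velocity at least twice the target
speed (same direction: forward candidates) or at most minus twice the
target speed (opposite direction: backward candidates), together with an
absolute acceleration above 300 cm/s^2.  The onset is the first sample of
the run of supra-threshold acceleration leading into the candidate; the
offset is the first sample after the velocity peak at which the slope of
the acceleration changes sign (this slightly underestimates the saccade
duration, which is accepted).

Pursuit onset is the start of the first velocity rise that exceeds twice
the fixation-velocity SD and subsequently stays above 30% of target speed
for 5 consecutive samples.

Taps are the first hand sample below 5 mm from the screen that moves
toward it while decelerating orthogonally by at least 50 cm/s^2 (online
criterion; 25 cm/s^2 offline), the online mode additionally requiring the
finger to have lifted at least 1 cm since trial start.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .preprocessing import KinematicTrace
from .trial_design import TrialDesign, target_position


@dataclass
class SaccadeEvent:
    onset: float               # s, relative to target motion onset
    offset: float
    amplitude: float           # cm, signed displacement over [onset, offset]
    direction_class: str       # "forward" | "backward"
    latency: float             # == onset (target onset is t = 0)
    ex: Optional[float] = None  # eye-crossing time, s; None if undefined

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PursuitOnset:
    latency: float
    baseline_sd: float         # cm/s, fixation velocity SD


@dataclass
class TapEvent:
    time: float
    pos: Tuple[float, float]   # (x, y) cm at the tap sample
    mode: str                  # "online" | "offline"


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Start/stop (inclusive) indices of True runs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_saccades(
    trace: KinematicTrace,
    design: TrialDesign,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> List[SaccadeEvent]:
    """Detect saccades during the target-motion epoch of a gaze trace."""
    t, vel, acc = trace.times, trace.vel, trace.acc
    rate = trace.rate
    speed = design.velocity
    v_al = design.direction * vel                   # along motion direction
    abs_acc = np.abs(np.where(np.isfinite(acc), acc, 0.0))

    epoch = (t >= 0) & (t <= design.duration)
    fast = (v_al >= config.saccade_velocity_factor * speed) | (
        v_al <= -config.saccade_velocity_factor * speed
    )
    cand = epoch & fast & (abs_acc > config.saccade_acc_threshold)

    runs = _runs(cand)
    # merge candidate runs separated by less than the merge gap
    gap = int(round(config.saccade_merge_gap_s * rate))
    merged: List[Tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    max_len = int(round(config.saccade_max_duration_s * rate))
    events: List[SaccadeEvent] = []
    half = int(round(config.acc_half_window_s * rate))
    for a, b in merged:
        # onset: walk back to the first sample of the acceleration run, then
        # advance by the estimator half-window.  The +/-10 ms two-point
        # acceleration at time t averages over [t-10, t+10] ms, so its first
        # threshold crossing leads the physical acceleration rise by the
        # half-window; adding it back locates the actual saccade start.
        i = a
        while i > 0 and abs_acc[i - 1] > config.saccade_acc_threshold:
            i -= 1
        onset_i = min(i + half, a)

        # saccade polarity from the candidate velocity (sign along motion)
        sign = 1.0 if v_al[a:b + 1].max() >= config.saccade_velocity_factor * speed else -1.0
        # peak velocity within the event
        hi = min(len(t) - 1, onset_i + max_len)
        seg = sign * v_al[onset_i:hi + 1]
        peak_i = onset_i + int(np.argmax(seg))

        # offset: first sign change of the acceleration slope after the peak
        jerk = np.diff(acc[peak_i:hi + 1])
        jerk = np.where(np.isfinite(jerk), jerk, 0.0)
        offset_i = hi
        if len(jerk) > 1:
            ref = np.sign(jerk[1]) if jerk[1] != 0 else -sign
            flips = np.nonzero(np.sign(jerk[1:]) == -ref)[0]
            if flips.size:
                offset_i = peak_i + 1 + int(flips[0])
        offset_i = min(offset_i, len(t) - 1)

        if (offset_i - onset_i) / rate < config.saccade_min_duration_s:
            continue
        # the offset rule truncates a symmetric saccade at ~3/4 of its
        # window (peak deceleration); amplitude is measured over the full
        # window, whose end is recovered by extending the detected
        # onset-offset interval by 4/3
        end_i = min(onset_i + int(round((offset_i - onset_i) * 4 / 3)), len(t) - 1)
        amplitude = float(trace.pos[end_i] - trace.pos[onset_i])
        direction_class = (
            "forward" if np.sign(amplitude) == design.direction else "backward"
        )
        events.append(
            SaccadeEvent(
                onset=float(t[onset_i]),
                offset=float(t[offset_i]),
                amplitude=amplitude,
                direction_class=direction_class,
                latency=float(t[onset_i]),
            )
        )
    return events


def detect_pursuit_onset(
    trace: KinematicTrace,
    design: TrialDesign,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Optional[PursuitOnset]:
    """First sustained rise of direction-aligned velocity, or None.

    The detection threshold is twice the SD of the eye velocity in the
    fixation window around target onset; the rise counts only if the
    velocity goes on to exceed 30% of target speed for 5 consecutive
    samples before dropping back below threshold.
    """
    t, vel = trace.times, trace.vel
    v_al = design.direction * vel
    lo, hi = config.baseline_window_s
    base = v_al[(t >= lo) & (t <= hi)]
    if base.size < 3:
        return None
    sd = float(np.std(base))
    thresh = config.pursuit_sd_factor * sd
    frac = config.pursuit_fraction * design.velocity
    k = config.pursuit_consecutive

    epoch = (t >= 0) & (t <= design.duration)
    above = epoch & (v_al > thresh)
    sustained = v_al >= frac
    for a, b in _runs(above):
        seg = sustained[a:b + 1]
        if seg.size >= k:
            hit = np.convolve(seg.astype(int), np.ones(k, dtype=int), "valid") == k
            if hit.any():
                return PursuitOnset(latency=float(t[a]), baseline_sd=sd)
    return None


def compute_ex(
    saccade: SaccadeEvent,
    trace: KinematicTrace,
    design: TrialDesign,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Optional[float]:
    """Eye-crossing time: position error / retinal slip, 100 ms pre-onset.

    Negative values mean the target is ahead of the eye.  Uses the
    saccade-interpolated 20 Hz velocity; undefined (None) when the retinal
    slip is below the guard epsilon or the evaluation point precedes target
    onset.
    """
    t_eval = saccade.onset - config.ex_lead_s
    if t_eval < 0 or t_eval < trace.times[0]:
        return None
    if trace.vel_interp is None:
        raise ValueError("attach vel_interp before computing EX")
    gaze_pos = trace.sample(trace.pos, t_eval)
    gaze_vel = trace.sample(trace.vel_interp, t_eval)
    err = gaze_pos - target_position(design, t_eval)
    slip = gaze_vel - design.signed_velocity
    if abs(slip) < config.ex_slip_epsilon:
        return None
    return float(err / slip)


def detect_tap(
    trace: KinematicTrace,
    mode: str = "online",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Optional[TapEvent]:
    """First qualifying screen-contact sample of a 3-D hand trace, or None."""
    if trace.pos.ndim != 2 or trace.pos.shape[1] != 3:
        raise ValueError("tap detection needs a 3-D hand trace (x, y, z)")
    if mode not in ("online", "offline"):
        raise ValueError(f"unknown tap mode {mode!r}")
    threshold = config.tap_decel_online if mode == "online" else config.tap_decel_offline

    z = trace.pos[:, 2]
    vz = trace.vel[:, 2]
    az = trace.acc[:, 2]
    ok = (
        (z < config.tap_height_cm)
        & (vz < 0)
        & np.where(np.isfinite(az), az >= threshold, False)
        # the lift guard keeps movement onset (filter ringing around
        # lift-off) from being misread as a tap; it is applied in both
        # modes since the offline search faces the same artifact
        & (np.maximum.accumulate(z) >= config.tap_lift_cm)
    )
    idx = np.nonzero(ok)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    return TapEvent(
        time=float(trace.times[i]),
        pos=(float(trace.pos[i, 0]), float(trace.pos[i, 1])),
        mode=mode,
    )
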