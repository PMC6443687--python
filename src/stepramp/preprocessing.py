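"""Signal conditioning for gaze and hand traces.

Raw position recordings are drift-corrected against the fixation epoch,
low-pass filtered with a zero-phase Butterworth filter (30 Hz cutoff,
2nd order applied forward-backward), differentiated with central
differences, and turned into acceleration with the +/-10 ms two-point rule.
A second, 20 Hz filtered velocity with saccade intervals linearly bridged
is produced for measures that must not be contaminated by saccadic peaks
(eye-crossing time, pre-tap gaze velocity).

Blink/dropout samples are bridged by linear interpolation only so the
filters stay well defined; the mask is preserved and trials with blinks
during target presentation are excluded downstream, never rescued.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .config import AnalysisConfig, DEFAULT_CONFIG

_UNIFORMITY_TOL = 1e-6  # s; allowed jitter of the sample clock


class FormatError(ValueError):
    """Raised for malformed or non-uniform recordings."""


class CannotCorrectError(ValueError):
    """Raised when the drift-correction window is too incomplete."""


@dataclass
class Recording:
    """Uniformly sampled position trace.

    ``pos`` is 1-D (horizontal gaze, cm) or (n, 3) for the hand, where
    columns are x (horizontal, fixation-centred), y (vertical) and z
    (distance orthogonal to the screen, 0 at contact).  ``missing`` marks
    blink / dropout samples.
    """

    times: np.ndarray
    pos: np.ndarray
    rate: float
    source: str = "gaze"          # "gaze" | "hand"
    missing: Optional[np.ndarray] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(
                self.pos if self.pos.ndim == 1 else self.pos[:, 0]
            )
        self.missing = np.asarray(self.missing, dtype=bool)
        if len(self.times) != len(self.pos):
            raise FormatError("times and pos must have equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            bad = np.nonzero(np.abs(dt - 1.0 / self.rate) > _UNIFORMITY_TOL)[0]
            if bad.size:
                raise FormatError(
                    f"non-uniform sampling at row {int(bad[0]) + 1}: "
                    f"dt={dt[bad[0]]:.6g} s, expected {1.0 / self.rate:.6g} s"
                )
        valid = ~self.missing
        arr = self.pos if self.pos.ndim == 1 else self.pos
        if not np.all(np.isfinite(arr[valid])):
            raise FormatError("non-finite position at non-missing sample")

    @property
    def n(self) -> int:
        return len(self.times)

    def copy(self) -> "Recording":
        return Recording(
            times=self.times.copy(),
            pos=self.pos.copy(),
            rate=self.rate,
            source=self.source,
            missing=self.missing.copy(),
        )


@dataclass
class KinematicTrace:
    """Filtered position plus velocity and acceleration, same time base.

    ``acc`` is NaN where the +/-10 ms window does not fit. ``vel_interp``
    (the 20 Hz, saccade-bridged velocity) is attached after saccade
    detection and is None until then.
    """

    times: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    rate: float
    source: str = "gaze"
    missing: Optional[np.ndarray] = None
    vel_interp: Optional[np.ndarray] = None

    def index_of(self, t: float) -> int:
        return int(round((t - self.times[0]) * self.rate))

    def sample(self, channel: np.ndarray, t: float) -> float:
        return float(np.interp(t, self.times, channel))


def _bridge_missing(times: np.ndarray, x: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Linearly interpolate across missing runs (edge runs held constant)."""
    if not missing.any():
        return x
    x = x.copy()
    good = ~missing
    if not good.any():
        raise FormatError("recording contains no valid samples")
    if x.ndim == 1:
        x[missing] = np.interp(times[missing], times[good], x[good])
    else:
        for j in range(x.shape[1]):
            x[missing, j] = np.interp(times[missing], times[good], x[good, j])
    return x


def drift_correct(
    rec: Recording,
    fixation_target: float | np.ndarray = 0.0,
    window: Tuple[float, float] | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Recording:
    """Shift the trace so its mean over the fixation window hits the target.

    The window defaults to the 100 ms preceding fixation-point offset.  The
    correction is a constant shift, so the operation is idempotent.  More
    than half the window missing raises :class:`CannotCorrectError`.
    """
    lo, hi = window if window is not None else config.drift_window_s
    sel = (rec.times >= lo) & (rec.times <= hi)
    if not sel.any():
        raise CannotCorrectError("drift window not sampled")
    ok = sel & ~rec.missing
    if ok.sum() < 0.5 * sel.sum():
        raise CannotCorrectError(">50% of drift window samples missing")
    out = rec.copy()
    if rec.pos.ndim == 1:
        out.pos = rec.pos - (rec.pos[ok].mean() - float(np.asarray(fixation_target)))
    else:
        target = np.broadcast_to(np.asarray(fixation_target, float), (rec.pos.shape[1],))
        out.pos = rec.pos - (rec.pos[ok].mean(axis=0) - target)
    return out


def _lowpass(x: np.ndarray, cutoff: float, rate: float, order: int) -> np.ndarray:
    if cutoff >= rate / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({rate / 2} Hz)")
    b, a = butter(order, cutoff / (rate / 2))
    return filtfilt(b, a, x, axis=0)


def filter_position(
    rec: Recording,
    cutoff: float | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Recording:
    """Zero-phase low-pass of position (default 30 Hz); DC gain is 1.

    Missing runs are bridged by linear interpolation before filtering and
    the mask re-applied after, so dropouts never leak filter transients.
    """
    cutoff = config.position_cutoff_hz if cutoff is None else cutoff
    x = _bridge_missing(rec.times, rec.pos, rec.missing)
    out = rec.copy()
    out.pos = _lowpass(x, cutoff, rec.rate, config.filter_order)
    return out


def differentiate(pos: np.ndarray, rate: float) -> np.ndarray:
    """Velocity by central differences (one-sided at the trace ends)."""
    if len(pos) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(pos, 1.0 / rate, axis=0)


def acceleration(
    vel: np.ndarray, rate: float, half_window_s: float | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """acc(t) = (vel(t+h) - vel(t-h)) / 2h with h = 10 ms; NaN at edges."""
    h = config.acc_half_window_s if half_window_s is None else half_window_s
    k = max(1, int(round(h * rate)))
    acc = np.full_like(np.asarray(vel, float), np.nan)
    acc[k:-k] = (vel[2 * k:] - vel[:-2 * k]) / (2 * k / rate)
    return acc


def compute_kinematics(
    rec: Recording,
    config: AnalysisConfig = DEFAULT_CONFIG,
    drift_target: float | np.ndarray | None = None,
) -> KinematicTrace:
    """Standard conditioning chain: drift-correct, filter, differentiate."""
    if drift_target is not None:
        rec = drift_correct(rec, drift_target, config=config)
    filt = filter_position(rec, config=config)
    vel = differentiate(filt.pos, rec.rate)
    acc = acceleration(vel, rec.rate, config=config)
    return KinematicTrace(
        times=rec.times,
        pos=filt.pos,
        vel=vel,
        acc=acc,
        rate=rec.rate,
        source=rec.source,
        missing=rec.missing.copy(),
    )


def _merge_intervals(intervals: Sequence[Tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted((float(a), float(b)) for a, b in intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return merged


def saccade_interpolated_velocity(
    trace: KinematicTrace,
    saccade_intervals: Sequence[Tuple[float, float]],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """20 Hz filtered velocity with saccades linearly bridged.

    Velocity inside each (onset, offset) interval is replaced by the chord
    between the bounding samples before the second-stage low-pass, removing
    saccadic peaks from smooth-pursuit velocity estimates.
    """
    vel = trace.vel.copy()
    for lo, hi in _merge_intervals(saccade_intervals):
        i0 = max(0, trace.index_of(lo))
        i1 = min(len(vel) - 1, trace.index_of(hi))
        if i1 <= i0:
            continue
        # anchor the chord on the samples just outside the saccade so the
        # bridge never includes saccadic velocity itself
        a = max(0, i0 - 1)
        b = min(len(vel) - 1, i1 + 1)
        vel[i0:i1 + 1] = np.interp(
            np.arange(i0, i1 + 1), [a, b], [vel[a], vel[b]]
        )
    return _lowpass(vel, config.interp_cutoff_hz, trace.rate, config.filter_order)
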