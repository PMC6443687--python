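"""Step-ramp stimulus design.

The target appears with a horizontal step away from fixation and immediately
ramps back, crossing the initial fixation location after a prescribed target
crossing time (TX).  The step size is therefore tied to the target velocity:
a target that should cross fixation after ``tx`` seconds while moving at
``velocity`` cm/s must appear ``velocity * tx`` cm on the far side of
fixation, opposite to its motion direction.

Coordinate conventions: horizontal screen position in cm, x = 0 at the
initial fixation location, rightward positive.  Time t = 0 at target motion
onset; the preceding fixation interval appears as negative time in
recordings.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

#: Factorial design levels of the protocol.
VELOCITIES: Tuple[float, ...] = (13.0, 15.0, 17.0)          # cm/s
CROSSING_TIMES: Tuple[float, ...] = (0.100, 0.240)          # s (short, long)
DURATIONS: Tuple[float, ...] = (0.600, 0.650, 0.700)        # s
DIRECTIONS: Tuple[int, ...] = (1, -1)                       # right, left

TASKS = ("judgment", "interception")


class InvalidDesignError(ValueError):
    """Raised for physically impossible stimulus parameters."""


def compute_step(velocity: float, tx: float, direction: int) -> float:
    """Signed initial step (cm) so the target crosses fixation at ``tx``.

    The step is placed opposite to the motion direction:
    ``step + direction * velocity * tx == 0``.
    """
    if velocity <= 0:
        raise InvalidDesignError(f"velocity must be positive, got {velocity}")
    if tx <= 0:
        raise InvalidDesignError(f"crossing time must be positive, got {tx}")
    if direction not in (-1, 1):
        raise InvalidDesignError(f"direction must be +1 or -1, got {direction}")
    return -direction * velocity * tx


@dataclass(frozen=True)
class TrialDesign:
    """One trial's target kinematics.

    ``step`` is derived from the other fields and satisfies
    ``sign(step) == -direction`` and ``|step| == velocity * tx``.
    """

    velocity: float            # cm/s, speed magnitude
    tx: float                  # s, target crossing time
    direction: int             # +1 rightward, -1 leftward
    duration: float            # s, motion duration
    task: str = "judgment"

    def __post_init__(self):
        compute_step(self.velocity, self.tx, self.direction)  # validates
        if self.duration <= self.tx:
            raise InvalidDesignError(
                f"duration {self.duration} must exceed crossing time {self.tx}"
            )
        if self.task not in TASKS:
            raise InvalidDesignError(f"unknown task {self.task!r}")

    @property
    def step(self) -> float:
        """Signed initial horizontal offset from fixation, cm."""
        return compute_step(self.velocity, self.tx, self.direction)

    @property
    def signed_velocity(self) -> float:
        return self.direction * self.velocity


def target_position(design: TrialDesign, t) -> np.ndarray | float:
    """Horizontal target position (cm) at time ``t`` since motion onset."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > design.duration):
        raise ValueError(
            f"t must lie in [0, {design.duration}] s (target visible epoch)"
        )
    out = design.step + design.direction * design.velocity * t
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TargetTrajectory:
    """Sampled target path; ``x(0) == step`` and ``x(tx) == 0``."""

    times: np.ndarray
    x: np.ndarray

    def interpolate(self, t: float) -> float:
        return float(np.interp(t, self.times, self.x))


def target_trajectory(design: TrialDesign, rate: float = 500.0) -> TargetTrajectory:
    """Sample the target position over the visible epoch [0, duration]."""
    n = int(round(design.duration * rate)) + 1
    times = np.arange(n) / rate
    times[-1] = min(times[-1], design.duration)
    return TargetTrajectory(times=times, x=target_position(design, times))


def find_crossing_time(traj: TargetTrajectory) -> float:
    """Root of x(t) = 0 by bracketing + Brent's method on the sampled path.

    Serves as the independent check that a generated trajectory really
    crosses fixation at the designed TX.
    """
    x = traj.x
    sign_change = np.nonzero(np.diff(np.sign(x)) != 0)[0]
    if x[0] == 0:
        return float(traj.times[0])
    if sign_change.size == 0:
        raise ValueError("trajectory never crosses fixation")
    i = int(sign_change[0])
    return float(
        brentq(traj.interpolate, traj.times[i], traj.times[i + 1], xtol=1e-12)
    )


def enumerate_block(
    repetitions: int,
    seed: int | np.random.Generator = 0,
    task: str = "judgment",
    velocities: Sequence[float] = VELOCITIES,
    crossing_times: Sequence[float] = CROSSING_TIMES,
    durations: Sequence[float] = DURATIONS,
    directions: Sequence[int] = DIRECTIONS,
) -> List[TrialDesign]:
    """Full factorial block (TX x duration x velocity x direction), shuffled.

    With the protocol levels and 7 repetitions this yields the standard
    252-trial block.  The same seed reproduces the same order bit-for-bit;
    different seeds permute the same multiset of designs.
    """
    if repetitions < 1:
        raise InvalidDesignError("repetitions must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    block = [
        TrialDesign(velocity=v, tx=tx, direction=d, duration=dur, task=task)
        for tx in crossing_times
        for dur in durations
        for v in velocities
        for d in directions
        for _ in range(repetitions)
    ]
    order = rng.permutation(len(block))
    return [block[i] for i in order]
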