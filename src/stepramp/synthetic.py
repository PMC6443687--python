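"""Synthetic gaze and hand recordings with known ground truth.

Every downstream stage (filtering, event detection, trial measures, effect
statistics) is tested against traces generated here, so the generator
models exactly the features those stages key on:

* gaze -- Gaussian fixation/measurement noise, pursuit that starts after a
  latency and approaches ``gain x target velocity`` with a first-order time
  constant, optional catch-up saccades with a raised-cosine velocity
  profile (peak velocity ``2 x amplitude / duration``) during which pursuit
  is paused, and blinks as runs of missing samples;
* hand -- a reach that lifts off the start position, travels to an aimed
  interception point with a minimum-jerk horizontal profile, descends with
  a constant-velocity final approach and brakes at screen contact with a
  configurable deceleration (small negative ``z`` excursions during braking
  stand in for finger-pad compression);
* cohort -- a full factorial session per participant in which the aimed
  endpoint and the velocity percept are biased by a configurable
  multiplicative misperception of target velocity tied to the trial's
  oculomotor class.

All randomness flows from explicit seeds; the same seed reproduces a
byte-identical dataset.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .preprocessing import Recording
from .trial_design import TrialDesign, enumerate_block, target_position


class InvalidPlanError(ValueError):
    """Raised for inconsistent simulation plans (e.g. saccade inside blink)."""


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SaccadePlan:
    """One injected catch-up saccade."""

    onset: float           # s, relative to target motion onset
    amplitude: float       # cm, signed in screen coordinates
    duration: float = 0.035  # s

    def __post_init__(self):
        if not (0 < self.duration <= 0.1):
            raise InvalidPlanError("saccade duration must be in (0, 0.1] s")
        if self.amplitude == 0:
            raise InvalidPlanError("saccade amplitude must be non-zero")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class BlinkPlan:
    onset: float
    duration: float


@dataclass(frozen=True)
class GazeSimParams:
    """Oculomotor model parameters.

    ``pursuit_tau`` is the first-order time constant of the rise of pursuit
    velocity towards ``pursuit_gain x target velocity``; 40 ms reflects the
    brisk pursuit initiation seen in step-ramp paradigms where the target
    moves near the fovea.  ``fixation_noise_sd`` is additive per-sample
    position noise (video-based tracker noise, applied to the whole trace).
    """

    pursuit_latency: float = 0.140     # s
    pursuit_gain: float = 0.95
    pursuit_tau: float = 0.040         # s
    fixation_noise_sd: float = 0.02    # cm
    saccade: Optional[SaccadePlan] = None
    blink: Optional[BlinkPlan] = None
    sample_rate: float = 500.0

    def __post_init__(self):
        if not (0 < self.pursuit_gain <= 1.5):
            raise InvalidPlanError("pursuit_gain must be in (0, 1.5]")
        if self.sample_rate <= 0:
            raise InvalidPlanError("sample_rate must be positive")
        if self.saccade is not None and self.blink is not None:
            if (self.saccade.onset < self.blink.onset + self.blink.duration
                    and self.blink.onset < self.saccade.offset):
                raise InvalidPlanError("saccade overlaps blink")


@dataclass(frozen=True)
class HandSimParams:
    """Reach model parameters.

    The aimed endpoint is the target position extrapolated over
    ``extrapolation_span`` (see :class:`AnalysisConfig`) using
    ``velocity_bias x target velocity`` -- the knob that turns a velocity
    misperception into a signed interception error.
    """

    reaction_time: float = 0.180       # s from target onset to lift-off
    movement_time: float = 0.300       # s from lift-off to contact
    velocity_bias: float = 1.0
    endpoint_noise_sd: float = 0.15    # cm, aim-point scatter
    trace_noise_sd: float = 0.001      # cm, marker jitter (~10 um, Optotrak-class)
    approach_height: float = 3.0       # cm, peak lift
    approach_velocity: float = 6.0     # cm/s, final descent speed
    approach_distance: float = 0.8     # cm, height where final descent starts
    contact_decel: float = 100.0       # cm/s^2, braking at the screen
    start_y: float = -25.0             # cm below the target's row
    sample_rate: float = 250.0

    def __post_init__(self):
        if self.approach_height <= 1.0:
            raise InvalidPlanError("approach_height must exceed 1 cm")
        if self.sample_rate <= 0:
            raise InvalidPlanError("sample_rate must be positive")

    @property
    def tap_time(self) -> float:
        return self.reaction_time + self.movement_time


@dataclass
class GroundTruth:
    """What the generator actually put into a trial."""

    pursuit_onset: Optional[float] = None
    saccade_onset: Optional[float] = None
    saccade_offset: Optional[float] = None
    saccade_amplitude: Optional[float] = None
    saccade_class: Optional[str] = None        # "forward" | "backward"
    tap_time: Optional[float] = None
    tap_pos: Optional[Tuple[float, float]] = None
    velocity_bias: Optional[float] = None
    params: dict = field(default_factory=dict)

    @property
    def oculomotor_class(self) -> str:
        return self.saccade_class or "pure_pursuit"


# --------------------------------------------------------------------------
# gaze
# --------------------------------------------------------------------------

def _time_base(duration: float, rate: float, pre_roll: float) -> np.ndarray:
    n = int(round((pre_roll + duration) * rate)) + 1
    return np.arange(n) / rate - pre_roll


def _pursuit_position(t: np.ndarray, latency: float, v: float, tau: float) -> np.ndarray:
    """Integral of v * (1 - exp(-(t - latency)/tau)) for t >= latency, else 0."""
    s = np.maximum(t - latency, 0.0)
    return v * (s - tau * (1.0 - np.exp(-s / tau)))


def _saccade_displacement(t: np.ndarray, plan: SaccadePlan) -> np.ndarray:
    """Displacement of a raised-cosine velocity pulse; integrates exactly
    to ``plan.amplitude`` over the saccade window."""
    u = np.clip((t - plan.onset) / plan.duration, 0.0, 1.0)
    return plan.amplitude * (u - np.sin(2 * np.pi * u) / (2 * np.pi))


def simulate_gaze(
    design: TrialDesign,
    params: GazeSimParams = GazeSimParams(),
    seed: int | np.random.Generator = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[Recording, GroundTruth]:
    """Simulate one trial's horizontal gaze trace.

    The eye fixates x = 0 (plus noise) until ``pursuit_latency``, then
    accelerates towards ``gain x target velocity`` with time constant
    ``pursuit_tau``.  If a saccade is planned, pursuit is paused for its
    duration and the raised-cosine displacement profile is inserted, so the
    trace displacement across the saccade window equals the requested
    amplitude exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = _time_base(design.duration, params.sample_rate, config.pre_roll_s)
    v_signed = design.signed_velocity * params.pursuit_gain

    plan = params.saccade
    x = _pursuit_position(t, params.pursuit_latency, v_signed, params.pursuit_tau)
    if plan is not None:
        # the saccadic pulse rides on ongoing pursuit; its own integral is
        # shrunk by the pursuit displacement over the window so the total
        # trace displacement across [onset, offset] equals the requested
        # amplitude exactly
        bounds = _pursuit_position(
            np.array([plan.onset, plan.offset]),
            params.pursuit_latency, v_signed, params.pursuit_tau,
        )
        pulse = dataclasses.replace(
            plan, amplitude=plan.amplitude - float(bounds[1] - bounds[0])
        )
        x = x + _saccade_displacement(t, pulse)

    if params.fixation_noise_sd > 0:
        x = x + rng.normal(0.0, params.fixation_noise_sd, size=t.shape)

    missing = np.zeros(t.shape, dtype=bool)
    if params.blink is not None:
        missing |= (t >= params.blink.onset) & (t < params.blink.onset + params.blink.duration)
        x = np.where(missing, np.nan, x)

    rec = Recording(times=t, pos=x, rate=params.sample_rate, source="gaze", missing=missing)
    truth = GroundTruth(
        pursuit_onset=params.pursuit_latency,
        params={"gaze": dataclasses.asdict(params)},
    )
    if plan is not None:
        truth.saccade_onset = plan.onset
        truth.saccade_offset = plan.offset
        truth.saccade_amplitude = plan.amplitude
        truth.saccade_class = (
            "forward" if np.sign(plan.amplitude) == design.direction else "backward"
        )
    return rec, truth


# --------------------------------------------------------------------------
# hand
# --------------------------------------------------------------------------

def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk position profile on s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


def aimed_endpoint(
    design: TrialDesign,
    tap_time: float,
    velocity_bias: float,
    span: float,
) -> float:
    """Aim point: target position ``span`` s before the planned tap,
    extrapolated with the (mis)perceived velocity."""
    anchor = target_position(
        design, float(np.clip(tap_time - span, 0.0, design.duration))
    )
    return anchor + velocity_bias * design.signed_velocity * span


def simulate_hand(
    design: TrialDesign,
    params: HandSimParams = HandSimParams(),
    seed: int | np.random.Generator = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[Recording, GroundTruth]:
    """Simulate one interception trial's 3-D fingertip trace.

    z is the distance orthogonal to the screen (0 at contact).  The finger
    rests on the start position, lifts to ``approach_height``, descends to
    ``approach_distance`` while travelling to the aimed endpoint, makes a
    constant-velocity final approach and brakes with ``contact_decel`` at
    the screen.  If the planned contact falls outside the recording the
    trial is generated without a tap (ground-truth tap is None).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = params.sample_rate
    t = _time_base(design.duration, rate, config.pre_roll_s)
    if params.tap_time >= design.duration + 0.3:
        raise InvalidPlanError("planned tap far beyond target presentation")

    t0 = params.reaction_time
    tc = params.tap_time
    t_app = params.approach_distance / params.approach_velocity
    tm = tc - t_app                      # start of final descent
    if tm <= t0:
        raise InvalidPlanError("movement too short for the approach phase")

    aim_x = aimed_endpoint(design, tc, params.velocity_bias, config.extrapolation_span_s)
    aim_x += rng.normal(0.0, params.endpoint_noise_sd)
    aim_y = rng.normal(0.0, params.endpoint_noise_sd)

    contact = tc <= t[-1] - 2.0 / rate   # otherwise: no contact in recording

    # horizontal / vertical: minimum jerk from start to aim over the movement
    s = _minimum_jerk((t - t0) / (tc - t0))
    x = aim_x * s
    y = params.start_y + (aim_y - params.start_y) * s

    # orthogonal: lift-and-descend bump, then linear approach, then braking
    h, z1, v1 = params.approach_height, params.approach_distance, params.approach_velocity
    u = np.clip((t - t0) / (tm - t0), 0.0, 1.0)
    z_bump = h * np.sin(np.pi * u) ** 2 * (1 - u) + z1 * u
    z = np.where(t < tm, z_bump, z1 - v1 * (t - tm))
    if contact:
        # braking: velocity ramps from -v1 to 0, then the finger rests;
        # dt_c is clipped so z holds at the small compression depth after
        dt_c = np.clip(t - tc, 0.0, v1 / params.contact_decel)
        z_brake = -v1 * dt_c + 0.5 * params.contact_decel * dt_c**2
        z = np.where(t >= tc, z_brake, z)
    z[t < t0] = 0.0

    pos = np.column_stack([x, y, z])
    if params.trace_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.trace_noise_sd, size=pos.shape)

    rec = Recording(times=t, pos=pos, rate=rate, source="hand")
    truth = GroundTruth(
        tap_time=tc if contact else None,
        tap_pos=(aim_x, aim_y) if contact else None,
        velocity_bias=params.velocity_bias,
        params={"hand": dataclasses.asdict(params)},
    )
    return rec, truth


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect structure of a simulated cohort.

    ``delta`` is the velocity misperception attached to corrective
    saccades: forward saccades bias the perceived velocity by ``1 + delta``,
    backward saccades by ``1 - delta``.  ``mixing`` gives, per crossing
    time, the probability that a trial is tracked with a saccade (short TX
    trials mix pure pursuit with forward saccades, long TX with backward
    ones).  ``effect_window_s`` restricts the bias to trials whose saccade
    falls within that time of the (planned) tap; None applies it always.
    """

    delta: float = 0.05
    participant_delta_sd: float = 0.01
    mixing: Dict[float, float] = field(
        default_factory=lambda: {0.100: 0.5, 0.240: 0.5}
    )
    judgment_slope: float = 1.0            # logistic slope per cm/s
    effect_window_s: Optional[float] = None
    saccade_latency: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: {
            ("judgment", "forward"): 0.314,
            ("judgment", "backward"): 0.253,
            ("interception", "forward"): 0.257,
            ("interception", "backward"): 0.197,
        }
    )
    saccade_latency_sd: float = 0.040
    min_saccade_amplitude: float = 1.2     # cm; smaller catch-ups are not injected
    pursuit_latency: Dict[str, float] = field(
        default_factory=lambda: {"judgment": 0.150, "interception": 0.130}
    )
    pursuit_latency_sd: float = 0.012


@dataclass
class SimulatedTrial:
    participant: int
    trial_id: str
    design: TrialDesign
    gaze: Recording
    truth: GroundTruth
    hand: Optional[Recording] = None
    judgment: Optional[str] = None         # "fast" | "slow"


def _planned_saccade(
    design: TrialDesign,
    sclass: str,
    onset: float,
    pursuit_latency: float,
    gaze: GazeSimParams,
    spec: EffectSpec,
) -> SaccadePlan:
    """Catch-up saccade whose amplitude is the model position error at onset."""
    eye = _pursuit_position(
        np.array([onset]), pursuit_latency,
        design.signed_velocity * gaze.pursuit_gain, gaze.pursuit_tau,
    )[0]
    err = target_position(design, min(onset, design.duration)) - eye
    sign = design.direction if sclass == "forward" else -design.direction
    amplitude = sign * max(spec.min_saccade_amplitude, abs(err))
    duration = float(np.clip(0.025 + 0.010 * abs(amplitude), 0.025, 0.06))
    return SaccadePlan(onset=onset, amplitude=amplitude, duration=duration)


def simulate_trial(
    design: TrialDesign,
    sclass: str,
    spec: EffectSpec,
    rng: np.random.Generator,
    participant_delta: float,
    reference_velocity: Optional[float],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[Recording, Optional[Recording], Optional[str], GroundTruth]:
    """One cohort trial of a given oculomotor class ('pure_pursuit',
    'forward' or 'backward')."""
    task = design.task
    pl = max(0.08, rng.normal(spec.pursuit_latency[task], spec.pursuit_latency_sd))
    gaze_params = GazeSimParams(pursuit_latency=pl)

    hand_defaults = HandSimParams()
    tap_planned = hand_defaults.tap_time

    plan = None
    if sclass != "pure_pursuit":
        mean_lat = spec.saccade_latency[(task, sclass)]
        lo = pl + 0.02
        hi = design.duration - 0.08
        onset = float(np.clip(rng.normal(mean_lat, spec.saccade_latency_sd), lo, hi))
        plan = _planned_saccade(design, sclass, onset, pl, gaze_params, spec)
        gaze_params = dataclasses.replace(gaze_params, saccade=plan)

    # effect: bias perceived velocity when a saccade is present (optionally
    # only when it lands close enough to the planned tap)
    delta = participant_delta
    bias = 1.0
    if plan is not None:
        active = True
        if spec.effect_window_s is not None:
            active = (tap_planned - plan.onset) <= spec.effect_window_s
        if active:
            bias = 1.0 + delta if sclass == "forward" else 1.0 - delta

    gaze_rec, truth = simulate_gaze(design, gaze_params, rng, config=config)
    truth.velocity_bias = bias

    hand_rec = None
    judgment = None
    if task == "interception":
        hand_params = dataclasses.replace(hand_defaults, velocity_bias=bias)
        hand_rec, hand_truth = simulate_hand(design, hand_params, rng, config=config)
        truth.tap_time = hand_truth.tap_time
        truth.tap_pos = hand_truth.tap_pos
        truth.params.update(hand_truth.params)
    else:
        perceived = bias * design.velocity
        ref = design.velocity if reference_velocity is None else reference_velocity
        p_fast = 1.0 / (1.0 + np.exp(-spec.judgment_slope * (perceived - ref)))
        judgment = "fast" if rng.random() < p_fast else "slow"

    return gaze_rec, hand_rec, judgment, truth


def simulate_cohort(
    n_participants: int = 10,
    effect_spec: EffectSpec = EffectSpec(),
    seed: int = 0,
    tasks: Sequence[str] = ("judgment", "interception"),
    blocks: int = 2,
    repetitions: int = 7,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> List[SimulatedTrial]:
    """Simulate a full multi-participant study.

    Each participant runs ``blocks`` factorial blocks per task.  Short-TX
    trials mix pure pursuit with forward saccades and long-TX trials mix
    pure pursuit with backward saccades, with the probabilities given by
    ``effect_spec.mixing``.  Judgment responses compare the (biased)
    perceived velocity against the running mean of previously presented
    velocities.
    """
    root = np.random.default_rng(seed)
    trials: List[SimulatedTrial] = []
    for p in range(n_participants):
        prng = np.random.default_rng(root.integers(2**31))
        pdelta = effect_spec.delta + prng.normal(0.0, effect_spec.participant_delta_sd)
        for task in tasks:
            seen: List[float] = []
            counter = 0
            for b in range(blocks):
                for design in enumerate_block(repetitions, prng, task=task):
                    p_sacc = effect_spec.mixing.get(design.tx, 0.0)
                    if prng.random() < p_sacc:
                        sclass = "forward" if design.tx == min(effect_spec.mixing) else "backward"
                    else:
                        sclass = "pure_pursuit"
                    ref = float(np.mean(seen)) if seen else None
                    gaze_rec, hand_rec, judgment, truth = simulate_trial(
                        design, sclass, effect_spec, prng, pdelta, ref, config=config
                    )
                    seen.append(design.velocity)
                    trials.append(
                        SimulatedTrial(
                            participant=p,
                            trial_id=f"p{p:02d}_{task[:3]}_{counter:04d}",
                            design=design,
                            gaze=gaze_rec,
                            hand=hand_rec,
                            judgment=judgment,
                            truth=truth,
                        )
                    )
                    counter += 1
    return trials
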