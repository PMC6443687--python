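# Methods

## Coordinate and time conventions

Positions are in cm on the screen (the recording rig reports screen
coordinates; at a typical viewing distance 1 cm ≈ 1° of visual angle, but
no angular conversion is performed). The horizontal axis is centred on the
initial fixation location, rightward positive; the 5 cm vertical offset of
the fixation point from the screen centre is treated as metadata since all
motion and all analyses are horizontal. Time zero is target motion onset;
recordings include a 0.65 s pre-roll (600 ms fixation + 50 ms gap), so a
700 ms trial sampled at 500 Hz has 676 samples. Hand traces are 3-D, with
z the distance orthogonal to the screen (0 at contact).

## Stimulus design

A trial is defined by speed v ∈ {13, 15, 17} cm/s, crossing time
TX ∈ {0.100, 0.240} s, direction d = ±1 and duration ∈ {0.600, 0.650,
0.700} s. The initial step is s = −d·v·TX, which makes the trajectory
x(t) = s + d·v·t cross fixation exactly at TX; `find_crossing_time`
verifies this by bracketing + Brent root-finding on the sampled
trajectory. Blocks are the full 36-cell factorial crossed with
repetitions and shuffled by a seeded generator; nothing constrains
consecutive repeats (the protocol does not specify any such constraint).

## Signal conditioning

Drift correction subtracts the difference between the mean gaze position
over the 100 ms before fixation offset and the fixation location; it is a
constant shift, hence idempotent and order-independent with respect to
filtering (correction is applied first). Position is low-pass filtered at
30 Hz with a 2nd-order Butterworth applied forward–backward (zero phase,
effective 4th order) — the filter order is not dictated by the protocol;
zero phase was chosen because event latencies are the primary measure.
Velocity is the central difference of filtered position (one-sided at the
ends); the differencing scheme is likewise an implementation choice.
Acceleration is (v(t+10 ms) − v(t−10 ms))/20 ms, undefined (NaN) within
10 ms of the trace ends. A second velocity signal for EX and pre-tap gaze
velocity is built by linearly bridging velocity across detected saccades
(anchored on the samples just outside each interval, overlapping intervals
merged) and filtering at 20 Hz. Missing runs (blinks) are bridged by
linear interpolation only to keep the filters well defined; the mask is
preserved and blink trials are excluded, never rescued.

## Event detection

**Saccades.** Candidate samples need direction-aligned velocity ≥ 2× the
target speed or ≤ −2× it, plus |acceleration| > 300 cm/s². Candidate runs
closer than 20 ms are merged and events shorter than 10 ms discarded
(debouncing; unspecified by the protocol). The onset is the first sample
of the supra-threshold acceleration run leading into the candidate,
advanced by the 10 ms half-window of the acceleration estimator: the
two-point ±10 ms difference at time t averages the acceleration over
[t−10, t+10] ms, so its first threshold crossing systematically leads the
physical acceleration rise by the half-window; adding it back recovers
injected saccade onsets with ~2 ms mean error instead of ~8 ms. The
offset is the first sign change of the acceleration slope after the
velocity peak. For a symmetric (raised-cosine) velocity profile that point
is the peak deceleration at ¾ of the saccade window, a known
underestimation of the duration which is accepted for the offset itself;
the *amplitude* is therefore measured as the position change over the
onset–offset interval extended by 4/3 — exact for symmetric profiles and
within 0.05 cm for the simulated catch-up range (1.2–2 cm). Amplitude sign
in screen coordinates against target direction gives the forward/backward
class.

**Pursuit onset.** The fixation-velocity SD is taken from −50 to +50 ms
around target onset; the latency is the start of the first velocity run
above 2 SD that goes on to exceed 30 % of target speed for 5 consecutive
samples. Onsets below 50 ms are treated as anticipatory downstream.

**Eye-crossing time.** EX = position error / retinal slip 100 ms before
saccade onset, using the 20 Hz saccade-bridged velocity. EX is undefined
when the evaluation point precedes target onset or |slip| < 0.5 cm/s (the
guard bounds EX at 10 s for a 5 cm error; the protocol states no epsilon).

**Taps.** First sample with z < 0.5 cm, moving toward the screen, with
orthogonal deceleration ≥ 50 cm/s² online / 25 cm/s² offline. The
requirement of having lifted ≥ 1 cm since trial start — which exists to
keep movement onset from being misread as a tap — is applied in both
modes: zero-phase filtering produces a brief toward-screen/decelerating
artifact at lift-off that would otherwise trigger the offline rule while
the finger still rests on the start position.

## Exclusion rules

A trial is excluded (all violated reasons recorded, order-independent) if:
no pursuit onset; pursuit latency < 50 ms; a blink during target
presentation; gaze-target error > 5 cm evaluated 10 ms after a saccade
offset (the evaluation delay is an implementation choice — immediately
post-saccadic, after transients); and for interception, no tap in either
mode or a tap > 3 cm from the target. Trials with saccades of both
classes are classified "mixed": retained in counts, left out of the
saccade-vs-pursuit contrasts (how multi-saccade trials were handled is not
specified; this is the conservative reading). Vertical tap error is
reported as mean ± SD only.

## Statistics

The saccade effect is computed per participant × class: within each
(TX, velocity) cell the saccade-trial mean minus the pure-pursuit mean of
the dependent variable, averaged over TX within velocity and then over the
velocities that have both trial types. Forward-vs-backward contrasts use
one-sided paired t-tests with the orientation fixed a priori (forward >
backward for p("fast"), interception error and pre-tap hand velocity);
other comparisons are two-sided. No multiple-testing correction is
applied. Cross-participant relations use Pearson correlation (n ≥ 3).
The interception window analysis pools trials across participants (per
window: saccade 100–200 or 200–300 ms before the tap), compares them to
the pooled pure-pursuit mean and attaches a seeded percentile-bootstrap CI
over trial resampling; windows with < 5 trials are flagged unstable. The
judgment counterpart aligns the windows on each participant's mean
time-until-tap from the interception task (plus a last-100 ms-of-trial
window) and bootstraps over participants.

## Synthetic data

The generator reproduces exactly the features the detectors key on, with
defaults chosen as typical for this class of experiment:

| parameter | default | rationale |
|---|---|---|
| pursuit latency | 150 ms judgment / 130 ms interception (SD 12 ms) | latencies shorten under time pressure |
| pursuit gain | 0.95, time constant 40 ms | brisk step-ramp pursuit initiation |
| gaze noise | 0.02 cm per sample | video eye-tracker jitter (~0.02°) |
| saccade profile | raised cosine, peak velocity 2·amplitude/duration | smooth, compactly supported; satisfies both detection thresholds for realistic sizes |
| saccade latencies | fwd 314/257 ms, bwd 253/197 ms (judgment/interception), SD 40 ms | forward saccades trail backward ones; both earlier under time pressure |
| saccade amplitude | model position error at onset, floor 1.2 cm | catch-up saccades correct the accumulated position error; smaller ones would sit below the velocity threshold and are not injected |
| hand marker noise | 0.001 cm | active-marker motion capture jitter (~10 µm) |
| reach | min-jerk, reaction 180 ms + movement 300 ms, lift 3 cm | taps land ~480 ms after target onset, inside the presentation |
| contact braking | 100 cm/s² from a 6 cm/s final descent | brisk tap; the small sub-screen z excursion during braking stands in for finger-pad compression |
| endpoint noise | 0.15 cm | motor scatter around the aimed point |

The injected saccadic pulse rides on continuous pursuit and is scaled so
the trace displacement across the saccade window equals the requested
amplitude exactly. The aimed interception point is the target position
100 ms before the planned tap extrapolated with `velocity_bias ×` target
velocity, so a bias of 1 ± δ produces an analytic error of ±δ·v·0.1 s.
Cohorts tie the bias to the oculomotor class (forward 1+δ, backward 1−δ;
δ = 0.05 by default with 0.01 between-participant SD), mix pure pursuit
and saccade trials 50/50 per TX, and generate judgment responses from a
logistic comparison of perceived velocity against the running mean of the
velocities seen so far. An optional `effect_window_s` restricts the bias
to saccades close to the planned tap, the construction used to test the
window analysis. The spontaneous-saccade mixing proportions are free
parameters of the generator; nothing in the protocol fixes them.

What the generator does **not** emulate: binocular disparity and averaging,
head movement, pursuit velocity fluctuations and catch-up dynamics beyond
a first-order rise, saccade main-sequence variability, online corrections
of the reach, or task learning. Passing the recovery suite therefore shows
that the detectors invert this forward model at realistic noise levels,
not that they are robust to every idiosyncrasy of human recordings.

## Numerical choices and problem sizes

All randomness descends from explicit integer seeds (NumPy PCG64); reruns
are byte-identical. Recordings are uniform to 1e-9 s relative tolerance on
write and 1e-6 s on read. The CSV float format (%.12g) keeps round trips
lossless to 1e-9. The test and acceptance suites use scaled cohorts — 100
trials per recovery condition, a 1008-trial single-task cohort for effect
recovery, 500 replications for bootstrap coverage — sizes at which the
Monte-Carlo error of each checked quantity is several times smaller than
its tolerance.

## Known limitations

- Saccade amplitudes assume an approximately symmetric velocity profile
  (the 4/3 window extension); strongly skewed profiles would bias them.
- The acceleration estimator limits event localisation near the trace
  edges (first/last 10 ms undefined).
- EX is undefined for saccades earlier than 100 ms after target onset.
- The judgment response model is stationary within a session; sequential
  effects beyond the running-mean reference are not modelled.
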