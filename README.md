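# stepramp

Analysis pipeline for step-ramp tracking and interception experiments:
oculomotor and manual event detection, derived kinematic measures, trial
exclusion accounting, and statistics for the effect of corrective saccades
on velocity judgments and interception errors. It is written for
sensorimotor researchers who record gaze (≈500 Hz) and fingertip
(≈250 Hz) positions on a screen while participants track step-ramp targets
and either judge their speed or tap on them.

## The paradigm and the measures

In a step-ramp (Rashbass) trial the target appears with a horizontal step
of size `−d · v · TX` away from fixation (direction `d = ±1`, speed `v`)
and immediately moves back, crossing the initial fixation location after
the *target crossing time* TX. Short TX (100 ms) evokes a mix of pure
pursuit and pursuit with **forward** catch-up saccades; long TX (240 ms)
evokes pursuit with **backward** saccades. The pipeline detects, per trial:

- **saccades** — samples where the direction-aligned eye velocity is at
  least twice the target speed (in either direction) with |acceleration| >
  300 cm/s²; onset at the start of the supra-threshold acceleration run,
  offset at the first sign change of the acceleration slope after the
  velocity peak;
- **pursuit onset** — first velocity rise above 2 SD of fixation velocity
  that stays above 30 % of target speed for 5 consecutive samples;
- **eye-crossing time** EX = (gaze − target position)/(gaze − target
  velocity), evaluated 100 ms before each saccade;
- **taps** — first hand sample < 5 mm from the screen, moving toward it,
  with orthogonal deceleration ≥ 50 cm/s² (online) or ≥ 25 cm/s² (offline).

Derived measures include the signed interception error (ahead of the
target positive, independent of motion direction), pre-tap hand and gaze
velocity (mean over 120–80 ms before the tap), and the *saccade effect*:
per participant and saccade class, the difference in a dependent variable
between saccade trials and pure-pursuit trials with identical targets,
averaged over the three target velocities. Hypothesis-driven contrasts
(forward > backward) use one-sided paired t-tests; pooled saccade-timing
contrasts use seeded percentile-bootstrap CIs.

A synthetic-data module generates gaze and hand recordings with known
ground truth (pursuit latency/gain, injected raised-cosine saccades,
blinks, a minimum-jerk reach whose endpoint is biased by a configurable
velocity misperception δ), so every stage is testable without human data.

## Worked example

```python
from stepramp.cli import run_pipeline

report = run_pipeline({
    "seed": 42, "out": "demo",
    "simulate": {"n_participants": 6, "repetitions": 2, "blocks": 1,
                 "tasks": ["judgment", "interception"], "delta": 0.05},
})
for t in report["tests"]:
    print(t["task"], t["dependent"], round(t["mean_forward"], 3),
          round(t["mean_backward"], 3), round(t["p"], 4))
```

prints (432 trials retained per task, no exclusions at default noise):

```
judgment judgment_p_fast 0.118 -0.166 0.0223
interception interception_error 0.069 -0.112 0.0015
interception hand_vel 0.14 -0.2 0.1496
```

With a 5 % velocity misperception tied to saccades, targets tracked with a
forward saccade are judged "fast" 12 points more often than pure-pursuit
trials and are tapped 0.069 cm further ahead; backward saccades show the
opposite bias (analytically δ·v·0.1 s ≈ ±0.075 cm at 15 cm/s). The
one-sided paired t-tests reject for judgments and interception errors.
The same run's pooled window analysis shows the forward-saccade effect is
larger when the saccade falls 100–200 ms before the tap (+0.109,
CI [0.037, 0.183]) than 200–300 ms before it (+0.065, CI [0.020, 0.107]).

The equivalent shell command is `stepramp run --seed 42 --out demo`;
`stepramp simulate | analyze | stats` expose the stages separately.

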