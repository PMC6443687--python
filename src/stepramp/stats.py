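"""Saccade-effect quantification and inferential statistics.

The central quantity is the saccade effect: for each participant and
saccade class, the difference between the mean of a dependent variable on
saccade trials and on pure-pursuit trials with identical targets (same
crossing time and velocity), averaged across the three target velocities.
Hypothesis-driven contrasts (forward saccades make targets look faster,
taps land further ahead, hands move faster) use one-sided paired t-tests;
everything else is two-sided.  Pooled time-window contrasts use seeded
percentile-bootstrap confidence intervals over trial resampling;
participant-level contrasts bootstrap over participants.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

DEPENDENTS = {
    "judgment_p_fast": "judgment",
    "interception_error": "interception_error",
    "hand_vel": "hand_vel_pre_tap",
}


class InsufficientDataError(ValueError):
    pass


def _cell_mean(df: pd.DataFrame, dependent: str) -> float:
    if dependent == "judgment_p_fast":
        return float((df["judgment"] == "fast").mean())
    return float(df[DEPENDENTS[dependent]].mean())


def _analysis_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Retained trials only; mixed-class trials are kept out of contrasts."""
    keep = ~trials["excluded"] & (trials["oculomotor_class"] != "mixed")
    return trials.loc[keep]


@dataclass
class EffectSummary:
    participant: int
    task: str
    saccade_class: str
    per_velocity: Dict[float, float]
    effect: float                      # mean of the existing per-velocity diffs

    @classmethod
    def build(cls, participant, task, saccade_class, per_velocity):
        diffs = [v for v in per_velocity.values() if np.isfinite(v)]
        return cls(
            participant=participant,
            task=task,
            saccade_class=saccade_class,
            per_velocity=per_velocity,
            effect=float(np.mean(diffs)) if diffs else np.nan,
        )


def saccade_effect(
    trials: pd.DataFrame,
    dependent: str,
    task: Optional[str] = None,
) -> pd.DataFrame:
    """Per participant x saccade class effect of corrective saccades.

    For every (TX, velocity) cell with both saccade and pure-pursuit trials
    the within-cell difference of means is computed; cells are averaged
    over TX within velocity and the per-velocity differences averaged into
    the participant's effect.  Cells with no pure-pursuit counterpart are
    dropped (with that velocity omitted from the average).
    """
    if dependent not in DEPENDENTS:
        raise ValueError(f"unknown dependent {dependent!r}")
    df = _analysis_frame(trials)
    if task is not None:
        df = df[df["task"] == task]
    rows = []
    for (p, t), dfp in df.groupby(["participant", "task"]):
        pursuit = dfp[dfp["oculomotor_class"] == "pure_pursuit"]
        for sclass in ("forward", "backward"):
            sacc = dfp[dfp["oculomotor_class"] == sclass]
            if sacc.empty:
                continue
            per_velocity: Dict[float, float] = {}
            for v, dfv in sacc.groupby("velocity"):
                cell_diffs = []
                for tx, dfc in dfv.groupby("tx"):
                    ref = pursuit[(pursuit["velocity"] == v) & (pursuit["tx"] == tx)]
                    if ref.empty:
                        continue
                    cell_diffs.append(
                        _cell_mean(dfc, dependent) - _cell_mean(ref, dependent)
                    )
                if cell_diffs:
                    per_velocity[float(v)] = float(np.mean(cell_diffs))
            if per_velocity:
                s = EffectSummary.build(p, t, sclass, per_velocity)
                rows.append(
                    {
                        "participant": s.participant,
                        "task": s.task,
                        "saccade_class": s.saccade_class,
                        "dependent": dependent,
                        "effect": s.effect,
                        **{f"v{v:g}": d for v, d in s.per_velocity.items()},
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    sided: str
    degenerate: bool = False


def paired_t(
    a: Sequence[float],
    b: Sequence[float],
    sided: str = "two",
) -> TTestResult:
    """Paired t-test, one- or two-sided.

    One-sided tests the fixed hypothesis mean(a - b) > 0 (e.g. forward
    effects exceed backward effects); the orientation is asserted by the
    caller's argument order, never inferred from the data.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise InsufficientDataError("need at least 2 pairs")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        return TTestResult(
            t=0.0 if d.mean() == 0 else np.inf * np.sign(d.mean()),
            df=df, p=np.nan, sided=sided, degenerate=True,
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = sps.t.sf(t, df) if sided == "one" else 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p), sided=sided)


def cross_participant_correlation(
    judgment_effects: Sequence[float],
    interception_effects: Sequence[float],
) -> Tuple[float, float]:
    """Pearson correlation (r, two-sided p) across participants."""
    x = np.asarray(judgment_effects, dtype=float)
    y = np.asarray(interception_effects, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("need >= 3 paired participant effects")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
    statistic=np.mean,
) -> Tuple[float, float]:
    """Seeded percentile bootstrap CI of a statistic of ``values``."""
    values = np.asarray(values, dtype=float)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boots = statistic(values[idx], axis=1)
    return (
        float(np.percentile(boots, 100 * alpha / 2)),
        float(np.percentile(boots, 100 * (1 - alpha / 2))),
    )


def _boot_diff_ci(
    x: np.ndarray, ref: np.ndarray, n_boot: int, rng: np.random.Generator,
    alpha: float = 0.05,
) -> Tuple[float, float]:
    """Percentile bootstrap CI of mean(x) - mean(ref), resampling trials."""
    ix = rng.integers(0, len(x), size=(n_boot, len(x)))
    ir = rng.integers(0, len(ref), size=(n_boot, len(ref)))
    boots = x[ix].mean(axis=1) - ref[ir].mean(axis=1)
    return (
        float(np.percentile(boots, 100 * alpha / 2)),
        float(np.percentile(boots, 100 * (1 - alpha / 2))),
    )


DEFAULT_WINDOWS: Tuple[Tuple[float, float], ...] = ((0.1, 0.2), (0.2, 0.3))
MIN_WINDOW_TRIALS = 5


def time_window_analysis(
    trials: pd.DataFrame,
    windows: Sequence[Tuple[float, float]] = DEFAULT_WINDOWS,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled saccade-timing contrast for the interception task.

    Saccade trials are selected by how long before the tap the saccade
    occurred and pooled across participants (individual cells would be too
    sparse); each window's mean error is compared with the pooled
    pure-pursuit mean, with a percentile bootstrap CI over trial
    resampling.  Windows with fewer than 5 trials are flagged unstable.
    """
    rng = np.random.default_rng(seed)
    df = _analysis_frame(trials)
    df = df[df["task"] == "interception"]
    pursuit = df[df["oculomotor_class"] == "pure_pursuit"]["interception_error"].dropna()
    rows = []
    for sclass in ("forward", "backward"):
        sacc = df[
            (df["oculomotor_class"] == sclass)
            & df["tap_time"].notna()
            & df["saccade_onset"].notna()
        ]
        lead = sacc["tap_time"] - sacc["saccade_onset"]
        for lo, hi in windows:
            sel = sacc.loc[(lead >= lo) & (lead < hi), "interception_error"].dropna()
            row = {
                "saccade_class": sclass,
                "window_lo": lo,
                "window_hi": hi,
                "n_trials": int(len(sel)),
                "unstable": len(sel) < MIN_WINDOW_TRIALS,
            }
            if len(sel) and len(pursuit):
                row["effect"] = float(sel.mean() - pursuit.mean())
                row["ci_lo"], row["ci_hi"] = _boot_diff_ci(
                    sel.to_numpy(), pursuit.to_numpy(), n_boot, rng
                )
            else:
                row["effect"] = np.nan
                row["ci_lo"] = row["ci_hi"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def mean_time_until_tap(trials: pd.DataFrame) -> Dict[Tuple[int, str], float]:
    """Per participant x saccade class mean tap time in the interception task."""
    df = _analysis_frame(trials)
    df = df[(df["task"] == "interception") & df["tap_time"].notna()]
    out: Dict[Tuple[int, str], float] = {}
    for (p, c), grp in df.groupby(["participant", "oculomotor_class"]):
        if c in ("forward", "backward"):
            out[(int(p), str(c))] = float(grp["tap_time"].mean())
    return out


def judgment_window_analysis(
    trials: pd.DataFrame,
    windows: Sequence[Tuple[float, float]] = DEFAULT_WINDOWS,
    n_boot: int = 2000,
    seed: int = 0,
    include_end_window: bool = True,
    end_window_s: float = 0.100,
) -> pd.DataFrame:
    """Saccade-timing contrast for judgment trials.

    There is no tap in the judgment task, so the windows are aligned on
    each participant's mean time-until-tap for the same saccade class in
    the interception task.  The per-participant effect is the difference in
    the probability of 'fast' responses between windowed saccade trials and
    that participant's pure-pursuit trials, averaged over velocities;
    confidence intervals bootstrap over participants.  An additional
    window covers saccades in the last 100 ms of the presentation.
    """
    rng = np.random.default_rng(seed)
    df = _analysis_frame(trials)
    jd = df[df["task"] == "judgment"]
    if jd.empty or not (jd["oculomotor_class"] != "pure_pursuit").any():
        return pd.DataFrame(
            columns=["saccade_class", "window", "n_participants", "effect",
                     "ci_lo", "ci_hi", "unstable"]
        )
    taps = mean_time_until_tap(trials)

    window_defs: List[Tuple[str, Optional[Tuple[float, float]]]] = [
        (f"{lo:g}-{hi:g}s_pre_tap", (lo, hi)) for lo, hi in windows
    ]
    if include_end_window:
        window_defs.append(("end_of_trial", None))

    rows = []
    for sclass in ("forward", "backward"):
        for name, win in window_defs:
            effects = []
            for p, dfp in jd.groupby("participant"):
                sacc = dfp[
                    (dfp["oculomotor_class"] == sclass) & dfp["saccade_onset"].notna()
                ]
                if win is not None:
                    anchor = taps.get((int(p), sclass))
                    if anchor is None:
                        continue
                    lo, hi = anchor - win[1], anchor - win[0]
                    sacc = sacc[(sacc["saccade_onset"] >= lo) & (sacc["saccade_onset"] < hi)]
                else:
                    sacc = sacc[sacc["saccade_onset"] >= sacc["duration"] - end_window_s]
                pursuit = dfp[dfp["oculomotor_class"] == "pure_pursuit"]
                if sacc.empty or pursuit.empty:
                    continue
                per_v = []
                for v, dfv in sacc.groupby("velocity"):
                    ref = pursuit[pursuit["velocity"] == v]
                    if ref.empty:
                        continue
                    per_v.append(
                        (dfv["judgment"] == "fast").mean()
                        - (ref["judgment"] == "fast").mean()
                    )
                if per_v:
                    effects.append(float(np.mean(per_v)))
            row = {
                "saccade_class": sclass,
                "window": name,
                "n_participants": len(effects),
                "unstable": len(effects) < MIN_WINDOW_TRIALS,
            }
            if effects:
                arr = np.asarray(effects)
                row["effect"] = float(arr.mean())
                if len(arr) > 1:
                    row["ci_lo"], row["ci_hi"] = bootstrap_ci(arr, n_boot, rng)
                else:
                    row["ci_lo"] = row["ci_hi"] = row["effect"]
            else:
                row["effect"] = row["ci_lo"] = row["ci_hi"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def effect_tests(trials: pd.DataFrame) -> pd.DataFrame:
    """Forward-vs-backward saccade-effect tests for each dependent variable.

    One-sided for the hypothesis-driven dependents (judgment speed,
    interception error, hand velocity: forward > backward).
    """
    rows = []
    for task, dependent in (
        ("judgment", "judgment_p_fast"),
        ("interception", "interception_error"),
        ("interception", "hand_vel"),
    ):
        eff = saccade_effect(trials, dependent, task=task)
        if eff.empty:
            continue
        wide = eff.pivot_table(
            index="participant", columns="saccade_class", values="effect"
        )
        if not {"forward", "backward"} <= set(wide.columns):
            continue
        paired = wide.dropna(subset=["forward", "backward"])
        if len(paired) < 2:
            continue
        res = paired_t(paired["forward"], paired["backward"], sided="one")
        rows.append(
            {
                "task": task,
                "dependent": dependent,
                "n": len(paired),
                "mean_forward": float(paired["forward"].mean()),
                "mean_backward": float(paired["backward"].mean()),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "sided": res.sided,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
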