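"""File formats: recordings, trial metadata, datasets, manifests.

Recordings are plain CSV with a ``time_s`` column plus ``x_cm`` (gaze) or
``x_cm,y_cm,z_cm`` (hand); missing samples (blinks, dropouts) are empty
fields.  A dataset directory holds ``trials.csv`` (one row per trial),
``recordings/<trial_id>_{gaze,hand}.csv``, an optional ``ground_truth.json``
sidecar and a ``manifest.json`` with seeds, package version and SHA-256
hashes of every file.
"""
from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .preprocessing import FormatError, Recording
from .synthetic import SimulatedTrial
from .trial_design import TrialDesign

_FLOAT_FMT = "%.12g"   # lossless for the 1e-9 round-trip contract


def write_recording(rec: Recording, path) -> None:
    path = Path(path)
    header = ["time_s", "x_cm"] if rec.pos.ndim == 1 else ["time_s", "x_cm", "y_cm", "z_cm"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for i, t in enumerate(rec.times):
            row = [_FLOAT_FMT % t]
            vals = [rec.pos[i]] if rec.pos.ndim == 1 else list(rec.pos[i])
            if rec.missing[i]:
                row += [""] * len(vals)
            else:
                row += [_FLOAT_FMT % v for v in vals]
            w.writerow(row)


def read_recording(path, source: Optional[str] = None) -> Recording:
    """Read a recording CSV; raises :class:`FormatError` on bad timestamps."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[0] != "time_s" or header[1] != "x_cm":
            raise FormatError(f"{path}: unexpected header {header}")
        ncol = len(header) - 1
        times, pos, missing = [], [], []
        for row in reader:
            times.append(float(row[0]))
            if any(cell == "" for cell in row[1:]):
                missing.append(True)
                pos.append([np.nan] * ncol)
            else:
                missing.append(False)
                pos.append([float(c) for c in row[1:]])
    times = np.asarray(times)
    if len(times) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(times)
    rate = 1.0 / np.median(dt)
    bad = np.nonzero(np.abs(dt - 1.0 / rate) > 1e-6)[0]
    if bad.size:
        raise FormatError(
            f"{path}: gap in timestamps at row {int(bad[0]) + 2} "
            f"(dt={dt[bad[0]]:.6g} s, expected {1.0 / rate:.6g} s)"
        )
    arr = np.asarray(pos)
    if ncol == 1:
        arr = arr[:, 0]
    if source is None:
        source = "gaze" if ncol == 1 else "hand"
    return Recording(
        times=times, pos=arr, rate=float(round(rate, 6)), source=source,
        missing=np.asarray(missing, dtype=bool),
    )


def _design_row(trial_id: str, participant: int, design: TrialDesign,
                judgment: Optional[str], seed) -> dict:
    return {
        "trial_id": trial_id,
        "participant": participant,
        "task": design.task,
        "velocity_cm_s": design.velocity,
        "tx_s": design.tx,
        "direction": design.direction,
        "duration_s": design.duration,
        "step_cm": design.step,
        "judgment": judgment or "",
        "seed": seed,
    }


def _truth_dict(trial: SimulatedTrial) -> dict:
    t = trial.truth
    return {
        "pursuit_onset": t.pursuit_onset,
        "saccade_onset": t.saccade_onset,
        "saccade_offset": t.saccade_offset,
        "saccade_amplitude": t.saccade_amplitude,
        "saccade_class": t.saccade_class,
        "tap_time": t.tap_time,
        "tap_pos": list(t.tap_pos) if t.tap_pos else None,
        "velocity_bias": t.velocity_bias,
    }


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(trials: Sequence[SimulatedTrial], out_dir, seed: int) -> Path:
    """Write a simulated cohort as a self-describing dataset directory."""
    out = Path(out_dir)
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    rows, truth = [], {}
    for trial in trials:
        rows.append(_design_row(
            trial.trial_id, trial.participant, trial.design, trial.judgment, seed
        ))
        write_recording(trial.gaze, rec_dir / f"{trial.trial_id}_gaze.csv")
        if trial.hand is not None:
            write_recording(trial.hand, rec_dir / f"{trial.trial_id}_hand.csv")
        truth[trial.trial_id] = _truth_dict(trial)
    pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    files = sorted(
        str(p.relative_to(out)) for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": seed,
        "n_trials": len(trials),
        "files": {f: sha256_of(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


class DataError(ValueError):
    pass


def load_dataset(path) -> List[dict]:
    """Load a dataset directory into per-trial records.

    Each record holds trial_id, participant, design, judgment, gaze and
    (optionally) hand Recording plus the ground-truth dict when present.
    Fails fast with the missing file names if recordings and metadata
    disagree.
    """
    path = Path(path)
    meta = pd.read_csv(path / "trials.csv", keep_default_na=False)
    truth = {}
    gt = path / "ground_truth.json"
    if gt.exists():
        truth = json.loads(gt.read_text())
    missing_files = []
    records = []
    for _, row in meta.iterrows():
        tid = row["trial_id"]
        gaze_path = path / "recordings" / f"{tid}_gaze.csv"
        if not gaze_path.exists():
            missing_files.append(str(gaze_path))
            continue
        design = TrialDesign(
            velocity=float(row["velocity_cm_s"]),
            tx=float(row["tx_s"]),
            direction=int(row["direction"]),
            duration=float(row["duration_s"]),
            task=row["task"],
        )
        rec = {
            "trial_id": tid,
            "participant": int(row["participant"]),
            "design": design,
            "judgment": row["judgment"] or None,
            "gaze": read_recording(gaze_path, "gaze"),
            "hand": None,
            "truth": truth.get(tid),
        }
        hand_path = path / "recordings" / f"{tid}_hand.csv"
        if hand_path.exists():
            rec["hand"] = read_recording(hand_path, "hand")
        records.append(rec)
    if missing_files:
        raise DataError(
            "dataset inconsistent; missing recordings: " + ", ".join(missing_files[:5])
        )
    return records
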