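"""Analysis configuration.

Every threshold used anywhere in the pipeline lives here, so that analysis
code contains no numeric literals and a full run is reproducible from a
single config file.  The defaults are the values used in the step-ramp
tracking-and-interception protocol this package analyses.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows for preprocessing, event detection and measures.

    Units are cm, s, Hz throughout (positions are measured on the screen;
    the recording rig reports screen coordinates rather than visual angle).
    """

    # -- preprocessing -------------------------------------------------
    position_cutoff_hz: float = 30.0      # zero-phase low-pass on position
    interp_cutoff_hz: float = 20.0        # second-stage velocity filter
    filter_order: int = 2                 # applied forward-backward
    acc_half_window_s: float = 0.010      # +/-10 ms velocity difference
    drift_window_s: Tuple[float, float] = (-0.15, -0.05)
    # 100 ms preceding fixation-point offset; the fixation point disappears
    # 50 ms before target motion onset (t = 0).

    # -- saccade detection ---------------------------------------------
    saccade_velocity_factor: float = 2.0  # x target speed, either direction
    saccade_acc_threshold: float = 300.0  # cm/s^2
    saccade_merge_gap_s: float = 0.020    # candidates closer than this merge
    saccade_min_duration_s: float = 0.010
    saccade_max_duration_s: float = 0.100

    # -- pursuit onset --------------------------------------------------
    pursuit_sd_factor: float = 2.0        # x fixation velocity SD
    pursuit_fraction: float = 0.30        # of target speed
    pursuit_consecutive: int = 5          # consecutive samples above fraction
    baseline_window_s: Tuple[float, float] = (-0.05, 0.05)

    # -- eye-crossing time ----------------------------------------------
    ex_lead_s: float = 0.100              # evaluated this long before onset
    ex_slip_epsilon: float = 0.5          # cm/s; below this EX is undefined

    # -- tap detection ---------------------------------------------------
    tap_decel_online: float = 50.0        # cm/s^2 orthogonal to screen
    tap_decel_offline: float = 25.0
    tap_height_cm: float = 0.5            # finger must be below 5 mm
    tap_lift_cm: float = 1.0              # must have lifted this much (online)

    # -- derived measures -------------------------------------------------
    pre_tap_window_s: Tuple[float, float] = (0.08, 0.12)  # before the tap
    extrapolation_span_s: float = 0.100

    # -- exclusion rules ---------------------------------------------------
    min_pursuit_latency_s: float = 0.050
    post_saccade_error_max_cm: float = 5.0
    post_saccade_eval_delay_s: float = 0.010
    tap_distance_max_cm: float = 3.0

    # -- trial timeline -----------------------------------------------------
    fixation_duration_s: float = 0.600
    gap_duration_s: float = 0.050

    @property
    def pre_roll_s(self) -> float:
        """Recording time before target motion onset (fixation + gap)."""
        return self.fixation_duration_s + self.gap_duration_s

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


DEFAULT_CONFIG = AnalysisConfig()
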