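"""Waveform feature extraction for long-flash (On-Off) ERGs.

Measurements follow the usual clinical conventions on baseline-corrected
waveforms: the a-wave is the cornea-negative trough early after flash
onset (amplitude measured baseline-to-trough), the b-wave the following
cornea-positive peak (measured a-trough-to-peak by default), and the
d-wave the positive deflection after flash offset.  The *drift* is the
absolute amplitude change between the b-wave peak and the level at flash
cessation, immediately before the Off-response — a measure of the
sustained negativity that develops during the flash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ERGRecording
from .errors import ValidationError


@dataclass(frozen=True)
class FeatureWindows:
    """Search-window policy for feature extraction.

    a_window_ms        a-trough searched in [onset, onset + a_window_ms]
    cessation_ms       flash-cessation level = mean over this many ms,
                       ending one sample before flash offset
    d_window_ms        d-peak searched in [offset, offset + d_window_ms]
    ratio_floor_uv     ratios are undefined (NaN) when the denominator
                       amplitude is below this floor
    b_convention       "trough_to_peak" (default) or "baseline_to_peak"
    """

    a_window_ms: float = 50.0
    cessation_ms: float = 5.0
    d_window_ms: float = 50.0
    ratio_floor_uv: float = 1.0
    b_convention: str = "trough_to_peak"

    def __post_init__(self) -> None:
        if self.b_convention not in ("trough_to_peak", "baseline_to_peak"):
            raise ValidationError(f"unknown b_convention {self.b_convention!r}")


@dataclass(frozen=True)
class WaveformFeatures:
    """Extracted amplitudes (µV, all >= 0), peak times (ms after onset) and ratios."""

    a_amplitude: float
    a_time: float
    b_amplitude: float
    b_time: float
    d_amplitude: float
    drift: float
    b_a_ratio: float  # NaN when a_amplitude below the ratio floor
    drift_b_ratio: float  # NaN when b_amplitude below the ratio floor
    a_wave_absent: bool = False


def _window_slice(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def extract_features(
    recording: ERGRecording, windows: FeatureWindows = FeatureWindows()
) -> WaveformFeatures:
    """Measure a-, b-, d-wave, drift and ratios on one waveform.

    The recording must be baseline-corrected and contain the whole flash
    plus ``d_window_ms`` beyond the offset.  Ties between equal extrema
    resolve to the earliest time.  When no deflection falls below zero
    in the a-window the a-wave is reported absent (amplitude 0, time 0)
    and the b-peak search starts at flash onset.
    """
    if not recording.baseline_corrected:
        raise ValidationError("extract_features requires a baseline-corrected recording")
    t = recording.times
    y = recording.amplitudes
    onset = recording.condition.flash_onset
    offset = recording.condition.flash_offset
    dt = recording.dt
    if offset + windows.d_window_ms > t[-1] + 1e-9:
        raise ValidationError(
            f"d-wave window ends at {offset + windows.d_window_ms} ms, beyond the "
            f"recording ({t[-1]} ms)"
        )

    # a-wave: minimum within the a-window after onset
    a_mask = _window_slice(t, onset, onset + windows.a_window_ms)
    a_idx = int(np.argmin(y[a_mask]))
    a_val = float(y[a_mask][a_idx])
    if a_val >= 0.0:
        a_absent = True
        a_amplitude, a_time_abs, a_val = 0.0, onset, 0.0
    else:
        a_absent = False
        a_amplitude = -a_val
        a_time_abs = float(t[a_mask][a_idx])

    # b-wave: maximum between the a-trough (or onset) and flash offset
    b_mask = _window_slice(t, a_time_abs, offset)
    b_idx = int(np.argmax(y[b_mask]))
    b_val = float(y[b_mask][b_idx])
    b_time_abs = float(t[b_mask][b_idx])
    if windows.b_convention == "trough_to_peak":
        b_amplitude = max(b_val - a_val, 0.0)
    else:
        b_amplitude = max(b_val, 0.0)

    # flash-cessation level: mean over the last cessation_ms, ending one
    # sample before offset ("immediately prior to the Off-response")
    c_hi = offset - dt
    c_mask = _window_slice(t, c_hi - windows.cessation_ms + dt, c_hi)
    if not np.any(c_mask):
        raise ValidationError("cessation window contains no samples")
    cessation = float(y[c_mask].mean())
    drift = abs(b_val - cessation)

    # d-wave: positive Off-deflection relative to the cessation level
    d_mask = _window_slice(t, offset, offset + windows.d_window_ms)
    d_val = float(np.max(y[d_mask]))
    d_amplitude = max(d_val - cessation, 0.0)

    floor = windows.ratio_floor_uv
    b_a = b_amplitude / a_amplitude if a_amplitude >= floor else math.nan
    drift_b = drift / b_amplitude if b_amplitude >= floor else math.nan

    return WaveformFeatures(
        a_amplitude=a_amplitude,
        a_time=a_time_abs - onset,
        b_amplitude=b_amplitude,
        b_time=b_time_abs - onset,
        d_amplitude=d_amplitude,
        drift=drift,
        b_a_ratio=b_a,
        drift_b_ratio=drift_b,
        a_wave_absent=a_absent,
    )


FEATURE_NAMES = [
    "a_amplitude",
    "a_time",
    "b_amplitude",
    "b_time",
    "d_amplitude",
    "drift",
    "b_a_ratio",
    "drift_b_ratio",
]


def features_to_frame(
    features: Mapping[tuple[str, float, float], WaveformFeatures]
) -> pd.DataFrame:
    """One row per recording, keyed by (subject, background, stimulus)."""
    rows = []
    for (sid, bg, stim), f in features.items():
        row = {"subject_id": sid, "background_cdm2": bg, "stimulus_cdm2": stim}
        row.update({name: getattr(f, name) for name in FEATURE_NAMES})
        row["a_wave_absent"] = f.a_wave_absent
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["subject_id", "background_cdm2", "stimulus_cdm2"], ignore_index=True
    )


def summarize_cohort(
    features: Mapping[tuple[str, float, float], WaveformFeatures] | pd.DataFrame
) -> pd.DataFrame:
    """Per-condition summary table: mean, SD (n-1) and n of every feature.

    Undefined (NaN) ratios are excluded from that cell's n; single-subject
    cells report SD 0 with n = 1 flagging the degenerate estimate.
    Output columns: background_cdm2, stimulus_cdm2, feature, mean, sd, n.
    """
    if isinstance(features, pd.DataFrame):
        df = features
    else:
        if len(features) == 0:
            raise ValidationError("summarize_cohort needs at least one recording")
        df = features_to_frame(features)
    if df.empty:
        raise ValidationError("summarize_cohort needs at least one recording")
    long = df.melt(
        id_vars=["background_cdm2", "stimulus_cdm2"],
        value_vars=FEATURE_NAMES,
        var_name="feature",
    ).dropna(subset=["value"])
    out = (
        long.groupby(["background_cdm2", "stimulus_cdm2", "feature"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out
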