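"""Core data model for full-field ERG recordings.

A recording is a single averaged waveform (time in ms, amplitude in µV)
tagged with its stimulus condition: background luminance, stimulus
luminance (both cd/m²) and the flash timing on the recording's time base.
Sign convention: cornea-negative deflections are negative, so the a-wave
trough is a minimum.

The on-disk format is a long-format CSV, one row per sample, with columns
``subject_id, background_cdm2, stimulus_cdm2, flash_duration_ms,
flash_onset_ms, time_ms, amplitude_uv``.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Column order of the long-format recording CSV.
CSV_COLUMNS = [
    "subject_id",
    "background_cdm2",
    "stimulus_cdm2",
    "flash_duration_ms",
    "flash_onset_ms",
    "time_ms",
    "amplitude_uv",
]

#: Tolerance (ms) for declaring the sampling grid uniform.
SPACING_TOL_MS = 1e-6

#: Default pre-stimulus segment length (ms) preceding flash onset.
DEFAULT_FLASH_ONSET_MS = 10.0

#: Default sampling interval (ms).
DEFAULT_DT_MS = 0.5


@dataclass(frozen=True)
class StimulusCondition:
    """One step of a long-flash protocol.

    Parameters
    ----------
    background_luminance : float
        Steady background luminance in cd/m² (>= 0; 0 means scotopic).
    stimulus_luminance : float
        Flash luminance in cd/m² (> 0).
    flash_duration : float
        Flash duration in ms (> 0).
    flash_onset : float
        Time of flash onset on the recording's time base, in ms (>= 0).
    """

    background_luminance: float
    stimulus_luminance: float
    flash_duration: float = 250.0
    flash_onset: float = DEFAULT_FLASH_ONSET_MS

    def __post_init__(self) -> None:
        if not math.isfinite(self.background_luminance) or self.background_luminance < 0:
            raise ValidationError(
                f"background_luminance must be finite and >= 0, got {self.background_luminance}"
            )
        if not math.isfinite(self.stimulus_luminance) or self.stimulus_luminance <= 0:
            raise ValidationError(
                f"stimulus_luminance must be finite and > 0, got {self.stimulus_luminance}"
            )
        if not math.isfinite(self.flash_duration) or self.flash_duration <= 0:
            raise ValidationError(f"flash_duration must be > 0 ms, got {self.flash_duration}")
        if not math.isfinite(self.flash_onset) or self.flash_onset < 0:
            raise ValidationError(f"flash_onset must be >= 0 ms, got {self.flash_onset}")

    @property
    def flash_offset(self) -> float:
        """Time of flash cessation on the recording time base (ms)."""
        return self.flash_onset + self.flash_duration


@dataclass
class ERGRecording:
    """One averaged ERG waveform under a single stimulus condition.

    ``times`` (ms) must be strictly increasing and uniformly spaced;
    ``amplitudes`` (µV) has the same length.  The flash must end before
    the recording does.
    """

    subject_id: str
    times: np.ndarray
    amplitudes: np.ndarray
    condition: StimulusCondition
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1 or self.amplitudes.ndim != 1:
            raise ValidationError("times and amplitudes must be 1-D")
        if len(self.times) != len(self.amplitudes):
            raise ValidationError(
                f"length mismatch: {len(self.times)} times vs {len(self.amplitudes)} amplitudes"
            )
        if len(self.times) < 2:
            raise ValidationError("a recording needs at least 2 samples")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            raise ValidationError(f"times must be strictly increasing ({self.key})")
        if np.ptp(diffs) > SPACING_TOL_MS:
            raise ValidationError(f"non-uniform sampling interval ({self.key})")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValidationError(f"non-finite amplitude in recording {self.key}")
        if self.condition.flash_offset >= self.times[-1]:
            raise ValidationError(
                f"flash (ends {self.condition.flash_offset} ms) must end before the "
                f"recording does ({self.times[-1]} ms) ({self.key})"
            )

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return float(self.times[1] - self.times[0])

    @property
    def key(self) -> tuple[str, float, float]:
        """(subject_id, background, stimulus) identifier."""
        return (
            self.subject_id,
            self.condition.background_luminance,
            self.condition.stimulus_luminance,
        )

    def with_amplitudes(self, amplitudes: np.ndarray, *, baseline_corrected: bool | None = None) -> "ERGRecording":
        """Copy of this recording with new amplitudes."""
        return ERGRecording(
            subject_id=self.subject_id,
            times=self.times.copy(),
            amplitudes=np.asarray(amplitudes, dtype=float),
            condition=self.condition,
            baseline_corrected=self.baseline_corrected
            if baseline_corrected is None
            else baseline_corrected,
        )


@dataclass
class Protocol:
    """Ordered list of stimulus conditions, one flash per step."""

    steps: list[StimulusCondition]
    inter_flash_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("a protocol needs at least one step")
        if self.inter_flash_interval_s <= 0:
            raise ValidationError("inter_flash_interval_s must be > 0")
        keys = [(s.background_luminance, s.stimulus_luminance) for s in self.steps]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (background, stimulus) pair in protocol")
        if keys != sorted(keys):
            raise ValidationError("protocol steps must be ordered by (background, stimulus)")

    @property
    def backgrounds(self) -> list[float]:
        seen: list[float] = []
        for s in self.steps:
            if s.background_luminance not in seen:
                seen.append(s.background_luminance)
        return seen

    @property
    def stimuli(self) -> list[float]:
        seen: list[float] = []
        for s in self.steps:
            if s.stimulus_luminance not in seen:
                seen.append(s.stimulus_luminance)
        return seen

    def to_json(self) -> str:
        return json.dumps(
            {
                "backgrounds_cdm2": self.backgrounds,
                "stimuli_cdm2": self.stimuli,
                "flash_duration_ms": self.steps[0].flash_duration,
                "flash_onset_ms": self.steps[0].flash_onset,
                "interval_s": self.inter_flash_interval_s,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Protocol":
        doc = json.loads(text)
        return build_protocol(
            doc["backgrounds_cdm2"],
            doc["stimuli_cdm2"],
            flash_duration=doc.get("flash_duration_ms", 250.0),
            interval_s=doc.get("interval_s", 1.0),
            flash_onset=doc.get("flash_onset_ms", DEFAULT_FLASH_ONSET_MS),
        )


def build_protocol(
    backgrounds: Sequence[float],
    stimuli: Sequence[float],
    flash_duration: float = 250.0,
    interval_s: float = 1.0,
    flash_onset: float = DEFAULT_FLASH_ONSET_MS,
) -> Protocol:
    """Build the full background × stimulus protocol grid.

    One step per (background, stimulus) pair, ordered by background then
    stimulus ascending; the step count is ``len(backgrounds) * len(stimuli)``.
    """
    if len(backgrounds) == 0 or len(stimuli) == 0:
        raise ValidationError("backgrounds and stimuli must be non-empty")
    steps = [
        StimulusCondition(
            background_luminance=float(b),
            stimulus_luminance=float(s),
            flash_duration=float(flash_duration),
            flash_onset=float(flash_onset),
        )
        for b in sorted(backgrounds)
        for s in sorted(stimuli)
    ]
    return Protocol(steps=steps, inter_flash_interval_s=float(interval_s))


def write_recordings(recordings: Iterable[ERGRecording], dest=None) -> str | None:
    """Write recordings as a long-format CSV.

    ``dest`` may be a path or an open text handle; if omitted, the CSV
    text is returned.  Numeric fields are written at full float precision
    so the read/write round trip is lossless to well below 1e-9 µV.
    """
    frames = []
    for rec in recordings:
        n = len(rec.times)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [rec.subject_id] * n,
                    "background_cdm2": rec.condition.background_luminance,
                    "stimulus_cdm2": rec.condition.stimulus_luminance,
                    "flash_duration_ms": rec.condition.flash_duration,
                    "flash_onset_ms": rec.condition.flash_onset,
                    "time_ms": rec.times,
                    "amplitude_uv": rec.amplitudes,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)[CSV_COLUMNS]
    else:
        df = pd.DataFrame(columns=CSV_COLUMNS)
    text = df.to_csv(index=False, float_format="%.17g")
    if dest is None:
        return text
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
    return None


def read_recordings(source) -> list[ERGRecording]:
    """Read recordings from a long-format CSV (path, handle, or text).

    Rows are grouped into one recording per (subject, background,
    stimulus); each group's time base is validated (strictly increasing,
    uniform spacing, no duplicates).  Missing columns or a malformed time
    base raise :class:`SchemaError` naming the offender.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    recordings: list[ERGRecording] = []
    for (sid, bg, stim), grp in df.groupby(
        ["subject_id", "background_cdm2", "stimulus_cdm2"], sort=True
    ):
        key = f"subject={sid} background={bg} stimulus={stim}"
        times = grp["time_ms"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise SchemaError(f"duplicate time points in recording {key}")
        if not np.all(np.diff(times) > 0):
            raise SchemaError(f"time not sorted/strictly increasing in recording {key}")
        if len(times) >= 2 and np.ptp(np.diff(times)) > SPACING_TOL_MS:
            raise SchemaError(f"non-uniform time spacing in recording {key}")
        dur = grp["flash_duration_ms"].iloc[0]
        onset = grp["flash_onset_ms"].iloc[0]
        try:
            cond = StimulusCondition(
                background_luminance=float(bg),
                stimulus_luminance=float(stim),
                flash_duration=float(dur),
                flash_onset=float(onset),
            )
            recordings.append(
                ERGRecording(
                    subject_id=str(sid),
                    times=times,
                    amplitudes=grp["amplitude_uv"].to_numpy(dtype=float),
                    condition=cond,
                )
            )
        except ValidationError as exc:
            raise SchemaError(f"invalid recording {key}: {exc}") from exc
    return recordings


def baseline_correct(
    recording: ERGRecording, window: tuple[float, float] | None = None
) -> ERGRecording:
    """Subtract the mean pre-stimulus amplitude from the whole waveform.

    ``window`` is a (start, end) interval in ms on the recording time
    base and must lie entirely before flash onset and contain at least
    one sample; the default is the full pre-stimulus segment.  The
    operation is idempotent on already-corrected input.
    """
    onset = recording.condition.flash_onset
    if window is None:
        window = (float(recording.times[0]), onset)
    start, end = window
    if start < recording.times[0] - SPACING_TOL_MS or end > onset + SPACING_TOL_MS:
        raise ValidationError(
            f"baseline window [{start}, {end}] must lie within the recording and "
            f"before flash onset ({onset} ms)"
        )
    mask = (recording.times >= start) & (recording.times < end + SPACING_TOL_MS)
    # include the onset sample itself only if the window ends exactly at onset
    mask &= recording.times < onset
    if not np.any(mask):
        raise ValidationError("baseline window contains no samples")
    mean = float(recording.amplitudes[mask].mean())
    return recording.with_amplitudes(recording.amplitudes - mean, baseline_corrected=True)
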