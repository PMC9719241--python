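"""PII isolation: subtract the modeled PIII from rod-only waveforms.

With the Birch-Hood parameters fitted to the a-wave leading edge, the
full rod PIII time course is reconstructed (the saturating response held
at its plateau for the flash duration) and subtracted from the
photopically subtracted waveform, leaving the postreceptoral PII
component.  The isolated PII is then quantified by its peak amplitude,
peak time and width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ERGRecording, StimulusCondition
from .errors import FitError, ValidationError
from .piii import FitResult, PIIIParams, birch_hood_response


@dataclass
class TimeSeries:
    """A plain (times ms, values µV) pair on the recording time base."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have the same shape")


def model_piii_waveform(
    params: PIIIParams,
    condition: StimulusCondition,
    times: np.ndarray,
    recovery_ms: float = 40.0,
) -> TimeSeries:
    """Reconstruct the full (cornea-negative) PIII time course.

    Zero before flash onset; the negated Birch-Hood response during the
    flash, holding its saturated plateau; after offset a linear return
    to baseline over ``recovery_ms`` (unused when the isolation window
    ends at offset, the default).
    """
    times = np.asarray(times, dtype=float)
    s = times - condition.flash_onset
    dev = np.clip(s, 0.0, condition.flash_duration)
    resp = birch_hood_response(condition.stimulus_luminance, dev, params)
    ramp = np.clip(1.0 - (s - condition.flash_duration) / recovery_ms, 0.0, 1.0)
    return TimeSeries(times=times, values=-resp * ramp)


def isolate_pii(
    rod_waveform: ERGRecording,
    fit: FitResult | PIIIParams,
    window: tuple[float, float] | None = None,
    force: bool = False,
) -> TimeSeries:
    """Subtract the modeled PIII from a rod-only waveform.

    ``window`` is (start, end) on the recording time base; the default
    runs from flash onset to flash offset (the On-phase).  An
    unconverged fit raises unless ``force=True``.
    """
    if isinstance(fit, FitResult):
        if not fit.converged and not force:
            raise FitError("PIII fit did not converge; pass force=True to isolate anyway")
        params = fit.params
    else:
        params = fit
    if not rod_waveform.baseline_corrected:
        raise ValidationError("rod waveform must be baseline-corrected")
    cond = rod_waveform.condition
    if window is None:
        window = (cond.flash_onset, cond.flash_offset)
    lo, hi = window
    mask = (rod_waveform.times >= lo - 1e-9) & (rod_waveform.times <= hi + 1e-9)
    if not np.any(mask):
        raise ValidationError("isolation window contains no samples")
    times = rod_waveform.times[mask]
    model = model_piii_waveform(params, cond, times)
    return TimeSeries(times=times, values=rod_waveform.amplitudes[mask] - model.values)


@dataclass(frozen=True)
class PIIMetrics:
    """Summary of an isolated PII response.

    peak_amplitude : µV (maximum value; 0-with-flag on an all-zero input)
    peak_time      : ms after flash onset (earliest tied maximum)
    width          : ms the response spends above 5% of its peak, from
                     the first crossing to the return below threshold
    residual_drift : µV, |mean amplitude over the last 5 ms before flash
                     offset| — the residual deviation from baseline at
                     flash cessation (≈0 when the isolated PII has fully
                     returned to baseline, i.e. the sustained negativity
                     has been removed with the PIII)
    """

    peak_amplitude: float
    peak_time: float
    width: float
    residual_drift: float
    is_flat: bool = False


def pii_metrics(
    isolated: TimeSeries,
    condition: StimulusCondition,
    width_threshold: float = 0.05,
    cessation_ms: float = 5.0,
) -> PIIMetrics:
    """Quantify an isolated PII time series.

    ``condition`` supplies the flash timing used for peak time (relative
    to onset) and the cessation window of ``residual_drift``.
    """
    t = isolated.times
    v = isolated.values
    if len(t) == 0:
        raise ValidationError("empty isolation window")
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0

    offset = condition.flash_offset
    c_mask = (t >= offset - cessation_ms - dt + 1e-9) & (t <= offset - dt + 1e-9)
    residual = abs(float(v[c_mask].mean())) if np.any(c_mask) else abs(float(v[-1]))

    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    if peak <= 0 or np.max(np.abs(v)) < 1e-12:
        return PIIMetrics(0.0, 0.0, 0.0, residual, is_flat=True)
    peak_time = float(t[peak_idx] - condition.flash_onset)

    thr = width_threshold * peak
    above = v >= thr
    first = int(np.argmax(above))
    after_peak = np.nonzero(~above[peak_idx:])[0]
    last = peak_idx + int(after_peak[0]) if len(after_peak) else len(v) - 1
    width = float(t[last] - t[first])
    return PIIMetrics(
        peak_amplitude=peak,
        peak_time=peak_time,
        width=width,
        residual_drift=residual,
    )
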