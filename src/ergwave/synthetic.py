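"""Synthetic long-flash ERG cohort generator.

Each simulated waveform is the sum of three noise-free components plus
i.i.d. Gaussian noise:

* **rod PIII** — the negated Birch–Hood saturating response, held for
  the flash duration and ramped back to baseline after offset;
* **rod-driven PII** — a cornea-positive gamma-kernel transient with an
  optional sustained plateau until flash offset (the b-wave generator);
* **cone On/Off terms** — small fast a/b deflections during the flash
  and a biphasic Off-response at flash cessation (positive d-deflection
  followed by a dominant negativity, the E-type configuration).

Light adaptation is Weber-like: each rod gain g declines with background
luminance B as ``g(B) = g_dark / (1 + B / B_half)``, with the PII gain
half-saturating at a much dimmer background than the PIII amplitude
(rod bipolar signalling saturates before the photoreceptor response).
The PIII sensitivity S adapts the same way with its own half-saturation
constant.  Backgrounds at or above ``rod_suppression_background``
silence the rod components entirely, so the photopic response is purely
cone-driven and photopic subtraction removes the cone terms exactly.
Cone gains are background-independent.

The whole cohort is a deterministic function of the config seed:
per-subject multiplicative gains are drawn first (lognormal, unit mean),
then per-recording noise in protocol order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import ERGRecording, Protocol, StimulusCondition
from .errors import ValidationError
from .piii import PIIIParams, birch_hood_response

#: Post-offset recovery ramp applied to sustained components (ms).
RECOVERY_MS = 40.0

#: Default post-flash tail recorded beyond the Off-response window (ms).
POST_FLASH_MS = 60.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth configuration of the synthetic cohort.

    Default values are arbitrary but physiologically plausible for a
    rod-dominated retina recorded at canine amplitudes; they are chosen
    to reproduce the qualitative mesopic regime (large scotopic b-wave,
    b:a crossover near 1 cd/m² background, sustained mesopic negativity)
    rather than any published amplitude table.
    """

    piii_params_dark: PIIIParams = field(
        default_factory=lambda: PIIIParams(r_max=150.0, s=0.008, t_d=4.0)
    )
    #: background at which the rod PIII amplitude halves (cd/m²)
    piii_background_half: float = 2.0
    #: background at which the PIII sensitivity S halves (cd/m²)
    s_background_half: float = 0.05
    pii_gain_dark: float = 300.0
    #: background at which the PII gain halves (cd/m²)
    pii_background_half: float = 0.15
    pii_time_to_peak: float = 60.0
    pii_shape: float = 4.0
    pii_plateau_fraction: float = 0.1
    cone_a_gain: float = 8.0
    cone_b_gain: float = 15.0
    cone_d_gain: float = 10.0
    offset_negative_gain: float = 15.0
    #: stimulus luminance at which cone gains half-saturate (cd/m²)
    cone_semisaturation: float = 100.0
    #: rods are fully suppressed at or above this background (cd/m²)
    rod_suppression_background: float = 30.0
    #: extra PIII integration beyond flash offset (ms); 0 for long
    #: flashes (PIII returns to baseline at offset), > 0 emulates the
    #: continued photoresponse development after a brief flash
    piii_integration_ms: float = 0.0
    noise_sd: float = 3.0
    n_subjects: int = 6
    subject_gain_cv: float = 0.15
    seed: int = 0
    dt_ms: float = 0.5
    post_flash_ms: float = POST_FLASH_MS

    def __post_init__(self) -> None:
        if self.pii_background_half >= self.piii_background_half:
            raise ValidationError(
                "pii_background_half must be below piii_background_half "
                "(PII saturates at dimmer backgrounds than PIII)"
            )
        for name in (
            "pii_gain_dark",
            "cone_a_gain",
            "cone_b_gain",
            "cone_d_gain",
            "offset_negative_gain",
            "noise_sd",
            "subject_gain_cv",
            "piii_integration_ms",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "piii_background_half",
            "s_background_half",
            "pii_background_half",
            "pii_time_to_peak",
            "cone_semisaturation",
            "rod_suppression_background",
            "dt_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.pii_shape <= 1:
            raise ValidationError(f"pii_shape must be > 1, got {self.pii_shape}")
        if not 0 <= self.pii_plateau_fraction <= 1:
            raise ValidationError("pii_plateau_fraction must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")


def adaptation_gain(background: float, gain_dark: float, background_half: float) -> float:
    """Weber-like gain under a steady background.

    ``gain_dark / (1 + background / background_half)``: equals the dark
    gain at background 0, halves at ``background_half`` and decreases
    strictly with luminance.
    """
    if background_half <= 0:
        raise ValidationError(f"background_half must be > 0, got {background_half}")
    if background < 0:
        raise ValidationError(f"background must be >= 0, got {background}")
    return gain_dark / (1.0 + background / background_half)


def _gamma_transient(t, time_to_peak: float, shape: float):
    """Unit-peak gamma transient ``(t/tau)^n * exp(n*(1 - t/tau))``, 0 for t <= 0."""
    t = np.asarray(t, dtype=float)
    x = np.clip(t / time_to_peak, 0.0, None)
    with np.errstate(over="ignore"):
        g = np.where(x > 0, x**shape * np.exp(shape * (1.0 - x)), 0.0)
    return g


def _offset_ramp(t_after_onset, flash_duration: float, recovery_ms: float = RECOVERY_MS):
    """Multiplicative clamp: 1 during the flash, linear to 0 over the recovery."""
    t = np.asarray(t_after_onset, dtype=float)
    return np.clip(1.0 - (t - flash_duration) / recovery_ms, 0.0, 1.0)


def pii_kernel(
    t_after_onset,
    time_to_peak: float,
    shape: float,
    plateau_fraction: float,
    flash_duration: float,
):
    """Unit-peak PII (b-wave) kernel.

    Gamma transient rising to exactly 1 at ``time_to_peak``; past the
    peak it relaxes toward ``plateau_fraction`` with the transient's
    exponentially decaying tail; after flash offset it is clamped back
    to 0 over a fixed 40 ms recovery.  Values lie in [0, 1].
    """
    t = np.asarray(t_after_onset, dtype=float)
    g = _gamma_transient(t, time_to_peak, shape)
    k = np.where(
        t <= time_to_peak, g, plateau_fraction + (1.0 - plateau_fraction) * g
    )
    k = k * _offset_ramp(t, flash_duration)
    out = np.clip(k, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _cone_waveform(config: SyntheticConfig, condition: StimulusCondition, s: np.ndarray):
    """Cone On/Off contribution (µV) on the shared after-onset time axis ``s``."""
    i = condition.stimulus_luminance
    drive = i / (i + config.cone_semisaturation)  # Naka-Rushton stimulus scaling
    dur = condition.flash_duration
    a = -config.cone_a_gain * _gamma_transient(s, 9.0, 3.0) * _offset_ramp(s, dur)
    b = config.cone_b_gain * pii_kernel(s, 25.0, 3.0, 0.8, dur)
    u = s - dur
    d = config.cone_d_gain * _gamma_transient(u, 10.0, 3.0)
    off = -config.offset_negative_gain * _gamma_transient(u, 22.0, 2.0)
    return drive * (a + b + d + off)


@dataclass
class ConditionTruth:
    """Noise-free components of one simulated recording."""

    piii: np.ndarray
    pii: np.ndarray
    cone: np.ndarray
    #: adaptation- and subject-scaled Birch–Hood truth (None when rods suppressed)
    piii_params: PIIIParams | None
    #: adaptation- and subject-scaled PII peak gain (µV)
    pii_peak: float

    @property
    def rod(self) -> np.ndarray:
        return self.piii + self.pii

    @property
    def total(self) -> np.ndarray:
        return self.piii + self.pii + self.cone


def _scaled_rod_truth(
    config: SyntheticConfig, background: float, subject_gain: float
) -> tuple[PIIIParams | None, float]:
    """Adaptation- and subject-scaled rod ground truth at a background."""
    if background >= config.rod_suppression_background:
        return None, 0.0
    dark = config.piii_params_dark
    r_max = adaptation_gain(background, dark.r_max, config.piii_background_half) * subject_gain
    s = adaptation_gain(background, dark.s, config.s_background_half)
    pii_peak = (
        adaptation_gain(background, config.pii_gain_dark, config.pii_background_half)
        * subject_gain
    )
    return PIIIParams(r_max=r_max, s=s, t_d=dark.t_d), pii_peak


def simulate_recording(
    config: SyntheticConfig,
    condition: StimulusCondition,
    subject_gain: float = 1.0,
    noise: np.ndarray | None = None,
    subject_id: str = "S1",
    times: np.ndarray | None = None,
) -> tuple[ERGRecording, ConditionTruth]:
    """Simulate one averaged waveform plus its noise-free truth.

    The waveform is ``-PIII + PII + cone + noise``; all component
    amplitudes scale with ``subject_gain``.  ``noise`` is a pre-drawn
    per-sample array (µV), making the output deterministic.
    """
    if times is None:
        end = condition.flash_offset + config.post_flash_ms
        times = np.arange(0.0, end + config.dt_ms / 2, config.dt_ms)
    times = np.asarray(times, dtype=float)
    s = times - condition.flash_onset
    dur = condition.flash_duration

    params, pii_peak = _scaled_rod_truth(
        config, condition.background_luminance, subject_gain
    )
    if params is None:
        piii = np.zeros_like(times)
        pii = np.zeros_like(times)
    else:
        hold = dur + config.piii_integration_ms
        dev = np.clip(s, 0.0, hold)
        resp = birch_hood_response(condition.stimulus_luminance, dev, params)
        piii = -resp * _offset_ramp(s, hold)
        pii = pii_peak * pii_kernel(
            s, config.pii_time_to_peak, config.pii_shape, config.pii_plateau_fraction, dur
        )
    cone = subject_gain * _cone_waveform(config, condition, s)

    clean = piii + pii + cone
    amplitudes = clean if noise is None else clean + noise
    rec = ERGRecording(
        subject_id=subject_id,
        times=times,
        amplitudes=amplitudes,
        condition=condition,
        baseline_corrected=noise is None,  # noise-free pre-stimulus segment is exactly 0
    )
    truth = ConditionTruth(
        piii=piii, pii=pii, cone=cone, piii_params=params, pii_peak=pii_peak
    )
    return rec, truth


@dataclass
class CohortTruth:
    """Noise-free ground truth for every recording of a simulated cohort."""

    times: np.ndarray
    subject_gains: dict[str, float]
    entries: dict[tuple[str, float, float], ConditionTruth]
    config: SyntheticConfig

    def __getitem__(self, key: tuple[str, float, float]) -> ConditionTruth:
        return self.entries[key]

    def to_frame(self) -> pd.DataFrame:
        """Long-format component table keyed by (subject, background, stimulus)."""
        frames = []
        for (sid, bg, stim), truth in self.entries.items():
            n = len(self.times)
            for comp_name in ("piii", "pii", "cone"):
                frames.append(
                    pd.DataFrame(
                        {
                            "subject_id": [sid] * n,
                            "background_cdm2": bg,
                            "stimulus_cdm2": stim,
                            "component": comp_name,
                            "time_ms": self.times,
                            "amplitude_uv": getattr(truth, comp_name),
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def draw_subject_gains(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, float]:
    """Per-subject multiplicative gains: lognormal with unit mean and CV as given."""
    cv = config.subject_gain_cv
    sigma = math.sqrt(math.log(1.0 + cv**2))
    gains = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=config.n_subjects)
    return {f"S{j + 1}": float(g) for j, g in enumerate(gains)}


def simulate_cohort(
    config: SyntheticConfig, protocol: Protocol
) -> tuple[list[ERGRecording], CohortTruth]:
    """Simulate ``n_subjects`` × ``len(protocol.steps)`` averaged recordings.

    A single integer seed determines everything: subject gains are drawn
    first, then per-recording noise in (subject, protocol-step) order.
    """
    rng = np.random.default_rng(config.seed)
    gains = draw_subject_gains(config, rng)
    end = max(step.flash_offset for step in protocol.steps) + config.post_flash_ms
    times = np.arange(0.0, end + config.dt_ms / 2, config.dt_ms)

    recordings: list[ERGRecording] = []
    entries: dict[tuple[str, float, float], ConditionTruth] = {}
    for sid, gain in gains.items():
        for step in protocol.steps:
            noise = (
                rng.normal(0.0, config.noise_sd, size=len(times))
                if config.noise_sd > 0
                else None
            )
            rec, truth = simulate_recording(
                config, step, subject_gain=gain, noise=noise, subject_id=sid, times=times
            )
            recordings.append(rec)
            entries[rec.key] = truth
    return recordings, CohortTruth(
        times=times, subject_gains=gains, entries=entries, config=config
    )


def short_flash_config(
    config: SyntheticConfig,
    flash_t_d: float = 2.0,
    integration_ms: float = 30.0,
) -> SyntheticConfig:
    """Variant config for a brief-flash comparison protocol.

    The same cohort model with a shorter transduction delay and a PIII
    response that keeps developing for ``integration_ms`` beyond the
    (few-ms) flash, emulating the photoresponse to a brief flash.
    """
    dark = config.piii_params_dark
    return replace(
        config,
        piii_params_dark=PIIIParams(r_max=dark.r_max, s=dark.s, t_d=flash_t_d),
        piii_integration_ms=integration_ms,
    )
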