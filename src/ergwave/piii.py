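"""Rod PIII modeling: photopic subtraction and Birch–Hood a-wave fitting.

The leading edge of the rod-driven a-wave is described by the delayed
saturating exponential

    R(I, t) = (1 - exp[-I * S * (t - td)^2]) * Rmax    for t > td,  else 0

with ``I`` the stimulus luminance, ``S`` a sensitivity factor, ``td`` a
short transduction delay and ``Rmax`` the maximum (saturated) response
magnitude.  ``I`` is taken as corneal stimulus luminance in cd/m²
as-given; ``S`` absorbs the unit choice, so fitted sensitivities are only
comparable between analyses using the same luminance units.

Rod-driven waveforms are obtained by photopic subtraction: the response
recorded on a rod-suppressing background at matched stimulus strength is
subtracted point-wise, removing cone contributions.

Fit quality uses the dimensionless least-squares ratio
``lsq = RSS / TSS`` (residual sum of squares over total sum of squares
about the mean of the observed points); values below 0.25 are
conventionally considered a good fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .core import ERGRecording
from .errors import FitError, ValidationError

#: Conventional good-fit bound on the lsq statistic.
GOOD_FIT_LSQ = 0.25


@dataclass(frozen=True)
class PIIIParams:
    """Birch–Hood parameter triplet.

    r_max : µV, maximum response magnitude (> 0)
    s     : sensitivity, (cd/m²)⁻¹·ms⁻² (> 0)
    t_d   : delay, ms (>= 0)
    """

    r_max: float
    s: float
    t_d: float

    def __post_init__(self) -> None:
        for name, val in (("r_max", self.r_max), ("s", self.s), ("t_d", self.t_d)):
            if not math.isfinite(val):
                raise ValidationError(f"{name} must be finite, got {val}")
        if self.r_max <= 0:
            raise ValidationError(f"r_max must be > 0, got {self.r_max}")
        if self.s <= 0:
            raise ValidationError(f"s must be > 0, got {self.s}")
        if self.t_d < 0:
            raise ValidationError(f"t_d must be >= 0, got {self.t_d}")


def birch_hood_response(i: float, t, params: PIIIParams):
    """Evaluate the PIII leading-edge model (response magnitude, µV).

    ``t`` is time after flash onset in ms (scalar or array); the response
    is 0 for ``t <= t_d``, rises as a saturating exponential in
    ``I*S*(t-td)^2`` and is bounded by ``r_max``.
    """
    if i <= 0:
        raise ValidationError(f"stimulus luminance must be > 0, got {i}")
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - params.t_d, 0.0, None)
    out = (1.0 - np.exp(-i * params.s * dt**2)) * params.r_max
    if out.ndim == 0:
        return float(out)
    return out


def goodness_of_fit(observed, fitted) -> float:
    """lsq statistic: RSS over total SS about the mean of ``observed``.

    0 for a perfect fit, 1 when the fit is no better than the mean.
    Raises on length mismatch, fewer than 2 points, or a constant
    observed vector (zero denominator).
    """
    y = np.asarray(observed, dtype=float)
    f = np.asarray(fitted, dtype=float)
    if y.shape != f.shape or y.ndim != 1:
        raise ValidationError("observed and fitted must be 1-D arrays of equal length")
    if len(y) < 2:
        raise ValidationError("goodness_of_fit needs at least 2 points")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 1e-12 * max(1.0, float(np.abs(y).max()) ** 2):
        raise ValidationError("observed vector is constant; lsq undefined")
    rss = float(np.sum((y - f) ** 2))
    return rss / tss


def photopic_subtract(
    recording: ERGRecording,
    photopic_match: ERGRecording,
    rod_suppressing_background: float | None = None,
) -> ERGRecording:
    """Remove cone components by subtracting the photopically matched response.

    Both recordings must be baseline-corrected, from the same subject,
    at the same stimulus luminance and on the same time base;
    ``photopic_match`` must be the recording on the rod-suppressing
    background (checked when ``rod_suppressing_background`` is given).
    Returns the rod-only waveform carrying ``recording``'s condition.
    """
    if recording.subject_id != photopic_match.subject_id:
        raise ValidationError(
            f"subject mismatch: {recording.subject_id} vs {photopic_match.subject_id}"
        )
    if recording.condition.stimulus_luminance != photopic_match.condition.stimulus_luminance:
        raise ValidationError(
            "stimulus luminance mismatch: "
            f"{recording.condition.stimulus_luminance} vs "
            f"{photopic_match.condition.stimulus_luminance}"
        )
    if not recording.baseline_corrected or not photopic_match.baseline_corrected:
        raise ValidationError("both recordings must be baseline-corrected before subtraction")
    if len(recording.times) != len(photopic_match.times) or not np.allclose(
        recording.times, photopic_match.times, atol=1e-9
    ):
        raise ValidationError("time bases differ; cannot subtract")
    if (
        rod_suppressing_background is not None
        and photopic_match.condition.background_luminance != rod_suppressing_background
    ):
        raise ValidationError(
            f"photopic match recorded at {photopic_match.condition.background_luminance} "
            f"cd/m², expected rod-suppressing background {rod_suppressing_background}"
        )
    return recording.with_amplitudes(
        recording.amplitudes - photopic_match.amplitudes, baseline_corrected=True
    )


def photopic_subtract_cohort(
    recordings: Iterable[ERGRecording], rod_suppressing_background: float
) -> list[ERGRecording]:
    """Photopically subtract every recording in a cohort.

    Pairs each recording with the same subject/stimulus recording at the
    rod-suppressing background; recordings at that background itself are
    dropped (they subtract to zero by construction).
    """
    recs = list(recordings)
    matches = {
        (r.subject_id, r.condition.stimulus_luminance): r
        for r in recs
        if r.condition.background_luminance == rod_suppressing_background
    }
    if not matches:
        raise ValidationError(
            f"no recordings at the rod-suppressing background {rod_suppressing_background}"
        )
    out = []
    for rec in recs:
        if rec.condition.background_luminance == rod_suppressing_background:
            continue
        key = (rec.subject_id, rec.condition.stimulus_luminance)
        if key not in matches:
            raise ValidationError(f"no photopic match for {key}")
        out.append(photopic_subtract(rec, matches[key], rod_suppressing_background))
    return out


@dataclass(frozen=True)
class WindowPolicy:
    """Leading-edge fit-window selection policy.

    The initial window runs from flash onset to ``min(trough time - 1
    sample, cap_ms)``.  The trough is the waveform minimum within
    ``a_window_ms`` of onset; when the minimum is a flat (saturated)
    plateau the latest tied sample is used, so fully saturated responses
    fall back to the cap.  A waveform with no deflection below
    ``trough_floor_uv`` has no detectable trough; ``fallback_end_ms``
    (if set) is then used instead of raising.

    The ensemble fit then refines the windows with an iterative
    *postreceptoral intrusion screen*: near the trough the rising
    (cornea-positive) PII component starts to cancel the PIII
    negativity, which shows up as a smoothed model-minus-data deficit
    growing monotonically at the window tail.  Each pass truncates every
    stimulus window at the start of its terminal run of deficits above
    ``max(screen_sigma_mult * noise_se, screen_rel_floor * r_max)`` and
    refits, stopping early once the windows stabilise.  The noise scale
    is estimated robustly from first differences of the residuals so a
    smooth intrusion does not inflate it.
    """

    a_window_ms: float = 50.0
    cap_ms: float = 35.0
    min_samples: int = 5
    trough_floor_uv: float = 5.0
    fallback_end_ms: float | None = None
    td_floor_ms: float = 0.0
    screen_iterations: int = 5
    screen_rel_floor: float = 0.003
    screen_smooth_samples: int = 5
    screen_sigma_mult: float = 2.5


def select_fit_window(
    recording: ERGRecording, policy: WindowPolicy = WindowPolicy()
) -> tuple[float, float]:
    """Select the leading-edge window (start, end) in ms after flash onset."""
    if not recording.baseline_corrected:
        raise ValidationError("waveform must be baseline-corrected")
    onset = recording.condition.flash_onset
    t = recording.times
    mask = (t >= onset) & (t <= onset + policy.a_window_ms)
    seg = recording.amplitudes[mask]
    seg_t = t[mask] - onset
    if len(seg) == 0:
        raise FitError("a-window contains no samples")
    amin = float(seg.min())
    if amin > -policy.trough_floor_uv:
        if policy.fallback_end_ms is None:
            raise FitError(
                f"no detectable a-wave trough (min {amin:.2f} µV above "
                f"-{policy.trough_floor_uv} µV floor) and no fallback window"
            )
        end = policy.fallback_end_ms
    else:
        # latest sample tied with the minimum: a saturated plateau then
        # defers to the cap instead of truncating at numerical noise
        tied = seg_t[seg <= amin + 1e-9]
        trough_t = float(tied[-1])
        end = min(trough_t - recording.dt, policy.cap_ms)
    start = policy.td_floor_ms
    n_in = int(np.sum((seg_t >= start) & (seg_t <= end + 1e-9)))
    if n_in < policy.min_samples:
        raise FitError(
            f"fit window [{start}, {end}] ms holds {n_in} samples; "
            f"need >= {policy.min_samples}"
        )
    return (start, float(end))


@dataclass
class FitResult:
    """Result of a (possibly ensemble) Birch–Hood fit."""

    params: PIIIParams
    lsq: float
    n_points: int
    per_stimulus_residual_rms: dict[float, float]
    converged: bool
    fit_windows: dict[float, tuple[float, float]]


def _pool_fit_data(
    rod_waveforms: Mapping[float, ERGRecording],
    windows: Mapping[float, tuple[float, float]] | None,
    policy: WindowPolicy,
):
    """Collect (stimulus, t-after-onset, magnitude) arrays for fitting."""
    data = []
    used_windows: dict[float, tuple[float, float]] = {}
    for stim in sorted(rod_waveforms):
        rec = rod_waveforms[stim]
        if rec.condition.stimulus_luminance != stim:
            raise ValidationError(
                f"key {stim} does not match recording stimulus "
                f"{rec.condition.stimulus_luminance}"
            )
        win = windows[stim] if windows is not None else select_fit_window(rec, policy)
        onset = rec.condition.flash_onset
        mask = (rec.times >= onset + win[0]) & (rec.times <= onset + win[1] + 1e-9)
        t = rec.times[mask] - onset
        y = -rec.amplitudes[mask]  # magnitudes: cornea-negative becomes positive
        data.append((stim, t, y))
        used_windows[stim] = win
    return data, used_windows


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Edge-padded moving average."""
    if w <= 1 or len(x) < w:
        return x.copy()
    pad = w // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    return np.convolve(xp, np.ones(w) / w, mode="valid")


def _screen_windows(
    data: list[tuple[float, np.ndarray, np.ndarray]],
    base_windows: dict[float, tuple[float, float]],
    params: PIIIParams,
    policy: WindowPolicy,
) -> dict[float, tuple[float, float]]:
    """One pass of the postreceptoral intrusion screen.

    Truncates each stimulus window at the start of the terminal run of
    smoothed model-minus-data deficits above the screen threshold.
    """
    diffs = [np.diff(y - birch_hood_response(stim, t, params)) for stim, t, y in data]
    sigma = float(np.median(np.abs(np.concatenate(diffs)))) * 1.4826 / np.sqrt(2.0)
    noise_se = policy.screen_sigma_mult * sigma / np.sqrt(policy.screen_smooth_samples)
    thr = max(noise_se, policy.screen_rel_floor * params.r_max)
    out: dict[float, tuple[float, float]] = {}
    for stim, t, y in data:
        deficit = _smooth(
            birch_hood_response(stim, t, params) - y, policy.screen_smooth_samples
        )
        j = len(deficit)
        while j > 0 and deficit[j - 1] > thr:
            j -= 1
        if j < len(deficit) and j >= policy.min_samples:
            out[stim] = (base_windows[stim][0], float(t[j - 1]))
        else:
            out[stim] = base_windows[stim]
    return out


def fit_piii(
    rod_waveforms: Mapping[float, ERGRecording],
    windows: Mapping[float, tuple[float, float]] | None = None,
    policy: WindowPolicy = WindowPolicy(),
    shared: bool = True,
    max_restarts: int = 3,
    screen: bool = True,
) -> FitResult | dict[float, FitResult]:
    """Fit the Birch–Hood model to the pooled a-wave leading edges.

    ``rod_waveforms`` maps stimulus luminance to the photopically
    subtracted, baseline-corrected waveform at that stimulus.  By default
    a single (r_max, s, t_d) triplet is shared across all stimuli
    (ensemble fit); with ``shared=False`` each stimulus is fitted
    separately and a dict of per-stimulus results is returned.

    Bounded least squares (Levenberg–Marquardt on internally transformed
    parameters), initialized from the data (r_max from the deepest
    pooled magnitude, t_d = 3 ms, s from a coarse log-grid scan) with
    jittered restarts on non-convergence.  Unless explicit ``windows``
    are supplied, the trough-based windows are refined by the iterative
    intrusion screen described in :class:`WindowPolicy`.
    """
    if len(rod_waveforms) == 0:
        raise ValidationError("need at least one stimulus to fit")
    if not shared:
        return {
            stim: fit_piii({stim: rec}, windows={stim: windows[stim]} if windows else None,
                           policy=policy, shared=True, max_restarts=max_restarts,
                           screen=screen)
            for stim, rec in rod_waveforms.items()
        }

    if windows is None and screen and policy.screen_iterations > 0:
        base_windows = {
            stim: select_fit_window(rec, policy) for stim, rec in rod_waveforms.items()
        }
        base_data, _ = _pool_fit_data(rod_waveforms, base_windows, policy)
        fit = fit_piii(
            rod_waveforms, windows=base_windows, policy=policy, shared=True,
            max_restarts=max_restarts,
        )
        current = base_windows
        for _ in range(policy.screen_iterations):
            refined = _screen_windows(base_data, base_windows, fit.params, policy)
            if refined == current:
                break
            current = refined
            fit = fit_piii(
                rod_waveforms, windows=current, policy=policy, shared=True,
                max_restarts=max_restarts,
            )
        return fit

    data, used_windows = _pool_fit_data(rod_waveforms, windows, policy)
    y_pool = np.concatenate([y for _, _, y in data])
    if float(np.abs(y_pool).max()) < 1e-9:
        raise FitError("degenerate all-zero input; nothing to fit")

    r0 = max(float(y_pool.max()), 1.0)
    r_hi = 2.0 * r0

    def residual(p):
        vals = p.valuesdict()
        params = PIIIParams(vals["r_max"], vals["s"], vals["t_d"])
        res = [y - birch_hood_response(stim, t, params) for stim, t, y in data]
        return np.concatenate(res)

    # coarse log-grid scan for the sensitivity initialization
    s_grid = np.logspace(-6, 0, 25)
    best_s, best_cost = s_grid[0], np.inf
    for s0 in s_grid:
        params = PIIIParams(r0, s0, 3.0)
        cost = sum(
            float(np.sum((y - birch_hood_response(stim, t, params)) ** 2))
            for stim, t, y in data
        )
        if cost < best_cost:
            best_s, best_cost = s0, cost

    starts = [(r0, best_s, 3.0)]
    for mult in (0.5, 2.0, 1.0):
        starts.append((min(r0 * (2 - mult * 0.5), r_hi * 0.99), best_s * mult, 1.0 * mult))

    result = None
    for attempt, (ri, si, tdi) in enumerate(starts[: max_restarts + 1]):
        p = lmfit.Parameters()
        p.add("r_max", value=ri, min=1e-3, max=r_hi)
        p.add("s", value=si, min=1e-9, max=10.0)
        p.add("t_d", value=tdi, min=0.0, max=20.0)
        try:
            res = lmfit.minimize(residual, p, method="leastsq")
        except Exception:  # optimizer blow-up: try next start
            continue
        if result is None or res.chisqr < result.chisqr:
            result = res
        if res.success:
            result = res if res.chisqr <= result.chisqr else result
            break
    if result is None:
        raise FitError("optimizer failed on every initialization")

    vals = result.params.valuesdict()
    fitted_params = PIIIParams(vals["r_max"], vals["s"], vals["t_d"])
    f_pool = np.concatenate(
        [birch_hood_response(stim, t, fitted_params) for stim, t, _ in data]
    )
    lsq = goodness_of_fit(y_pool, f_pool)
    rms = {
        stim: float(np.sqrt(np.mean((y - birch_hood_response(stim, t, fitted_params)) ** 2)))
        for stim, t, y in data
    }
    return FitResult(
        params=fitted_params,
        lsq=lsq,
        n_points=len(y_pool),
        per_stimulus_residual_rms=rms,
        converged=bool(result.success),
        fit_windows=used_windows,
    )


FIT_TABLE_COLUMNS = [
    "subject_id",
    "background_cdm2",
    "r_max_uv",
    "s",
    "t_d_ms",
    "lsq",
    "converged",
    "n_points",
]


def fit_all_backgrounds(
    rod_recordings: Iterable[ERGRecording],
    backgrounds: Sequence[float],
    policy: WindowPolicy = WindowPolicy(),
    shared: bool = True,
) -> pd.DataFrame:
    """Ensemble-fit every subject at every requested background.

    ``rod_recordings`` are photopically subtracted waveforms covering all
    requested backgrounds.  Returns one row per (subject, background)
    with the fitted parameters, lsq and convergence flag.
    """
    by_subject: dict[str, dict[float, dict[float, ERGRecording]]] = {}
    for rec in rod_recordings:
        by_subject.setdefault(rec.subject_id, {}).setdefault(
            rec.condition.background_luminance, {}
        )[rec.condition.stimulus_luminance] = rec
    if not by_subject:
        raise ValidationError("no rod recordings supplied")
    missing = []
    for sid, by_bg in by_subject.items():
        for bg in backgrounds:
            if bg not in by_bg:
                missing.append((sid, bg))
    if missing:
        raise ValidationError(f"missing rod recordings for (subject, background): {missing}")
    rows = []
    for sid in sorted(by_subject):
        for bg in backgrounds:
            fit = fit_piii(by_subject[sid][bg], policy=policy, shared=shared)
            rows.append(
                {
                    "subject_id": sid,
                    "background_cdm2": bg,
                    "r_max_uv": fit.params.r_max,
                    "s": fit.params.s,
                    "t_d_ms": fit.params.t_d,
                    "lsq": fit.lsq,
                    "converged": fit.converged,
                    "n_points": fit.n_points,
                }
            )
    return pd.DataFrame(rows, columns=FIT_TABLE_COLUMNS)


def summarize_fits(fit_table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of each fitted parameter per background."""
    long = fit_table.melt(
        id_vars=["background_cdm2"],
        value_vars=["r_max_uv", "s", "t_d_ms", "lsq"],
        var_name="parameter",
    )
    out = (
        long.groupby(["background_cdm2", "parameter"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return out
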