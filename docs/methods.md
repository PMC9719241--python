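# Methods

`ergwave` analyses On–Off (long-flash) full-field electroretinograms:
sustained flashes (250 ms by default) presented on a series of steady
background luminances, so that responses to stimulus onset (On: a-wave,
b-wave) and offset (Off: d-wave and after-negativity) are separated in
time.  The package covers the full chain from waveforms to statistics:
feature extraction, photopic subtraction, PIII model fitting, PII
isolation and repeated-measures comparison, together with a synthetic
cohort generator that provides exact ground truth for every stage.

## The rod PIII model

The leading edge of the rod-driven a-wave is modelled by the delayed
saturating exponential

```
R(I, t) = (1 − exp[−I·S·(t − td)²]) · Rmax      for t > td,  else 0
```

with `I` the stimulus luminance, `S` a sensitivity factor, `td` a short
transduction delay (ms) and `Rmax` the saturated response magnitude
(µV).  The model describes only the rising phase of the photoreceptor
response; for a sustained flash the response is assumed to hold its
saturated level until flash offset and then return to baseline.

**Units.** `I` is corneal stimulus luminance in cd/m² exactly as given;
`S` absorbs the unit choice and therefore carries units of
(cd/m²)⁻¹·ms⁻².  No pupil or troland conversion is attempted (none of
the required optics data is modelled), so fitted sensitivities are
comparable only between analyses using the same luminance convention.
This is stated prominently because `S` values change by orders of
magnitude under a different unit choice.

**Fitting contract.** A single (Rmax, S, td) triplet is shared across
the five stimuli recorded at one background (ensemble fit; a
per-stimulus mode exists behind `shared=False`).  The optimiser is
bounded nonlinear least squares (lmfit's Levenberg–Marquardt on
internally transformed parameters) with bounds Rmax ≤ 2× the deepest
pooled magnitude, S ∈ [1e-9, 10], td ∈ [0, 20] ms.  Initialisation:
Rmax from the deepest pooled magnitude, td = 3 ms, S from a coarse
25-point log-grid scan; up to three jittered restarts on
non-convergence.  Fit quality is the dimensionless ratio
`lsq = RSS / TSS` (residual sum of squares over total sum of squares
about the mean of the fitted points); values below 0.25 are
conventionally regarded as a good fit.

## Leading-edge window selection

The initial fit window for each stimulus runs from flash onset to
`min(trough time − 1 sample, 35 ms)`, the trough being the waveform
minimum within 50 ms of onset (earliest sample for a clean trough; the
latest tied sample for a flat saturated plateau, which then defers to
the 35 ms cap).  A waveform with no deflection below 5 µV has no
detectable trough and raises unless a fallback window is configured.

A trough-based window alone is not enough: near the trough the rising
cornea-positive PII component partially cancels the PIII negativity, so
points close to the trough are systematically contaminated and bias
Rmax down by a few percent and S by tens of percent.  The ensemble fit
therefore applies an iterative **postreceptoral intrusion screen**:
after each fit, the model-minus-data deficit (positive where something
cornea-positive is cancelling the modelled negativity) is smoothed over
5 samples and each stimulus window is truncated at the start of its
terminal run of deficits above

```
max(2.5 · σ̂ / √5,  0.003 · Rmax)
```

where σ̂ is a robust noise scale estimated from first differences of
the residuals (first differences are insensitive to the smooth
intrusion itself).  Truncation applies only to a terminal run because
PII intrusion grows monotonically toward the trough; an isolated
mid-window excursion is noise, not intrusion.  The screen runs for at
most 5 passes and stops early when the windows stabilise.  On noise-free
synthetic cohorts this brings Rmax recovery from 2–4% error to under
0.5% and S from 15–35% error to under 3%; with 3 µV noise the median
errors over seeded cohorts are ≈1.5% (Rmax), ≈7–9% (S) and well under
1 ms (td).

## Photopic subtraction and PII isolation

Cone contributions are removed by subtracting the response recorded on
the rod-suppressing background (42 cd/m² by default) at matched
stimulus strength, point-wise on the shared time base.  Both waveforms
must be baseline-corrected and from the same subject.

The full PIII time course is then reconstructed from the fitted
parameters — zero before onset, the saturating response held at its
plateau during the flash, a linear 40 ms return after offset — and
subtracted from the rod-only waveform over the On-phase window
(onset → offset).  The isolation window ends at flash offset because
the post-offset recovery kinetics of PIII are not constrained by the
model; everything after offset is Off-pathway territory.

Isolated-PII metrics: peak amplitude (µV), peak time (ms after onset,
earliest on ties), width (time spent above 5% of peak, from first
crossing to the return below threshold — a relative threshold because
"return to baseline" is noise-ambiguous), and `residual_drift`.

**`residual_drift` definition.** The drift statistic on the raw
waveform is the absolute change between the b-wave peak and the level
at flash cessation.  On an isolated PII that is deliberately transient
this literal difference equals the peak itself and carries no
information.  What the isolation is expected to remove is the
*sustained negativity* at flash cessation, so `residual_drift` is
defined as |mean amplitude over the last 5 ms before flash offset| —
the residual deviation from baseline just before the Off-response.  A
successful isolation drives it to ≈0 even though the PII itself has
long decayed.

## Waveform features

All features are measured on baseline-corrected waveforms
(cornea-negative = negative).  The a-wave is the minimum within 50 ms
of onset, measured baseline-to-trough; when nothing falls below zero
the a-wave is reported absent (amplitude 0, flagged) and the b-wave
search starts at onset — weak scotopic responses genuinely lack
a-waves.  The b-wave is the maximum between the a-trough and flash
offset, measured a-trough→peak by default (the common clinical
convention; a baseline→peak alternative is configurable since b:a
ratios depend on it).  The flash-cessation level is the mean over the
5 ms ending one sample before offset — "immediately prior to the
Off-response" — and drift = |b-peak value − cessation level|.  The
d-wave is the maximum within 50 ms after offset, measured relative to
the cessation level.  Ties between equal extrema resolve to the
earliest time.  Ratios (b:a, drift:b) are undefined (missing, never
zero) when the denominator is below 1 µV, which keeps near-zero
denominators from producing absurd ratios in summary tables.

Cohort summaries report mean, SD (n−1 denominator) and n per
(background, stimulus) cell; undefined ratios are excluded from that
cell's n, and single-subject cells report SD 0 with n = 1 flagging the
degenerate estimate.

## The synthetic cohort generator

The generator emulates a six-subject study over the full 6-background ×
5-stimulus grid of 250 ms flashes.  Each waveform is
`−PIII + PII + cone + noise`:

* **PIII**: negated Birch–Hood response held for the flash duration and
  linearly recovered over 40 ms after offset.
* **PII**: a unit-peak gamma kernel `(t/τ)ⁿ·exp(n(1−t/τ))` rising to 1
  at `τ` = 60 ms (shape n = 4), relaxing past the peak toward a
  sustained plateau fraction (default 0.1) with the transient's own
  exponentially decaying tail, and clamped back to zero over 40 ms
  after offset.  This is a descriptive shape for the b-wave generator,
  not a mechanistic bipolar-cell model.
* **Cone terms**: small fast a/b deflections during the flash and a
  biphasic Off-response (positive d-deflection followed by a dominant
  negativity — the E-type, dog-like configuration; swapping the two
  gains produces a primate-like positive d-wave).  Cone gains scale
  with stimulus through a Naka–Rushton term (half-saturation
  100 cd/m²) and are background-independent, so photopic subtraction
  removes them exactly in noise-free tests — the property the analysis
  relies on.

**Adaptation.** Every rod gain follows Weber-like adaptation
`g(B) = g_dark / (1 + B/B_half)`.  Defaults: dark PIII
Rmax = 150 µV, S = 0.008, td = 4 ms; PII dark gain 300 µV.  The PII
gain half-saturates at 0.15 cd/m² while the PIII amplitude
half-saturates at 2 cd/m², encoding the central finding that the
bipolar-driven pathway saturates at much dimmer backgrounds than the
photoreceptor response.  The PIII sensitivity S adapts with its own
half-saturation constant of 0.05 cd/m²; this value was chosen so that
mesopic backgrounds slow the PIII rise enough that the 1 cd/m²
waveform shows the characteristic sustained negativity with a small
b-wave riding on it, the drift:b ratio peaks at an interior background,
and the b:a ratio crosses unity near 1 cd/m².  Backgrounds at or above
30 cd/m² (the conventional rod-suppressing level) silence the rod
components entirely.  All amplitude defaults are arbitrary but
plausible for a rod-dominated retina at canine amplitudes; no figure
digitisation was attempted.

**Stochasticity.** One integer seed drives everything: per-subject
multiplicative gains first (lognormal, unit mean, CV 0.15), then
i.i.d. Gaussian per-sample noise (sd 3 µV) per recording in protocol
order.  Same seed ⇒ byte-identical cohort; different seeds share the
identical noise-free truth when the gain CV is zero.  A truth record
stores every noise-free component per recording for oracle tests.

**Short-flash variant.** For the brief-flash comparison condition the
same model is reused with a ~4 ms flash, a shorter transduction delay
(2 ms) and a PIII that keeps developing for 30 ms beyond the flash,
emulating the photoresponse to a brief flash outlasting the stimulus.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: oscillatory potentials, mains
interference or any correlated noise; background-dependent PII
*kinetics* (peak time and width are background-invariant by default,
so the shortening of isolated-PII peak time seen in real mesopic
recordings is not reproduced unless a kinetics-speedup is configured);
the absolute drift-amplitude *increase* with background (with the
fixed 0.1 plateau fraction the scotopic drift is large in absolute
terms; only the ratio behaviour mirrors the real regime); eye-level
replicates or session effects.

## Statistics

Fitted parameters are compared across condition labels (short-flash
plus the fitted long-flash backgrounds) with a one-way within-subject
(repeated-measures) ANOVA: SS_total decomposes into condition, subject
and error terms; F = MS_condition/MS_error with (k−1, (k−1)(n−1))
degrees of freedom.  No sphericity correction is applied by default.
Missing cells are an error — no imputation.  Identical columns return
F = 0, p = 1 by convention rather than 0/0.

Post-hoc testing is Tukey's HSD on the within-subject error term:
q = |mean difference| / √(MS_error/n), with p from the
studentized-range distribution on (k, df_error) and significance at
p < 0.05.  The subject is the experimental unit throughout (one value
per subject per condition; eyes are not modelled separately).

Calibration checks in the test suite: F equals the squared paired-t at
k = 2 to 1e-9; the SS identity holds to 1e-9; and the familywise
false-positive rate of ANOVA-gated Tukey over 500 null cohorts
(n = 6, k = 5) lies within [0.01, 0.10] at nominal 0.05.

## Problem sizes and tolerances used in the tests

Oracle tests run on a noise-free single-subject cohort (exact component
decomposition, subtraction identities to 1e-9 µV).  Recovery tests use
20 seeded six-subject cohorts at the default 3 µV noise with the
tolerances quoted above.  Monte-Carlo calibration uses 100 replicates
for power and 500 for the null rate.  These sizes make the full suite
run in about a minute while keeping every Monte-Carlo margin wide
relative to its binomial standard error.

## Known limitations

* The Birch–Hood plateau assumption (PIII flat until offset) is an
  idealisation; real photoreceptor responses sag slowly during long
  flashes, which would leak into the isolated PII as a slow positive
  ramp.
* The intrusion screen assumes intrusion is cornea-positive and
  monotone near the trough; a large cone residue of the opposite sign
  (imperfect photopic match) would not be caught.
* Fits at backgrounds of 10 cd/m² and above are deliberately
  unsupported: after photopic subtraction almost no rod signal remains
  there and the trough floor rejects the fit rather than returning
  noise-fit parameters.
* CSV input assumes averaged waveforms; single-sweep averaging,
  artifact rejection and vendor binary formats are out of scope.
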