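# ergwave

Analysis of On–Off (long-flash) full-field electroretinograms (ERGs).

A long-flash protocol presents sustained flashes (here 250 ms) on a
ladder of steady background luminances, separating the retina's
response to stimulus onset (On: the cornea-negative a-wave from
photoreceptors, the cornea-positive b-wave from ON bipolar cells) from
its response to stimulus offset (Off: the d-wave and after-negativity).
Sweeping the background from darkness through mesopic to photopic
levels progressively suppresses the rod pathway, and the way each
waveform component declines reveals where in the retina the suppression
acts.  `ergwave` is written for visual electrophysiologists who want
that analysis as a tested, scriptable pipeline rather than a spreadsheet.

The package provides:

* a documented long-format CSV schema for averaged ERG waveforms, with
  protocol building, validation and baseline correction;
* a **synthetic cohort generator** with exact per-component ground
  truth (rod PIII, rod-driven PII, cone On/Off terms, Weber-like light
  adaptation, seeded Gaussian noise) for end-to-end validation;
* **waveform features**: a-, b-, d-wave amplitudes and times, the
  *drift* (amplitude change between the b-wave peak and the level at
  flash cessation), and b:a / drift:b ratios with cohort summaries;
* **rod isolation and PIII fitting**: photopic subtraction, then a
  shared-parameter fit of the Birch–Hood model

  ```
  R(I, t) = (1 − exp[−I·S·(t − td)²]) · Rmax      for t > td
  ```

  to the a-wave leading edges of all stimuli at one background, with
  the `lsq = RSS/TSS` goodness-of-fit statistic (< 0.25 = good fit);
* **PII isolation** by subtracting the modelled PIII, with peak,
  timing, width and residual-negativity metrics;
* **repeated-measures statistics**: within-subject ANOVA plus Tukey HSD
  across luminance conditions for each fitted parameter;
* a CLI (`ergwave simulate | features | fit | isolate | stats | all`)
  driving the whole pipeline from a JSON/YAML config.

## Worked example

Simulate the default six-subject cohort (30-step protocol: backgrounds
0, 0.01, 0.1, 1, 10, 42 cd/m² × stimuli 2.5, 25, 180, 500, 1250 cd/m²),
isolate the rod response by photopic subtraction, and fit the PIII
model per subject and background:

```python
from ergwave import (SyntheticConfig, build_protocol, simulate_cohort,
                     baseline_correct, photopic_subtract_cohort,
                     fit_all_backgrounds, summarize_fits)

protocol = build_protocol(backgrounds=[0, 0.01, 0.1, 1, 10, 42],
                          stimuli=[2.5, 25, 180, 500, 1250],
                          flash_duration=250.0)
config = SyntheticConfig(seed=42)
recordings, truth = simulate_cohort(config, protocol)     # 180 waveforms
corrected = [baseline_correct(r) for r in recordings]
rods = photopic_subtract_cohort(corrected, rod_suppressing_background=42.0)
fits = fit_all_backgrounds(rods, backgrounds=[0, 0.01, 0.1, 1])
summary = summarize_fits(fits)
print(summary[summary.parameter == "r_max_uv"].to_string(index=False))
```

prints

```
 background_cdm2 parameter       mean        sd  n
            0.00  r_max_uv 140.011685 23.577896  6
            0.01  r_max_uv 139.578985 25.719724  6
            0.10  r_max_uv 133.652034 22.719164  6
            1.00  r_max_uv  93.323502 16.551756  6
```

the cohort mean ± SD of the fitted saturated rod amplitude `Rmax`: flat
across the two dimmest backgrounds, then clearly suppressed at 1 cd/m²
(the generator's dark truth is 150 µV with a 15% between-subject gain
spread, so the ≈ 23 µV SD is dominated by real subject differences, not
fit error).  The underlying per-fit table carries the full triplet and
fit quality, e.g. for the first subject:

```
subject_id  background_cdm2   r_max_uv        s   t_d_ms      lsq  converged  n_points
        S1             0.00 151.561621 0.007381 3.965230 0.004997       True        83
        S1             0.01 154.241313 0.006175 3.986341 0.004522       True        83
        S1             0.10 143.233022 0.002809 4.006640 0.005921       True        87
        S1             1.00 100.104445 0.000349 3.875105 0.015515       True       164
```

Every `lsq` is far below the 0.25 good-fit bound, and the sensitivity
`s` falls steeply into the mesopic range while the delay `t_d` stays
near its 4 ms truth.  The same pipeline end-to-end, including feature
tables, isolated-PII metrics and the ANOVA/Tukey reports:

```sh
ergwave all --seed 42 --out out/
```

See `docs/methods.md` for the model, the leading-edge window policy,
the generator's design and its known limitations.

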