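import dataclasses
import math

import numpy as np
import pytest

from ergwave import (
    StimulusCondition,
    SyntheticConfig,
    ValidationError,
    adaptation_gain,
    baseline_correct,
    birch_hood_response,
    extract_features,
    pii_kernel,
    simulate_cohort,
    simulate_recording,
)

from conftest import BACKGROUNDS, FIT_BACKGROUNDS


class TestAdaptationGain:
    @pytest.mark.parametrize(
        "background,expected_fraction",
        [(0.0, 1.0), (2.0, 0.5), (6.0, 0.25)],  # 0, half-sat, 3x half-sat
    )
    def test_weber_decline(self, background, expected_fraction):
        assert adaptation_gain(background, 150.0, 2.0) == pytest.approx(
            150.0 * expected_fraction
        )

    def test_strictly_decreasing(self):
        gains = [adaptation_gain(b, 100.0, 0.5) for b in [0, 0.1, 1, 10, 42]]
        assert all(a > b for a, b in zip(gains, gains[1:]))

    def test_invalid_half_saturation(self):
        with pytest.raises(ValidationError):
            adaptation_gain(1.0, 100.0, 0.0)


class TestPiiKernel:
    def test_vanishes_at_onset(self):
        assert pii_kernel(0.0, 60.0, 4.0, 0.1, 250.0) == 0.0

    def test_unit_peak_at_time_to_peak(self):
        assert pii_kernel(60.0, 60.0, 4.0, 0.1, 250.0) == pytest.approx(1.0)

    def test_gamma_tail_value_at_twice_peak_time(self):
        # transient formula: (2)^4 * exp(-4) with zero plateau
        expected = 16.0 * math.exp(-4.0)
        assert pii_kernel(120.0, 60.0, 4.0, 0.0, 250.0) == pytest.approx(expected)

    def test_bounded_and_recovers_after_offset(self):
        t = np.arange(0.0, 320.0, 0.5)
        k = pii_kernel(t, 60.0, 4.0, 0.1, 250.0)
        assert np.all((k >= 0.0) & (k <= 1.0))
        assert np.all(k[t >= 290.0] == 0.0)  # 40 ms recovery after offset

    def test_plateau_sustained_until_offset(self):
        k_late = pii_kernel(249.0, 60.0, 4.0, 0.3, 250.0)
        assert k_late == pytest.approx(0.3, abs=0.01)


class TestSimulateRecording:
    def test_all_gains_zero_gives_flat_waveform(self):
        cfg = SyntheticConfig(
            piii_params_dark=dataclasses.replace(
                SyntheticConfig().piii_params_dark, r_max=1e-9
            ),
            pii_gain_dark=0.0,
            cone_a_gain=0.0,
            cone_b_gain=0.0,
            cone_d_gain=0.0,
            offset_negative_gain=0.0,
            noise_sd=0.0,
        )
        rec, _ = simulate_recording(cfg, StimulusCondition(0.0, 180.0))
        np.testing.assert_allclose(rec.amplitudes, 0.0, atol=1e-8)

    def test_piii_only_equals_negated_birch_hood_during_flash(self):
        cfg = SyntheticConfig(
            pii_gain_dark=0.0,
            cone_a_gain=0.0,
            cone_b_gain=0.0,
            cone_d_gain=0.0,
            offset_negative_gain=0.0,
            noise_sd=0.0,
        )
        cond = StimulusCondition(0.0, 180.0)
        rec, truth = simulate_recording(cfg, cond)
        in_flash = (rec.times >= cond.flash_onset) & (rec.times <= cond.flash_offset)
        t_after = rec.times[in_flash] - cond.flash_onset
        expected = -birch_hood_response(180.0, t_after, cfg.piii_params_dark)
        np.testing.assert_allclose(rec.amplitudes[in_flash], expected, atol=1e-12)
        np.testing.assert_allclose(truth.piii[in_flash], expected, atol=1e-12)

    def test_rods_silenced_on_rod_suppressing_background(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        rec, truth = simulate_recording(cfg, StimulusCondition(42.0, 180.0))
        assert truth.piii_params is None
        np.testing.assert_array_equal(truth.piii, 0.0)
        np.testing.assert_array_equal(truth.pii, 0.0)
        np.testing.assert_allclose(rec.amplitudes, truth.cone, atol=1e-12)


class TestSimulateCohort:
    def test_cohort_size_six_subjects_thirty_steps(self, noisy_cohort, protocol):
        _, recordings, _ = noisy_cohort
        assert len(recordings) == 6 * 30
        assert len({r.key for r in recordings}) == 180

    def test_zero_gain_cv_makes_subjects_identical(self, protocol):
        cfg = SyntheticConfig(seed=5, noise_sd=0.0, n_subjects=3, subject_gain_cv=0.0)
        _, truth = simulate_cohort(cfg, protocol)
        for bg in BACKGROUNDS[:2]:
            ref = truth[("S1", bg, 180.0)]
            for sid in ("S2", "S3"):
                other = truth[(sid, bg, 180.0)]
                np.testing.assert_allclose(other.total, ref.total, atol=1e-12)

    def test_waveform_decomposes_into_truth_components(self, clean_cohort):
        _, recordings, truth = clean_cohort
        for rec in recordings:
            np.testing.assert_allclose(
                rec.amplitudes, truth[rec.key].total, atol=1e-9
            )

    def test_same_seed_identical_different_seed_same_truth(self, protocol):
        cfg = SyntheticConfig(seed=3, n_subjects=2, subject_gain_cv=0.0)
        recs_a, _ = simulate_cohort(cfg, protocol)
        recs_b, _ = simulate_cohort(cfg, protocol)
        for a, b in zip(recs_a, recs_b):
            np.testing.assert_array_equal(a.amplitudes, b.amplitudes)
        recs_c, truth_c = simulate_cohort(dataclasses.replace(cfg, seed=4), protocol)
        assert any(
            not np.array_equal(a.amplitudes, c.amplitudes)
            for a, c in zip(recs_a, recs_c)
        )
        _, truth_a = simulate_cohort(cfg, protocol)
        for key in truth_a.entries:
            np.testing.assert_allclose(
                truth_a[key].total, truth_c[key].total, atol=1e-12
            )

    def test_noise_sd_matches_model(self, protocol):
        cfg = SyntheticConfig(seed=9, n_subjects=2)
        recordings, truth = simulate_cohort(cfg, protocol)
        resid = np.concatenate(
            [rec.amplitudes - truth[rec.key].total for rec in recordings]
        )
        assert resid.std() == pytest.approx(cfg.noise_sd, rel=0.05)

    def test_pii_saturates_below_piii_invariant_enforced(self):
        with pytest.raises(ValidationError, match="pii_background_half"):
            SyntheticConfig(pii_background_half=3.0, piii_background_half=2.0)


class TestCohortShapeMirrorsStudy:
    """Qualitative regime of the default generator (noise-free means)."""

    def _features(self, clean_cohort):
        _, recordings, _ = clean_cohort
        return {
            rec.key: extract_features(baseline_correct(rec)) for rec in recordings
        }

    def test_b_wave_non_increasing_with_background(self, clean_cohort):
        feats = self._features(clean_cohort)
        for stim in [2.5, 25.0, 180.0, 500.0, 1250.0]:
            b = [feats[("S1", bg, stim)].b_amplitude for bg in FIT_BACKGROUNDS]
            assert all(x >= y for x, y in zip(b, b[1:])), f"stimulus {stim}: {b}"

    def test_b_a_ratio_declines_faster_than_a(self, clean_cohort):
        feats = self._features(clean_cohort)
        for stim in [25.0, 180.0, 500.0, 1250.0]:
            r = [feats[("S1", bg, stim)].b_a_ratio for bg in FIT_BACKGROUNDS]
            assert all(x > y for x, y in zip(r, r[1:])), f"stimulus {stim}: {r}"

    def test_drift_b_ratio_peaks_at_interior_background(self, clean_cohort):
        feats = self._features(clean_cohort)
        means = {}
        for bg in BACKGROUNDS:
            vals = [
                feats[("S1", bg, stim)].drift_b_ratio
                for stim in [2.5, 25.0, 180.0, 500.0, 1250.0]
            ]
            vals = [v for v in vals if not math.isnan(v)]
            means[bg] = float(np.mean(vals))
        best = max(means, key=means.get)
        assert best not in (BACKGROUNDS[0], BACKGROUNDS[-1]), means
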