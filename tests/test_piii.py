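import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergwave import (
    ERGRecording,
    FitError,
    PIIIParams,
    StimulusCondition,
    SyntheticConfig,
    ValidationError,
    WindowPolicy,
    baseline_correct,
    birch_hood_response,
    fit_all_backgrounds,
    fit_piii,
    goodness_of_fit,
    photopic_subtract,
    select_fit_window,
    simulate_recording,
)
from ergwave.synthetic import _scaled_rod_truth

from conftest import FIT_BACKGROUNDS, ROD_SUPPRESSING


def piii_only_config(**kw):
    return SyntheticConfig(
        pii_gain_dark=0.0,
        cone_a_gain=0.0,
        cone_b_gain=0.0,
        cone_d_gain=0.0,
        offset_negative_gain=0.0,
        noise_sd=kw.pop("noise_sd", 0.0),
        **kw,
    )


class TestBirchHoodResponse:
    def test_zero_at_and_before_delay(self):
        p = PIIIParams(150.0, 0.008, 4.0)
        assert birch_hood_response(180.0, 4.0, p) == 0.0
        assert birch_hood_response(180.0, 1.0, p) == 0.0

    def test_half_saturation_identity(self):
        # i*s*(t-td)^2 = ln 2  =>  response = r_max / 2
        p = PIIIParams(150.0, 0.008, 4.0)
        t = 4.0 + math.sqrt(math.log(2.0) / (180.0 * 0.008))
        assert birch_hood_response(180.0, t, p) == pytest.approx(75.0)

    def test_direct_formula_arithmetic(self):
        p = PIIIParams(150.0, 0.008, 4.0)
        expected = 150.0 * (1.0 - math.exp(-180.0 * 0.008 * 1.0))
        assert birch_hood_response(180.0, 5.0, p) == pytest.approx(expected)
        assert expected == pytest.approx(114.46, abs=0.01)

    def test_monotone_in_time_and_stimulus_and_bounded(self):
        p = PIIIParams(150.0, 0.008, 4.0)
        t = np.arange(0.0, 250.0, 0.5)
        for i in (2.5, 25.0, 1250.0):
            r = birch_hood_response(i, t, p)
            assert np.all(np.diff(r) >= -1e-12)
            assert np.all((r >= 0.0) & (r <= p.r_max + 1e-12))
        r_weak = birch_hood_response(2.5, 20.0, p)
        r_strong = birch_hood_response(1250.0, 20.0, p)
        assert r_strong >= r_weak


class TestGoodnessOfFit:
    def test_perfect_fit_is_zero(self):
        y = np.array([1.0, 2.0, 5.0])
        assert goodness_of_fit(y, y) == 0.0

    def test_mean_model_is_one(self):
        y = np.array([1.0, 2.0, 6.0])
        f = np.full(3, y.mean())
        assert goodness_of_fit(y, f) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert goodness_of_fit([0, 1, 2], [0, 1, 3]) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.floats(-100, 100))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_common_shift(self, c):
        y = np.array([0.0, 1.0, 2.0, 4.0])
        f = np.array([0.1, 0.9, 2.2, 3.9])
        assert goodness_of_fit(y + c, f + c) == pytest.approx(
            goodness_of_fit(y, f), rel=1e-9
        )


class TestPhotopicSubtract:
    def _pair(self, cfg=None):
        cfg = cfg or SyntheticConfig(noise_sd=0.0)
        meso, _ = simulate_recording(cfg, StimulusCondition(1.0, 180.0))
        photo, _ = simulate_recording(cfg, StimulusCondition(42.0, 180.0))
        return meso, photo

    def test_self_subtraction_is_zero(self):
        meso, _ = self._pair()
        out = photopic_subtract(meso, meso)
        np.testing.assert_allclose(out.values if hasattr(out, "values") else out.amplitudes, 0.0)

    def test_removes_cone_leaving_rod_truth(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        meso, truth = simulate_recording(cfg, StimulusCondition(1.0, 180.0))
        photo, _ = simulate_recording(cfg, StimulusCondition(42.0, 180.0))
        out = photopic_subtract(meso, photo, ROD_SUPPRESSING)
        np.testing.assert_allclose(out.amplitudes, truth.rod, atol=1e-9)

    def test_mismatched_stimulus_rejected(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        meso, _ = simulate_recording(cfg, StimulusCondition(1.0, 180.0))
        photo, _ = simulate_recording(cfg, StimulusCondition(42.0, 500.0))
        with pytest.raises(ValidationError, match="stimulus"):
            photopic_subtract(meso, photo)

    def test_wrong_background_rejected_when_designated(self):
        cfg = SyntheticConfig(noise_sd=0.0)
        meso, _ = simulate_recording(cfg, StimulusCondition(1.0, 180.0))
        other, _ = simulate_recording(cfg, StimulusCondition(10.0, 180.0))
        with pytest.raises(ValidationError, match="rod-suppressing"):
            photopic_subtract(meso, other, ROD_SUPPRESSING)


class TestSelectFitWindow:
    def test_saturated_piii_only_falls_back_to_cap(self):
        rec, _ = simulate_recording(piii_only_config(), StimulusCondition(0.0, 180.0))
        start, end = select_fit_window(rec)
        assert start == 0.0
        assert end == pytest.approx(35.0)

    def test_clear_trough_truncates_one_sample_before(self):
        times = np.arange(0.0, 320.5, 0.5)
        cond = StimulusCondition(0.0, 180.0)
        amps = np.interp(times, [0, 10, 28, 60, 260, 320], [0, 0, -100, 50, 50, 0])
        rec = ERGRecording("S1", times, amps, cond, baseline_corrected=True)
        _, end = select_fit_window(rec)  # trough at 18 ms after onset
        assert end == pytest.approx(17.5)

    def test_flat_waveform_rejected_without_fallback(self):
        times = np.arange(0.0, 320.5, 0.5)
        rec = ERGRecording(
            "S1", times, np.zeros_like(times), StimulusCondition(0.0, 180.0),
            baseline_corrected=True,
        )
        with pytest.raises(FitError, match="trough"):
            select_fit_window(rec)
        start, end = select_fit_window(
            rec, WindowPolicy(fallback_end_ms=20.0)
        )
        assert (start, end) == (0.0, 20.0)


class TestFitPiii:
    STIMULI = [2.5, 25.0, 180.0, 500.0, 1250.0]

    def _rod_ensemble(self, cfg, background=0.0):
        out = {}
        for stim in self.STIMULI:
            rec, _ = simulate_recording(cfg, StimulusCondition(background, stim))
            out[stim] = rec
        return out

    def test_self_consistency_recovers_truth(self):
        cfg = piii_only_config()
        fit = fit_piii(self._rod_ensemble(cfg))
        truth = cfg.piii_params_dark
        assert fit.converged
        assert fit.params.r_max == pytest.approx(truth.r_max, rel=1e-3)
        assert fit.params.s == pytest.approx(truth.s, rel=1e-3)
        assert fit.params.t_d == pytest.approx(truth.t_d, abs=0.01)
        assert fit.lsq < 1e-6

    def test_full_generator_rmax_within_two_percent(self, clean_rods, clean_cohort):
        cfg, _, _ = clean_cohort
        for bg in FIT_BACKGROUNDS:
            fit = fit_piii(clean_rods[bg])
            truth, _ = _scaled_rod_truth(cfg, bg, 1.0)
            assert fit.params.r_max == pytest.approx(truth.r_max, rel=0.02), bg

    def test_noisy_ensemble_meets_good_fit_criterion(self):
        cfg = piii_only_config(noise_sd=3.0, seed=2)
        rng = np.random.default_rng(2)
        wavs = {}
        for stim in self.STIMULI:
            rec, _ = simulate_recording(
                cfg,
                StimulusCondition(0.0, stim),
                noise=rng.normal(0.0, 3.0, size=641),
            )
            wavs[stim] = baseline_correct(rec)
        fit = fit_piii(wavs)
        assert fit.converged
        assert fit.lsq < 0.25

    def test_degenerate_all_zero_input_rejected(self):
        times = np.arange(0.0, 320.5, 0.5)
        rec = ERGRecording(
            "S1", times, np.zeros_like(times), StimulusCondition(0.0, 180.0),
            baseline_corrected=True,
        )
        with pytest.raises(FitError):
            fit_piii({180.0: rec}, windows={180.0: (0.0, 35.0)})

    def test_per_stimulus_mode_returns_one_fit_each(self):
        cfg = piii_only_config()
        fits = fit_piii(self._rod_ensemble(cfg), shared=False)
        assert set(fits) == set(self.STIMULI)
        for stim, fit in fits.items():
            assert fit.params.r_max == pytest.approx(150.0, rel=0.01), stim


class TestFitAllBackgrounds:
    def test_rmax_means_decrease_with_background(self, clean_rods):
        rods = [rec for by_stim in clean_rods.values() for rec in by_stim.values()]
        table = fit_all_backgrounds(rods, FIT_BACKGROUNDS)
        assert len(table) == len(FIT_BACKGROUNDS)  # single subject
        rmax = table.sort_values("background_cdm2")["r_max_uv"].to_numpy()
        assert np.all(np.diff(rmax) < 0)

    def test_fitted_s_similar_at_dimmest_backgrounds(self, clean_rods):
        rods = [rec for by_stim in clean_rods.values() for rec in by_stim.values()]
        table = fit_all_backgrounds(rods, [0.0, 0.01]).set_index("background_cdm2")
        assert table.loc[0.01, "s"] == pytest.approx(table.loc[0.0, "s"], rel=0.20)

    def test_missing_background_listed(self, clean_rods):
        rods = [rec for stim, rec in clean_rods[0.0].items()]
        with pytest.raises(ValidationError, match="0.01"):
            fit_all_backgrounds(rods, [0.0, 0.01])

    def test_rod_suppressing_background_unavailable(self, clean_rods):
        rods = [rec for by_stim in clean_rods.values() for rec in by_stim.values()]
        with pytest.raises(ValidationError, match="42"):
            fit_all_backgrounds(rods, [42.0])
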