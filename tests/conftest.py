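import dataclasses

import numpy as np
import pytest

from ergwave import (
    SyntheticConfig,
    baseline_correct,
    build_protocol,
    photopic_subtract_cohort,
    simulate_cohort,
)

BACKGROUNDS = [0.0, 0.01, 0.1, 1.0, 10.0, 42.0]
STIMULI = [2.5, 25.0, 180.0, 500.0, 1250.0]
FIT_BACKGROUNDS = [0.0, 0.01, 0.1, 1.0]
ROD_SUPPRESSING = 42.0


@pytest.fixture(scope="session")
def protocol():
    return build_protocol(BACKGROUNDS, STIMULI, flash_duration=250.0)


@pytest.fixture(scope="session")
def clean_cohort(protocol):
    """Noise-free single-subject cohort with unit gain: exact component truth."""
    cfg = SyntheticConfig(seed=1, noise_sd=0.0, n_subjects=1, subject_gain_cv=0.0)
    recordings, truth = simulate_cohort(cfg, protocol)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def noisy_cohort(protocol):
    """Default six-subject cohort (noise sd 3 µV, between-subject gain spread)."""
    cfg = SyntheticConfig(seed=11)
    recordings, truth = simulate_cohort(cfg, protocol)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def clean_rods(clean_cohort):
    """Photopically subtracted noise-free rod waveforms, grouped by background."""
    _, recordings, _ = clean_cohort
    rods = photopic_subtract_cohort(
        [baseline_correct(r) for r in recordings], ROD_SUPPRESSING
    )
    by_bg = {}
    for r in rods:
        by_bg.setdefault(r.condition.background_luminance, {})[
            r.condition.stimulus_luminance
        ] = r
    return by_bg


def group_by_background(rods):
    by_bg = {}
    for r in rods:
        by_bg.setdefault(r.condition.background_luminance, {})[
            r.condition.stimulus_luminance
        ] = r
    return by_bg
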