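"""Shared fixtures: desk-scale model variants and synthetic cohorts.

The full-size architectures are only *built* in tests (parameter and MAC
accounting); everything that trains uses reduced stage widths, a reduced
filter bank and a reduced sampling rate so the whole suite stays fast.
"""

import numpy as np
import pytest

from edgemi.data import default_profile, extract_window, generate_subject, make_cohort
from edgemi.models import ModelVariant, StageSpec

TEST_FS = 64.0          # desk-scale sampling rate for trained models
TEST_WINDOW = (2.0, 4.5)


def tiny_variant(name="TINY", f1=8, cs=False, bank=24):
    """A reduced variant preserving the architecture's topology."""
    return ModelVariant(name, StageSpec(f1, 16, 2, 8), StageSpec(8, 8, 1, 8),
                        uses_channel_selection=cs, spatial_bank=bank)


@pytest.fixture(scope="session")
def tiny():
    return tiny_variant()


@pytest.fixture(scope="session")
def strong_profile():
    """High-SNR, deep-ERD profile with no subject mixing (separable task)."""
    return default_profile(erd_depth=0.8, snr_db=10.0, mixing_strength=0.0,
                           depth_jitter=0.0)


@pytest.fixture(scope="session")
def windowed_trials(strong_profile):
    """96 separable trials at desk scale, imagery window extracted."""
    ts = generate_subject(strong_profile, 96, fs=TEST_FS, trial_s=7.0, seed=3)
    return extract_window(ts, *TEST_WINDOW)


@pytest.fixture(scope="session")
def small_cohort(strong_profile):
    """3 source + 1 target subjects, 2 sessions x 24 trials, desk scale."""
    src, tgt = make_cohort(3, 1, strong_profile, seed=11, n_trials=24,
                           n_sessions=2, fs=TEST_FS, trial_s=7.0)

    def window(cohort):
        cohort.subjects = [
            (sid, [extract_window(ts, *TEST_WINDOW) for ts in sess])
            for sid, sess in cohort.subjects
        ]
        return cohort

    return window(src), window(tgt)
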