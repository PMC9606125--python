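"""Shared fixtures: small synthetic cohorts and quiet configs.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from fnirsbci.hemodynamics import mbll_invert
from fnirsbci.features import concat_features, extract_features
from fnirsbci.preprocessing import (bandpass, channel_means,
                                    collect_channel_means, epoch)
from fnirsbci.synthetic import (NoiseConfig, SimulationConfig,
                                simulate_recording)


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig(seed=123)


@pytest.fixture(scope="session")
def quiet_cfg() -> SimulationConfig:
    """No noise, no inter-subject variability: analytic signal only."""
    return SimulationConfig(
        seed=7,
        noise=NoiseConfig(cardiac_uM=0, respiration_uM=0, mayer_uM=0,
                          drift_uM_per_min=0, white_uM=0),
        subject_gain_sd=0.0, channel_jitter_sd=0.0, trial_gain_sd=0.0)


def preprocess_cohort(cfg: SimulationConfig, n_subjects: int,
                      sessions=(1, 2)):
    """Run simulate -> MBLL -> filter -> epoch for a small cohort."""
    epochsets = []
    for subj in range(n_subjects):
        for sess in sessions:
            rec = simulate_recording(cfg, subj, sess)
            epochsets.append(epoch(bandpass(mbll_invert(
                rec, cfg.extinction, cfg.dpf, cfg.distance_cm))))
    return epochsets


@pytest.fixture(scope="session")
def small_cohort_features():
    """Feature matrix + channel means for a 6-subject default cohort."""
    cfg = SimulationConfig(seed=42, n_subjects=6)
    epochsets = preprocess_cohort(cfg, 6)
    fm = concat_features([extract_features(e) for e in epochsets])
    means = collect_channel_means([channel_means(e) for e in epochsets])
    return fm, means


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
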