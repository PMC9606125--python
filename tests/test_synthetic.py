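"""Synthetic cohort generator: analytic cases, determinism,
Monte-Carlo recovery of questionnaire/purchase targets."""

from __future__ import annotations

import numpy as np
import pytest

from fnirsbci.preprocessing import epoch
from fnirsbci.synthetic import (GroundTruth, NoiseConfig, SimulationConfig,
                                hemo_to_od, simulate_cohort, simulate_hemo,
                                simulate_purchases, simulate_questionnaire,
                                trial_response)


def test_zero_amplitude_zero_noise_is_identically_zero(quiet_cfg):
    cfg = SimulationConfig(
        seed=1, amplitude_scale=0.0, noise=quiet_cfg.noise,
        subject_gain_sd=0, channel_jitter_sd=0, trial_gain_sd=0)
    h = simulate_hemo(cfg, 0, 1)
    assert np.all(h.dhbo == 0) and np.all(h.dhbr == 0)


def test_noise_free_epoch_mean_matches_response_integral(quiet_cfg):
    """Single trial, unit amplitude: the 0-60 s epoch mean equals the
    numeric time-average of the configured trial response."""
    cfg = SimulationConfig(
        seed=3, trials_per_session=1, noise=quiet_cfg.noise,
        subject_gain_sd=0, channel_jitter_sd=0, trial_gain_sd=0,
        amplitude_map={1: np.ones(15), 2: np.zeros(15)})
    h = simulate_hemo(cfg, 0, 1)
    e = epoch(h)
    measured = e.trial_average()[e.task_slice()].mean(axis=0)
    fs = cfg.sampling_rate_hz
    onset = h.task_onsets()[0]
    tt = (np.arange(int(np.floor(60 * fs))) + onset) / fs - onset / fs
    oracle = trial_response(cfg, tt).mean()
    # baseline correction subtracts the (zero) pre-onset mean here
    assert np.allclose(measured, oracle, atol=1e-9)


def test_same_seed_is_bit_identical():
    cfg = SimulationConfig(seed=9)
    a = simulate_hemo(cfg, 2, 1)
    b = simulate_hemo(cfg, 2, 1)
    assert np.array_equal(a.dhbo, b.dhbo)
    assert np.array_equal(a.dhbr, b.dhbr)
    c = simulate_hemo(SimulationConfig(seed=10), 2, 1)
    assert not np.array_equal(a.dhbo, c.dhbo)


def test_events_follow_trial_structure():
    cfg = SimulationConfig(seed=0)
    h = simulate_hemo(cfg, 0, 1)
    onsets = h.task_onsets()
    assert len(onsets) == 5
    fs = cfg.sampling_rate_hz
    expected = [int(np.floor((1.0 + 61.0 * k) * fs)) for k in range(5)]
    assert onsets == expected


def test_hemo_to_od_zero_maps_to_zero(quiet_cfg):
    cfg = SimulationConfig(
        seed=1, amplitude_scale=0.0, noise=quiet_cfg.noise,
        subject_gain_sd=0, channel_jitter_sd=0, trial_gain_sd=0)
    rec = hemo_to_od(simulate_hemo(cfg, 0, 1), cfg)
    assert np.all(rec.optical_density == 0)


def test_ground_truth_stored_with_cohort():
    cfg = SimulationConfig(seed=4, n_subjects=3)
    recs, gt = simulate_cohort(cfg)
    assert len(recs) == 6
    assert len(gt.true_epoch_mean) == 6
    assert len(gt.session_effect) == 15
    assert all(v >= 0 for v in gt.session_effect)


def test_ground_truth_json_round_trip(tmp_path):
    cfg = SimulationConfig(seed=4, n_subjects=2)
    _, gt = simulate_cohort(cfg)
    p = gt.to_json(tmp_path / "gt.json")
    back = GroundTruth.from_json(p)
    assert back.amplitude_map == gt.amplitude_map
    assert back.true_epoch_mean == gt.true_epoch_mean


class TestQuestionnaire:
    def test_tiny_sd_means_everyone_scores_round_m(self, rng):
        df, _ = simulate_questionnaire(
            rng, "impulse_buying", {"g": (4.0, 1e-3, 20)})
        assert (df["score"] == 4).all()

    def test_empty_group(self, rng):
        df, report = simulate_questionnaire(
            rng, "impulse_buying", {"g": (4.0, 1.0, 0)})
        assert len(df) == 0
        assert "g" in report  # calibration still reported

    def test_invalid_sd_rejected(self, rng):
        with pytest.raises(ValueError, match="sd"):
            simulate_questionnaire(rng, "impulse_buying", {"g": (4.0, 0.0, 5)})

    def test_mean_outside_scale_rejected(self, rng):
        with pytest.raises(ValueError, match="scale"):
            simulate_questionnaire(rng, "price_discount", {"g": (5.31, 0.8, 5)})

    def test_monte_carlo_group_mean_recovery(self):
        """200 replicates: recovered group means within +-0.1 of the
        two self-report targets."""
        params = {"duty_free": (4.52, 1.35, 30), "regular": (3.26, 1.46, 30)}
        rng = np.random.default_rng(77)
        sums = {g: 0.0 for g in params}
        reps = 200
        for _ in range(reps):
            df, _ = simulate_questionnaire(rng, "impulse_buying", params)
            construct = df.groupby(["condition", "respondent_id"])["score"].mean()
            for g in params:
                sums[g] += construct.loc[g].mean()
        for g, (m, _, _) in params.items():
            assert abs(sums[g] / reps - m) < 0.1

    def test_clipping_rate_reported_for_infeasible_sd(self, rng):
        _, report = simulate_questionnaire(
            rng, "impulse_buying", {"g": (4.52, 1.35, 10)})
        assert report["g"]["clipping_rate"] > 0.1
        assert report["g"]["achievable_item_sd"] < report["g"]["latent_sigma"]


class TestPurchases:
    def test_zero_sum_all_zero(self, rng):
        df = simulate_purchases(rng, {1: {"cosmetics": (0, 0.5)}}, 30)
        assert (df["count"] == 0).all()

    def test_saturated_sum_all_fives(self, rng):
        df = simulate_purchases(rng, {1: {"alcohol": (150, 1.0)}}, 30)
        assert (df["count"] == 5).all()

    def test_infeasible_sum_rejected(self, rng):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_purchases(rng, {1: {"alcohol": (151, 1.0)}}, 30)

    def test_monte_carlo_sum_recovery(self):
        rng = np.random.default_rng(88)
        total = 0.0
        reps = 200
        for _ in range(reps):
            df = simulate_purchases(rng, {1: {"alcohol": (60, 1.26)}}, 30)
            total += df["count"].sum()
        assert abs(total / reps - 60) < 3


def test_channel_tests_track_true_effect_ranking():
    """Channels with the largest injected session effects are the ones
    the downstream t-tests flag (rank agreement with ground truth)."""
    from scipy.stats import spearmanr
    from fnirsbci.pipeline import cohort_analysis
    from fnirsbci import stats as fstats

    cfg = SimulationConfig(seed=21, n_subjects=12)
    _, gt = simulate_cohort(cfg)
    res = cohort_analysis(cfg, classify=False)
    cc = fstats.channel_contrast(res["channel_means"]).sort_values("channel")
    rho = spearmanr(np.abs(cc["t"]), gt.session_effect).statistic
    assert rho > 0.5
    top_channel = int(np.argmax(gt.session_effect)) + 1
    assert bool(cc.loc[cc["channel"] == top_channel, "significant"].iloc[0])


def test_noise_config_defaults_are_positive():
    nz = NoiseConfig()
    assert nz.cardiac_hz > nz.respiration_hz > nz.mayer_hz
    assert 0 <= nz.local_fraction <= 1
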