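"""Synthetic two-condition fNIRS cohort generator.

Emulates the study design the analysis assumes: 30 subjects, two
sessions (1 = impulse-buying task, 2 = control shopping task), five
trials per session, each trial 1 s cue + 25 s task + 35 s rest, 15
prefrontal channels sampled at 8.138 Hz at 780/850 nm.

Per channel, the clean signal is a canonical double-gamma hemodynamic
response at each task onset scaled by a session- and channel-specific
amplitude (uM).  The default amplitude maps encode the qualitative
session contrast of the study's topography — session 1 dominated by
medial PFC and left ventrolateral PFC, session 2 broadly active over
DLPFC/mPFC/OFC — and are NOT estimates of the study's effect sizes.
Physiological noise adds cardiac (~1 Hz), respiratory (~0.3 Hz) and
Mayer-wave (~0.1 Hz) oscillations, a slow linear drift, and white
noise; subjects get a shared multiplicative response gain and
per-channel jitter so cohort-level variability is realistic.

dHbR is generated as an anticorrelated fraction of dHbO plus its own
noise; downstream analysis uses dHbO only.  Concentrations are mapped
to optical density with the forward modified Beer-Lambert law, so the
generator output enters the pipeline exactly where a recording from
the instrument would.

All randomness derives from a single integer seed through numpy
SeedSequence -> PCG64 generators keyed per subject/session stream, so
cohorts are reproducible bit-for-bit across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm
from scipy.optimize import brentq

from .hemodynamics import (DEFAULT_DPF, DEFAULT_EXTINCTION_UM_CM,
                           HemoTimeSeries, mbll_forward)
from .io import (CATEGORIES, DEFAULT_WAVELENGTHS, Event, RawRecording,
                 validate_purchases, validate_questionnaire)
from .montage import N_CHANNELS, ProbeLayout, default_layout

__all__ = [
    "NoiseConfig",
    "SimulationConfig",
    "GroundTruth",
    "canonical_hrf",
    "trial_response",
    "simulate_hemo",
    "hemo_to_od",
    "simulate_recording",
    "simulate_cohort",
    "simulate_questionnaire",
    "simulate_purchases",
    "default_amplitude_maps",
]

#: Construct -> number of questionnaire items (3 impulse-buying items,
#: 6 time-pressure items, 3 price-discount items).
CONSTRUCT_ITEMS = {"impulse_buying": 3, "time_pressure": 6, "price_discount": 3}


@dataclass(frozen=True)
class NoiseConfig:
    """Additive physiological + instrument noise (amplitudes in uM).

    Cardiac, respiratory and Mayer-wave oscillations are systemic: one
    global waveform per recording couples into every channel with a
    channel-specific gain (``coupling_sd`` spread around 1) plus a
    smaller channel-independent residual (``local_fraction`` of the
    amplitude).  White sensor noise is independent per channel.
    """

    cardiac_hz: float = 1.0
    cardiac_uM: float = 0.30
    respiration_hz: float = 0.30
    respiration_uM: float = 0.20
    mayer_hz: float = 0.10
    mayer_uM: float = 0.08
    drift_uM_per_min: float = 0.10
    white_uM: float = 0.10
    coupling_sd: float = 0.30
    local_fraction: float = 0.20


def default_amplitude_maps(layout: ProbeLayout | None = None) -> dict[int, np.ndarray]:
    """Session -> per-channel peak dHbO amplitude (uM).

    Session 1: medial PFC strongest, left VLPFC clearly active, a mild
    right-over-left ventrolateral bias; session 2: broad DLPFC/mPFC/OFC
    activation with quiet VLPFC.  The maps differ on every channel so
    that the per-channel session contrast is marked throughout, as in
    the study topography; values are plausible task-evoked peak dHbO
    amplitudes, not estimates of the study's effect sizes.
    """
    layout = layout or default_layout()
    by_roi = {
        1: {"mPFC": 0.55, "VLPFC_L": 0.30, "VLPFC_R": 0.18, "DLPFC": 0.08, "OFC": 0.08},
        2: {"mPFC": 0.35, "VLPFC_L": 0.05, "VLPFC_R": 0.05, "DLPFC": 0.45, "OFC": 0.45},
    }
    maps = {}
    for session, table in by_roi.items():
        amp = np.array([table[layout.roi[ch]] for ch in layout.channel_ids])
        maps[session] = amp
    return maps


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; ``seed`` fixes every draw."""

    n_subjects: int = 30
    trials_per_session: int = 5
    cue_s: float = 1.0
    task_s: float = 25.0
    rest_s: float = 35.0
    sampling_rate_hz: float = 8.138
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    response: str = "sustained"         # "sustained" (boxcar x HRF) | "impulse"
    amplitude_map: dict[int, np.ndarray] = field(default_factory=default_amplitude_maps)
    amplitude_scale: float = 1.0
    hbr_ratio: float = -0.3
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    subject_gain_sd: float = 0.20       # log-normal sigma of per-subject gain
    channel_jitter_sd: float = 0.10     # per-channel multiplicative jitter
    trial_gain_sd: float = 0.20         # per-trial multiplicative jitter
    dpf: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_DPF))
    extinction: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION_UM_CM))
    distance_cm: float = 3.0
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    seed: int = 0

    @property
    def trial_s(self) -> float:
        return self.cue_s + self.task_s + self.rest_s

    @property
    def session_s(self) -> float:
        return self.trials_per_session * self.trial_s

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.session_s * self.sampling_rate_hz))

    def validate(self) -> "SimulationConfig":
        for name in ("cue_s", "task_s", "rest_s", "sampling_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for sess, amp in self.amplitude_map.items():
            if not np.all(np.isfinite(amp)):
                raise ValueError(f"amplitude_map[{sess}] contains non-finite values")
        return self

    def subject_rng(self, subject: int, stream: str) -> np.random.Generator:
        # stable child seeds: one entropy tuple per (seed, subject, stream)
        ss = np.random.SeedSequence(
            [self.seed, subject, sum(ord(c) for c in stream)])
        return np.random.default_rng(ss)


def canonical_hrf(t: np.ndarray, peak_s: float = 6.0,
                  undershoot_s: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Double-gamma hemodynamic response, unit peak amplitude, h(t<0)=0."""
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    h[pos] = (gamma_dist.pdf(tp, peak_s + 1.0)
              - undershoot_ratio * gamma_dist.pdf(tp, undershoot_s + 1.0))
    peak = h.max()
    if peak > 0:
        h /= peak
    return h


def trial_response(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Unit-peak per-trial response evaluated at times ``t`` (s from onset).

    ``"impulse"`` is the bare canonical HRF; the default
    ``"sustained"`` convolves it with the task boxcar (a neurally
    sustained 25 s task), which is what a block task evokes.
    """
    t = np.asarray(t, dtype=float)
    if cfg.response == "impulse":
        return canonical_hrf(t, cfg.hrf_peak_s, cfg.hrf_undershoot_s,
                             cfg.hrf_undershoot_ratio)
    if cfg.response != "sustained":
        raise ValueError(f"unknown response form {cfg.response!r}")
    fs = cfg.sampling_rate_hz
    support = cfg.task_s + cfg.rest_s
    tt = np.arange(0.0, support, 1.0 / fs)
    h = canonical_hrf(tt, cfg.hrf_peak_s, cfg.hrf_undershoot_s,
                      cfg.hrf_undershoot_ratio)
    box = np.ones(max(1, int(np.floor(cfg.task_s * fs))))
    r = np.convolve(h, box)[:tt.size]
    r /= np.abs(r).max()
    out = np.zeros_like(t)
    mask = (t >= 0) & (t < support)
    idx = np.clip(np.searchsorted(tt, t[mask]), 0, r.size - 1)
    out[mask] = r[idx]
    return out


def _event_schedule(cfg: SimulationConfig) -> list[Event]:
    fs = cfg.sampling_rate_hz
    events = []
    for trial in range(cfg.trials_per_session):
        t0 = trial * cfg.trial_s
        events.append(Event(int(np.floor(t0 * fs)), "cue", trial))
        events.append(Event(int(np.floor((t0 + cfg.cue_s) * fs)), "task_start", trial))
        events.append(Event(
            int(np.floor((t0 + cfg.cue_s + cfg.task_s) * fs)), "task_end", trial))
        rest_end = min(cfg.n_samples - 1, int(np.floor((t0 + cfg.trial_s) * fs)))
        events.append(Event(rest_end, "rest_end", trial))
    return events


def simulate_hemo(cfg: SimulationConfig, subject: int,
                  session: int) -> HemoTimeSeries:
    """One subject-session of clean response + physiological noise (uM)."""
    cfg.validate()
    if session not in cfg.amplitude_map:
        raise ValueError(f"no amplitude map for session {session}")
    fs = cfg.sampling_rate_hz
    n = cfg.n_samples
    t = np.arange(n) / fs

    gain_rng = cfg.subject_rng(subject, "gain")
    subject_gain = float(np.exp(gain_rng.normal(0.0, cfg.subject_gain_sd)))
    channel_jitter = 1.0 + gain_rng.normal(0.0, cfg.channel_jitter_sd, N_CHANNELS)

    rng = cfg.subject_rng(subject, f"session{session}")
    amp = (np.asarray(cfg.amplitude_map[session], dtype=float)
           * cfg.amplitude_scale * subject_gain * channel_jitter)

    signal = np.zeros((n, N_CHANNELS))
    events = _event_schedule(cfg)
    trial_gains = 1.0 + rng.normal(0.0, cfg.trial_gain_sd, cfg.trials_per_session)
    for ev in events:
        if ev.kind != "task_start":
            continue
        onset_s = ev.onset_sample / fs
        h = trial_response(cfg, t - onset_s)
        signal += trial_gains[ev.trial_index] * h[:, None] * amp[None, :]

    nz = cfg.noise

    def oscillation(freq: float, amp_uM: float) -> np.ndarray:
        # systemic: one global waveform, channel-specific coupling gain,
        # plus a smaller channel-independent residual
        phase = rng.uniform(0, 2 * np.pi)
        coupling = 1.0 + nz.coupling_sd * rng.standard_normal(N_CHANNELS)
        common = np.sin(2 * np.pi * freq * t + phase)[:, None] * coupling[None, :]
        local_phases = rng.uniform(0, 2 * np.pi, N_CHANNELS)
        local = np.sin(2 * np.pi * freq * t[:, None] + local_phases[None, :])
        return amp_uM * (common + nz.local_fraction * local)

    noise = (oscillation(nz.cardiac_hz, nz.cardiac_uM)
             + oscillation(nz.respiration_hz, nz.respiration_uM)
             + oscillation(nz.mayer_hz, nz.mayer_uM))
    slopes = rng.normal(0.0, nz.drift_uM_per_min, N_CHANNELS) / 60.0
    noise += slopes[None, :] * t[:, None]
    noise += nz.white_uM * rng.standard_normal((n, N_CHANNELS))

    dhbo = signal + noise
    dhbr = cfg.hbr_ratio * signal + 0.5 * nz.white_uM * rng.standard_normal(
        (n, N_CHANNELS))
    return HemoTimeSeries(
        subject_id=f"S{subject:02d}", session=session, sampling_rate=fs,
        dhbo=dhbo, dhbr=dhbr, events=events).validate()


def hemo_to_od(h: HemoTimeSeries, cfg: SimulationConfig) -> RawRecording:
    """Forward MBLL: concentrations -> two-wavelength optical density."""
    m_check = np.array([cfg.extinction[wl] for wl in cfg.wavelengths], float)
    if abs(np.linalg.det(m_check)) < 1e-30:
        raise ValueError("extinction matrix is singular")
    od = mbll_forward(h.dhbo, h.dhbr, cfg.wavelengths, cfg.extinction,
                      cfg.dpf, cfg.distance_cm)
    return RawRecording(
        subject_id=h.subject_id, session=h.session,
        sampling_rate=h.sampling_rate, optical_density=od,
        events=list(h.events), wavelengths=cfg.wavelengths,
    ).validate(expect_task_starts=None)


def simulate_recording(cfg: SimulationConfig, subject: int,
                       session: int) -> RawRecording:
    return hemo_to_od(simulate_hemo(cfg, subject, session), cfg)


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter recovery."""

    # (subject, session) -> expected noise-free epoch-mean dHbO per channel
    true_epoch_mean: dict[str, list[float]] = field(default_factory=dict)
    # session -> configured amplitude map
    amplitude_map: dict[int, list[float]] = field(default_factory=dict)
    # channel -> |session contrast| of the cohort-expected epoch means
    session_effect: list[float] = field(default_factory=list)
    questionnaire_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(asdict(self), indent=1))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        gt = cls(**{k: raw[k] for k in ("true_epoch_mean", "session_effect",
                                        "questionnaire_params")})
        gt.amplitude_map = {int(k): v for k, v in raw["amplitude_map"].items()}
        return gt


def _response_epoch_mean(cfg: SimulationConfig,
                         window_s: tuple[float, float] = (0.0, 60.0)) -> float:
    """Time-average of the unit trial response over the analysis window."""
    fs = cfg.sampling_rate_hz
    n0, n1 = int(np.floor(window_s[0] * fs)), int(np.floor(window_s[1] * fs))
    tt = np.arange(n0, n1) / fs
    return float(np.mean(trial_response(cfg, tt)))


def simulate_cohort(cfg: SimulationConfig,
                    sessions: tuple[int, ...] = (1, 2),
                    ) -> tuple[list[RawRecording], GroundTruth]:
    """Full cohort of recordings plus the injected ground truth."""
    cfg.validate()
    hmean = _response_epoch_mean(cfg)
    gt = GroundTruth(
        amplitude_map={s: list(map(float, cfg.amplitude_map[s]))
                       for s in sessions})
    recs: list[RawRecording] = []
    expected = {s: np.zeros(N_CHANNELS) for s in sessions}
    for subject in range(cfg.n_subjects):
        gain_rng = cfg.subject_rng(subject, "gain")
        subject_gain = float(np.exp(gain_rng.normal(0.0, cfg.subject_gain_sd)))
        channel_jitter = 1.0 + gain_rng.normal(0.0, cfg.channel_jitter_sd, N_CHANNELS)
        for session in sessions:
            amp = (np.asarray(cfg.amplitude_map[session], float)
                   * cfg.amplitude_scale * subject_gain * channel_jitter)
            truth = amp * hmean
            gt.true_epoch_mean[f"S{subject:02d}/{session}"] = list(map(float, truth))
            expected[session] += truth / cfg.n_subjects
            recs.append(simulate_recording(cfg, subject, session))
    if len(sessions) == 2:
        s1, s2 = sessions
        gt.session_effect = list(map(float, np.abs(expected[s1] - expected[s2])))
    return recs, gt


# ---------------------------------------------------------------------------
# questionnaire


def _discrete_stats(mu: float, sigma: float) -> tuple[float, float, float]:
    """Mean, sd and clipping rate of clip(round(N(mu, sigma)), 1, 5)."""
    cuts = np.array([1.5, 2.5, 3.5, 4.5])
    cdf = norm.cdf((cuts - mu) / sigma)
    probs = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    scores = np.arange(1, 6)
    mean = float(np.sum(scores * probs))
    var = float(np.sum((scores - mean) ** 2 * probs))
    clip_rate = float(norm.cdf((0.5 - mu) / sigma) + norm.sf((5.5 - mu) / sigma))
    return mean, np.sqrt(var), clip_rate


def _calibrate_latent_mean(target_mean: float, sigma: float) -> float:
    """mu of the latent Gaussian whose discretized mean equals the target."""
    def f(mu: float) -> float:
        return _discrete_stats(mu, sigma)[0] - target_mean
    return brentq(f, -20.0, 26.0, xtol=1e-10)


def simulate_questionnaire(
    rng: np.random.Generator,
    construct: str,
    group_params: Mapping[str, tuple[float, float, int]],
    n_items: int | None = None,
    item_correlation: float = 0.7,
    genders: Mapping[str, list[str]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Likert tables whose group means match targets in expectation.

    ``group_params`` maps condition label -> (M, sd, n).  Items share a
    respondent-level latent factor (loading sqrt(item_correlation)) so
    internal consistency is realistic; each item score is the latent
    Gaussian rounded to the nearest integer and clipped to 1..5.  The
    latent mean is calibrated so the discretized score mean equals M
    exactly in expectation; sds above what the 1..5 scale supports are
    flagged via the reported clipping rate and achievable sd.
    """
    if construct not in CONSTRUCT_ITEMS:
        raise ValueError(f"unknown construct {construct!r}")
    if n_items is None:
        n_items = CONSTRUCT_ITEMS[construct]
    rho = float(item_correlation)
    rows = []
    report: dict[str, dict] = {}
    for condition, (m, sd, n) in group_params.items():
        if sd <= 0:
            raise ValueError(f"{condition}: sd must be > 0, got {sd}")
        if not 1.0 <= m <= 5.0:
            raise ValueError(f"{condition}: mean {m} outside the 1..5 scale")
        # respondent-construct sd target -> per-item latent sigma
        shrink = np.sqrt(rho + (1.0 - rho) / n_items)
        sigma = sd / shrink
        mu = _calibrate_latent_mean(m, sigma)
        ach_mean, ach_sd, clip_rate = _discrete_stats(mu, sigma)
        report[condition] = {
            "target_mean": m, "target_sd": sd,
            "latent_mu": mu, "latent_sigma": sigma,
            "achievable_item_mean": ach_mean,
            "achievable_item_sd": ach_sd,
            "clipping_rate": clip_rate,
        }
        if n == 0:
            continue
        gender_list = (genders or {}).get(condition)
        if gender_list is None:
            # 13 male / 17 female split of the default 30-subject cohort
            n_male = int(round(n * 13 / 30))
            gender_list = ["male"] * n_male + ["female"] * (n - n_male)
        latent = rng.standard_normal(n)
        for i in range(n):
            item_noise = rng.standard_normal(n_items)
            z = np.sqrt(rho) * latent[i] + np.sqrt(1 - rho) * item_noise
            raw = mu + sigma * z
            scores = np.clip(np.rint(raw), 1, 5).astype(int)
            for j, s in enumerate(scores):
                rows.append({
                    "respondent_id": f"{condition}-{i:02d}",
                    "construct": construct,
                    "item_id": f"{construct}_{j + 1}",
                    "score": int(s),
                    "condition": condition,
                    "gender": gender_list[i],
                })
    df = pd.DataFrame(
        rows, columns=["respondent_id", "construct", "item_id", "score",
                       "condition", "gender"])
    return validate_questionnaire(df), report


# ---------------------------------------------------------------------------
# purchases


def simulate_purchases(
    rng: np.random.Generator,
    session_sums: Mapping[int, Mapping[str, tuple[float, float]]],
    n_subjects: int = 30,
    max_per_category: int = 5,
) -> pd.DataFrame:
    """Per-subject purchase counts whose category sums match in expectation.

    ``session_sums`` maps session -> {category: (SUM, sd)}.  Counts are
    beta-binomial(5) when the target across-subject sd exceeds the
    binomial sd (moment-matched overdispersion), binomial otherwise.
    """
    rows = []
    for session, cats in session_sums.items():
        for category, (total, sd) in cats.items():
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r}")
            if not 0 <= total <= max_per_category * n_subjects:
                raise ValueError(
                    f"{category}: SUM={total} infeasible for {n_subjects} subjects "
                    f"x {max_per_category} items")
            p = total / (max_per_category * n_subjects)
            if p in (0.0, 1.0):
                counts = np.full(n_subjects, int(round(p * max_per_category)))
            else:
                v_binom = max_per_category * p * (1 - p)
                rho = 0.0
                if sd is not None and sd ** 2 > v_binom:
                    rho = min((sd ** 2 / v_binom - 1) / (max_per_category - 1), 0.95)
                if rho > 0:
                    a = p * (1 / rho - 1)
                    b = (1 - p) * (1 / rho - 1)
                    ps = rng.beta(a, b, n_subjects)
                else:
                    ps = np.full(n_subjects, p)
                counts = rng.binomial(max_per_category, ps)
            for i, c in enumerate(counts):
                rows.append({
                    "respondent_id": f"S{i:02d}",
                    "session": session,
                    "category": category,
                    "count": int(c),
                })
    df = pd.DataFrame(rows, columns=["respondent_id", "session", "category", "count"])
    return validate_purchases(df)


#: Category sums and across-subject sds reported for the two shopping
#: sessions; used as the generator's default behavioral targets.
DEFAULT_PURCHASE_SUMS: dict[int, dict[str, tuple[float, float]]] = {
    1: {"cosmetics": (47, 1.05), "alcohol": (60, 1.26),
        "health supplements": (46, 0.99), "cigarettes": (19, 0.60),
        "perfumes": (42, 0.84)},
    2: {"cosmetics": (38, 0.63), "alcohol": (40, 0.91),
        "health supplements": (37, 0.67), "cigarettes": (17, 0.62),
        "perfumes": (28, 0.44)},
}

#: Default self-report targets: impulse-buying construct per shopping
#: condition (duty-free vs. regular online store).
DEFAULT_QUESTIONNAIRE_PARAMS: dict[str, dict[str, tuple[float, float, int]]] = {
    "impulse_buying": {"session1": (4.52, 1.35, 30), "session2": (3.26, 1.46, 30)},
    "time_pressure": {"high": (4.48, 0.95, 30), "low": (3.19, 0.90, 30)},
    "price_discount": {"session1": (4.04, 1.29, 30), "session2": (3.50, 1.20, 30)},
}
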