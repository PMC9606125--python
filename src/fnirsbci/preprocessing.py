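"""Band-pass filtering, epoching, baseline correction, channel means.

The hemodynamic band of interest is 0.01-0.1 Hz.  The default filter
is a 4th-order Chebyshev type-II band-pass applied forward-backward
(zero phase); type II puts its ripple in the stopband, so the passband
is flat, and the two-pass application doubles the stopband attenuation
while leaving epoch timing untouched.  A linear-phase FIR design is
available behind ``method="fir"``.

Epochs span -1..60 s around each task onset (floor(61 s x 8.138 Hz) =
496 samples: 8 baseline + 488 task/rest samples) and are baseline
corrected by subtracting the -1..0 s mean.  Sample intervals are
half-open, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .hemodynamics import HemoTimeSeries

__all__ = [
    "EpochSet",
    "bandpass",
    "design_bandpass_sos",
    "epoch",
    "channel_means",
    "collect_channel_means",
]

SESSION_LABELS = {1: "impulse", 2: "non-impulse"}


def design_bandpass_sos(fs: float, low_hz: float = 0.01, high_hz: float = 0.1,
                        order: int = 4, attenuation_db: float = 40.0,
                        stop_factor: float = 2.5) -> np.ndarray:
    """Chebyshev-II band-pass as second-order sections.

    ``low_hz``/``high_hz`` are the passband edges; the stopband edges
    sit a factor ``stop_factor`` outside them, where the single-pass
    response is ``attenuation_db`` down.
    """
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyq:.3g}) Hz")
    stop = [low_hz / stop_factor, min(high_hz * stop_factor, 0.99 * nyq)]
    return sps.cheby2(order, attenuation_db, stop, btype="bandpass",
                      fs=fs, output="sos")


def bandpass(h: HemoTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4, attenuation_db: float = 40.0,
             zero_phase: bool = True, method: str = "cheby2",
             stop_factor: float = 2.5) -> HemoTimeSeries:
    """Band-pass both concentration series; events pass through unchanged."""
    fs = h.sampling_rate
    if h.n_samples <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    if method == "cheby2":
        sos = design_bandpass_sos(fs, low_hz, high_hz, order,
                                  attenuation_db, stop_factor)
        if zero_phase:
            filt = lambda x: sps.sosfiltfilt(sos, x, axis=0)
        else:
            filt = lambda x: sps.sosfilt(sos, x, axis=0)
    elif method == "fir":
        nyq = fs / 2.0
        if not 0 < low_hz < high_hz < nyq:
            raise ValueError(
                f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyq:.3g}) Hz")
        ntaps = min(int(2 * fs / low_hz), h.n_samples // 4) | 1
        taps = sps.firwin(ntaps, [low_hz, high_hz], pass_zero=False, fs=fs)
        filt = lambda x: sps.filtfilt(taps, [1.0], x, axis=0,
                                      padlen=min(ntaps, h.n_samples - 1))
    else:
        raise ValueError(f"unknown filter method {method!r}")
    return replace(h, dhbo=filt(h.dhbo), dhbr=filt(h.dhbr)).validate()


@dataclass
class EpochSet:
    """Baseline-corrected -1..60 s windows, one per trial."""

    subject_id: str
    session: int
    sampling_rate: float
    epochs: np.ndarray            # (trial, time, channel), dHbO in uM
    times: np.ndarray             # (time,) seconds relative to task onset
    n_baseline: int               # leading samples covering -1..0 s
    baseline_window_s: tuple[float, float] = (-1.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = SESSION_LABELS.get(self.session, str(self.session))

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[1]

    def trial_average(self) -> np.ndarray:
        """(time, channel) mean time course across trials."""
        return self.epochs.mean(axis=0)

    def task_slice(self) -> slice:
        """Samples covering the 0..60 s analysis window."""
        return slice(self.n_baseline, self.n_times)


def epoch(h: HemoTimeSeries, pre_s: float = 1.0, post_s: float = 60.0,
          signal: str = "dhbo") -> EpochSet:
    """Cut baseline-corrected epochs around every task onset."""
    fs = h.sampling_rate
    n_pre = int(np.floor(pre_s * fs))
    n_post = int(np.floor(post_s * fs))
    onsets = h.task_onsets()
    if not onsets:
        raise ValueError("recording has no task_start events")
    data = getattr(h, signal)
    epochs = []
    for trial, onset in enumerate(onsets):
        start, stop = onset - n_pre, onset + n_post
        if start < 0 or stop > h.n_samples:
            raise ValueError(
                f"trial {trial}: epoch [{start}, {stop}) outside recording "
                f"of {h.n_samples} samples")
        win = data[start:stop].copy()
        win -= win[:n_pre].mean(axis=0, keepdims=True)
        epochs.append(win)
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    return EpochSet(
        subject_id=h.subject_id, session=h.session, sampling_rate=fs,
        epochs=np.stack(epochs), times=times, n_baseline=n_pre,
        baseline_window_s=(-pre_s, 0.0))


def channel_means(e: EpochSet) -> pd.DataFrame:
    """Temporal mean of dHbO over 0..60 s per channel.

    Trials are averaged first, then time; the two averages commute for
    equal-length epochs, so the order is a documentation choice.
    """
    avg = e.trial_average()[e.task_slice()]  # (time, channel)
    vals = avg.mean(axis=0)
    return pd.DataFrame({
        "subject": e.subject_id,
        "session": e.session,
        "channel": np.arange(1, vals.size + 1),
        "mean_dhbo": vals,
    })


def collect_channel_means(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-subject-session channel means into one tidy table."""
    out = pd.concat(frames, ignore_index=True)
    dup = out.duplicated(["subject", "session", "channel"])
    if dup.any():
        raise ValueError("duplicate (subject, session, channel) entries")
    return out
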