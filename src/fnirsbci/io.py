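"""Recording and table I/O.

Recordings are optical-density time series (time x 15 channels x 2
wavelengths) with event markers.  Two on-disk formats are supported:

* SNIRF — a minimal SNIRF v1.0 HDF5 layout written with h5py: one
  ``/nirs1/data1`` block whose 30 measurement-list entries are
  channel-major (ch1@780, ch1@850, ch2@780, ...) processed ``dOD``
  channels, plus one ``stim`` group per event kind.
* CSV — a long table ``time_s, channel, wavelength_nm, od`` with an
  ``<stem>.events.csv`` sidecar (``onset_sample, kind, trial_index``;
  onsets are 0-based sample indices) and an ``<stem>.meta.json``
  sidecar carrying subject, session, and sampling rate.

Questionnaire and purchase-count tables are plain CSV read into
pandas DataFrames and validated against their schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd

from .montage import N_CHANNELS

__all__ = [
    "Event",
    "RawRecording",
    "ValidationError",
    "read_recording",
    "write_recording",
    "read_questionnaire",
    "write_questionnaire",
    "validate_questionnaire",
    "read_purchases",
    "write_purchases",
    "validate_purchases",
]

DEFAULT_WAVELENGTHS = (780.0, 850.0)
EVENT_KINDS = ("cue", "task_start", "task_end", "rest_end")
CONSTRUCTS = ("impulse_buying", "time_pressure", "price_discount")
CATEGORIES = ("cosmetics", "alcohol", "health supplements", "cigarettes", "perfumes")


class ValidationError(ValueError):
    """Input data violates the recording or table schema."""


@dataclass(frozen=True)
class Event:
    """An experiment marker at a 0-based sample index."""
    onset_sample: int
    kind: str
    trial_index: int


@dataclass
class RawRecording:
    """One subject-session of two-wavelength optical density."""

    subject_id: str
    session: int
    sampling_rate: float
    optical_density: np.ndarray  # (time, channel, wavelength)
    events: list[Event] = field(default_factory=list)
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS

    @property
    def n_samples(self) -> int:
        return self.optical_density.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def task_onsets(self) -> list[int]:
        return [e.onset_sample for e in self.events if e.kind == "task_start"]

    def validate(self, expect_task_starts: int | None = 5) -> "RawRecording":
        od = np.asarray(self.optical_density)
        if od.ndim != 3:
            raise ValidationError(
                f"optical_density: expected 3-d (time, channel, wavelength), got {od.ndim}-d")
        if od.shape[1] != N_CHANNELS:
            raise ValidationError(
                f"optical_density: expected {N_CHANNELS} channels, got {od.shape[1]}")
        if od.shape[2] != 2 or len(self.wavelengths) != 2:
            raise ValidationError("optical_density: expected exactly 2 wavelengths")
        if not np.all(np.isfinite(od)):
            raise ValidationError("optical_density: contains non-finite values")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate: must be > 0, got {self.sampling_rate}")
        if self.session not in (1, 2):
            raise ValidationError(f"session: must be 1 or 2, got {self.session}")
        onsets = [e.onset_sample for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            first_bad = next(b for a, b in zip(onsets, onsets[1:]) if b < a)
            raise ValidationError(
                f"events: onsets not time-ordered (first offending onset {first_bad})")
        for e in self.events:
            if e.kind not in EVENT_KINDS:
                raise ValidationError(f"events: unknown kind {e.kind!r}")
            if not 0 <= e.onset_sample < od.shape[0]:
                raise ValidationError(
                    f"events: onset {e.onset_sample} outside recording "
                    f"of {od.shape[0]} samples")
        if expect_task_starts is not None:
            n_task = len(self.task_onsets())
            if n_task != expect_task_starts:
                raise ValidationError(
                    f"events: expected {expect_task_starts} task_start markers, got {n_task}")
        return self

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (self.subject_id == other.subject_id
                and self.session == other.session
                and np.isclose(self.sampling_rate, other.sampling_rate)
                and self.wavelengths == other.wavelengths
                and self.events == other.events
                and self.optical_density.shape == other.optical_density.shape
                and np.array_equal(self.optical_density, other.optical_density))


# ---------------------------------------------------------------------------
# SNIRF


def _write_snirf(rec: RawRecording, path: Path) -> None:
    n_time = rec.n_samples
    data = rec.optical_density.reshape(n_time, N_CHANNELS * 2)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs1")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=str(rec.subject_id))
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("Session", data=str(rec.session))
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=rec.times)
        from .montage import DEFAULT_PAIRS, DEFAULT_POSITIONS
        for ch in range(1, N_CHANNELS + 1):
            src, det = DEFAULT_PAIRS[ch]
            for wi in (1, 2):
                ml = d1.create_group(f"measurementList{(ch - 1) * 2 + wi}")
                ml.create_dataset("sourceIndex", data=src)
                ml.create_dataset("detectorIndex", data=det)
                ml.create_dataset("wavelengthIndex", data=wi)
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset("dataTypeLabel", data="dOD")
                ml.create_dataset("dataTypeIndex", data=ch)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))
        pos = np.array([DEFAULT_POSITIONS[ch] for ch in range(1, N_CHANNELS + 1)])
        probe.create_dataset("sourcePos2D", data=pos[:5])
        probe.create_dataset("detectorPos2D", data=pos[:7])
        for i, kind in enumerate(EVENT_KINDS, start=1):
            evs = [e for e in rec.events if e.kind == kind]
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=kind)
            rows = np.array(
                [[e.onset_sample / rec.sampling_rate, 0.0, float(e.trial_index)]
                 for e in evs], dtype=float).reshape(len(evs), 3)
            stim.create_dataset("data", data=rows)


def _read_str(ds) -> str:
    val = ds[()]
    return val.decode() if isinstance(val, bytes) else str(val)


def _read_snirf(path: Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs1"]
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"])
        times = np.asarray(d1["time"])
        if data.shape[1] != N_CHANNELS * 2:
            raise ValidationError(
                f"{path}: expected {N_CHANNELS * 2} measurement columns "
                f"({N_CHANNELS} channels), got {data.shape[1]}")
        if times.size > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValidationError(f"{path}: time vector not strictly increasing")
            fs = 1.0 / float(np.mean(dt))
        else:
            raise ValidationError(f"{path}: time vector too short")
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
        if len(wavelengths) != 2:
            raise ValidationError(f"{path}: expected 2 wavelengths, got {len(wavelengths)}")
        subject = _read_str(nirs["metaDataTags/SubjectID"])
        session = int(_read_str(nirs["metaDataTags/Session"]))
        events: list[Event] = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[key]
            kind = _read_str(stim["name"])
            for onset_s, _dur, trial in np.asarray(stim["data"]).reshape(-1, 3):
                events.append(Event(int(round(onset_s * fs)), kind, int(trial)))
        # ties: a trial's rest_end precedes the next trial's cue
        events.sort(key=lambda e: (e.onset_sample, e.trial_index,
                                   EVENT_KINDS.index(e.kind)))
    rec = RawRecording(
        subject_id=subject, session=session, sampling_rate=fs,
        optical_density=data.reshape(-1, N_CHANNELS, 2),
        events=events, wavelengths=wavelengths)
    return rec.validate(expect_task_starts=None)


# ---------------------------------------------------------------------------
# long CSV


def _write_csv(rec: RawRecording, path: Path) -> None:
    t = rec.times
    n = rec.n_samples
    rows = {
        "time_s": np.repeat(t, N_CHANNELS * 2),
        "channel": np.tile(np.repeat(np.arange(1, N_CHANNELS + 1), 2), n),
        "wavelength_nm": np.tile(np.asarray(rec.wavelengths), n * N_CHANNELS),
        "od": rec.optical_density.reshape(-1),
    }
    # %.17g guarantees exact float64 round trip through text
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    ev = pd.DataFrame(
        [(e.onset_sample, e.kind, e.trial_index) for e in rec.events],
        columns=["onset_sample", "kind", "trial_index"])
    ev.to_csv(path.with_suffix(".events.csv"), index=False)
    meta = {
        "subject_id": rec.subject_id,
        "session": rec.session,
        "sampling_rate_hz": rec.sampling_rate,
        "wavelengths_nm": list(rec.wavelengths),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def _read_csv(path: Path) -> RawRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "channel", "wavelength_nm", "od"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    channels = np.sort(df["channel"].unique())
    if len(channels) != N_CHANNELS:
        raise ValidationError(f"{path}: expected {N_CHANNELS} channels, got {len(channels)}")
    found_wl = set(df["wavelength_nm"].unique())
    if found_wl != set(wavelengths):
        raise ValidationError(
            f"{path}: wavelength mismatch — meta {sorted(wavelengths)}, "
            f"data {sorted(found_wl)} (missing wavelength?)")
    times = np.sort(df["time_s"].unique())
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"{path}: non-monotone timestamps")
    wide = df.pivot_table(index="time_s", columns=["channel", "wavelength_nm"],
                          values="od", sort=True)
    cols = pd.MultiIndex.from_product([range(1, N_CHANNELS + 1), wavelengths])
    od = wide.reindex(columns=cols).to_numpy().reshape(len(times), N_CHANNELS, 2)
    if np.any(np.isnan(od)):
        raise ValidationError(f"{path}: incomplete channel/wavelength grid")
    fs = float(meta["sampling_rate_hz"])
    ev_path = path.with_suffix(".events.csv")
    events: list[Event] = []
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        prev = -1
        for _, row in ev.iterrows():
            onset = int(row["onset_sample"])
            if onset < prev:
                raise ValidationError(
                    f"{ev_path}: events out of order (first offending onset {onset})")
            prev = onset
            events.append(Event(onset, str(row["kind"]), int(row["trial_index"])))
    rec = RawRecording(
        subject_id=str(meta["subject_id"]), session=int(meta["session"]),
        sampling_rate=fs, optical_density=od, events=events,
        wavelengths=wavelengths)
    return rec.validate(expect_task_starts=None)


def read_recording(path: str | Path,
                   format: Literal["snirf", "csv"] | None = None) -> RawRecording:
    """Read a recording from SNIRF or long CSV (format inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "snirf" if path.suffix == ".snirf" else "csv"
    if format == "snirf":
        return _read_snirf(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_recording(rec: RawRecording, path: str | Path,
                    format: Literal["snirf", "csv"] | None = None) -> Path:
    """Write a recording; refuses invalid recordings (e.g. NaN samples)."""
    path = Path(path)
    rec.validate(expect_task_starts=None)
    if format is None:
        format = "snirf" if path.suffix == ".snirf" else "csv"
    if format == "snirf":
        _write_snirf(rec, path)
    elif format == "csv":
        _write_csv(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# questionnaire / purchase tables

QUESTIONNAIRE_COLUMNS = ["respondent_id", "construct", "item_id", "score",
                         "condition", "gender"]
PURCHASE_COLUMNS = ["respondent_id", "session", "category", "count"]


def validate_questionnaire(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(QUESTIONNAIRE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"questionnaire: missing columns {sorted(missing)}")
    if len(df) == 0:
        return df
    bad = df[~df["construct"].isin(CONSTRUCTS)]
    if len(bad):
        raise ValidationError(
            f"questionnaire: unknown construct {bad['construct'].iloc[0]!r}")
    scores = df["score"]
    if not ((scores >= 1) & (scores <= 5)).all():
        raise ValidationError("questionnaire: score outside 1..5")
    dup = df.duplicated(["respondent_id", "construct", "item_id", "condition"])
    if dup.any():
        raise ValidationError(
            "questionnaire: a respondent answered the same item twice")
    # every respondent answers every item of a construct exactly once
    for (construct, condition), g in df.groupby(["construct", "condition"]):
        counts = g.groupby("respondent_id")["item_id"].nunique()
        if counts.nunique() > 1:
            raise ValidationError(
                f"questionnaire: uneven item coverage for {construct!r}/{condition!r}")
    return df


def validate_purchases(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PURCHASE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"purchases: missing columns {sorted(missing)}")
    if len(df) == 0:
        return df
    bad = df[~df["category"].isin(CATEGORIES)]
    if len(bad):
        raise ValidationError(f"purchases: unknown category {bad['category'].iloc[0]!r}")
    counts = df["count"]
    if not ((counts >= 0) & (counts <= 5)).all():
        raise ValidationError("purchases: count outside 0..5")
    return df


def read_questionnaire(path: str | Path) -> pd.DataFrame:
    return validate_questionnaire(pd.read_csv(path))


def write_questionnaire(df: pd.DataFrame, path: str | Path) -> Path:
    validate_questionnaire(df)
    df.to_csv(path, index=False)
    return Path(path)


def read_purchases(path: str | Path) -> pd.DataFrame:
    return validate_purchases(pd.read_csv(path))


def write_purchases(df: pd.DataFrame, path: str | Path) -> Path:
    validate_purchases(df)
    df.to_csv(path, index=False)
    return Path(path)
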