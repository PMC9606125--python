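"""Prefrontal probe geometry and region-of-interest assignments.

The montage is a 15-channel forehead array (5 sources, 7 detectors,
3 cm source-detector separation) laid out after the 10/20 system:
channels 1-7 cover the right frontal lobe, channel 8 sits on the
midline, and channels 9-15 mirror to the left.  Each channel belongs
to exactly one prefrontal region of interest (ROI): dorsolateral PFC,
left/right ventrolateral PFC, medial PFC, or orbitofrontal cortex.

Only a subset of the channel->ROI table is fixed by the montage
definition (channels 12, 14, 15 are left VLPFC; channel 8 is medial);
the remaining assignments are a documented symmetric default and can
be overridden with :func:`ProbeLayout.with_roi_overrides` or a YAML
mapping via :func:`load_roi_overrides`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ROIS",
    "ProbeLayout",
    "LayoutError",
    "default_layout",
    "load_roi_overrides",
]

N_CHANNELS = 15
N_SOURCES = 5
N_DETECTORS = 7

ROIS = ("DLPFC", "VLPFC_L", "VLPFC_R", "mPFC", "OFC")

#: Default symmetric channel -> ROI table.  Left VLPFC membership of
#: channels 12, 14, 15 is part of the montage definition; the mirror
#: image fixes 1, 2, 4 on the right, the midline channel 8 is medial,
#: and the remaining channels fill DLPFC (top row) and OFC (bottom row).
DEFAULT_ROI: dict[int, str] = {
    1: "VLPFC_R", 2: "VLPFC_R", 4: "VLPFC_R",
    12: "VLPFC_L", 14: "VLPFC_L", 15: "VLPFC_L",
    3: "DLPFC", 13: "DLPFC",
    7: "mPFC", 8: "mPFC", 9: "mPFC",
    5: "OFC", 6: "OFC", 10: "OFC", 11: "OFC",
}

# Schematic forehead coordinates (cm) used for topographic rendering.
# x > 0 is the participant's right; y > 0 is superior.  These are a
# drawing aid, not measured optode positions.
DEFAULT_POSITIONS: dict[int, tuple[float, float]] = {
    1: (5.5, 0.5), 2: (4.5, 1.4), 3: (3.0, 2.0), 4: (4.0, -0.5),
    5: (2.5, -1.5), 6: (1.2, -1.8), 7: (1.2, 1.0), 8: (0.0, 1.3),
    9: (-1.2, 1.0), 10: (-1.2, -1.8), 11: (-2.5, -1.5), 12: (-4.0, -0.5),
    13: (-3.0, 2.0), 14: (-4.5, 1.4), 15: (-5.5, 0.5),
}

# Channel -> (source, detector).  Each of the 5 sources feeds three
# neighbouring detectors; all 7 detectors are used.
DEFAULT_PAIRS: dict[int, tuple[int, int]] = {
    1: (1, 1), 2: (1, 2), 3: (1, 3),
    4: (2, 2), 5: (2, 3), 6: (2, 4),
    7: (3, 3), 8: (3, 4), 9: (3, 5),
    10: (4, 4), 11: (4, 5), 12: (4, 6),
    13: (5, 5), 14: (5, 6), 15: (5, 7),
}


class LayoutError(ValueError):
    """A probe layout violates a montage invariant."""


def _hemisphere(ch: int) -> str:
    if ch <= 7:
        return "right"
    if ch == 8:
        return "midline"
    return "left"


@dataclass(frozen=True)
class ProbeLayout:
    """Geometry and ROI table of the 15-channel prefrontal montage."""

    channel_pairs: dict[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PAIRS))
    roi: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ROI))
    positions: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_POSITIONS))
    source_detector_distance_cm: float = 3.0

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(range(1, N_CHANNELS + 1))

    @property
    def hemisphere(self) -> dict[int, str]:
        return {ch: _hemisphere(ch) for ch in self.channel_ids}

    def channels_in_roi(self, roi: str) -> tuple[int, ...]:
        return tuple(ch for ch in self.channel_ids if self.roi[ch] == roi)

    def channels_in_hemisphere(self, side: str) -> tuple[int, ...]:
        return tuple(ch for ch in self.channel_ids
                     if _hemisphere(ch) == side)

    def validate(self) -> "ProbeLayout":
        chans = set(self.channel_pairs)
        if chans != set(range(1, N_CHANNELS + 1)):
            raise LayoutError(
                f"channel_pairs: expected channels 1..{N_CHANNELS}, "
                f"got {sorted(chans)}")
        sources = {s for s, _ in self.channel_pairs.values()}
        detectors = {d for _, d in self.channel_pairs.values()}
        if sources != set(range(1, N_SOURCES + 1)):
            raise LayoutError(f"expected sources 1..{N_SOURCES}, got {sorted(sources)}")
        if detectors != set(range(1, N_DETECTORS + 1)):
            raise LayoutError(f"expected detectors 1..{N_DETECTORS}, got {sorted(detectors)}")
        if set(self.roi) != set(range(1, N_CHANNELS + 1)):
            missing = set(range(1, N_CHANNELS + 1)) - set(self.roi)
            extra = set(self.roi) - set(range(1, N_CHANNELS + 1))
            raise LayoutError(
                f"roi table must cover every channel exactly once "
                f"(missing {sorted(missing)}, extra {sorted(extra)})")
        for ch, r in self.roi.items():
            if r not in ROIS:
                raise LayoutError(f"channel {ch}: unknown ROI {r!r}")
        if set(self.positions) != set(range(1, N_CHANNELS + 1)):
            raise LayoutError("positions must cover channels 1..15")
        if not self.source_detector_distance_cm > 0:
            raise LayoutError("source-detector distance must be positive")
        return self

    def with_roi_overrides(self, overrides: Mapping[int, str]) -> "ProbeLayout":
        """Return a copy with selected channel->ROI entries replaced."""
        new_roi = dict(self.roi)
        for ch, r in overrides.items():
            new_roi[int(ch)] = str(r)
        return replace(self, roi=new_roi).validate()


def default_layout() -> ProbeLayout:
    """The documented default montage (validated)."""
    return ProbeLayout().validate()


def load_roi_overrides(path: str | Path) -> dict[int, str]:
    """Read a channel->ROI override table from a YAML mapping file.

    The file maps channel id to ROI name.  A channel listed more than
    once (e.g. as both an int and a string key) is an error, because a
    channel belongs to exactly one ROI.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise LayoutError(f"{path}: expected a mapping of channel -> ROI")
    out: dict[int, str] = {}
    for key, value in raw.items():
        ch = int(key)
        if ch in out:
            raise LayoutError(
                f"{path}: channel {ch} assigned to more than one ROI "
                f"({out[ch]!r} and {value!r})")
        out[ch] = str(value)
    return out
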