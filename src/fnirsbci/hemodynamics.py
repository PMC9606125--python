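"""Modified Beer-Lambert law (MBLL) conversion.

Optical-density change at wavelength lambda relates linearly to the
chromophore concentration changes:

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)

with eps the extinction coefficients (cm^-1 uM^-1 here), d the
source-detector separation (cm) and DPF the differential pathlength
factor.  With two wavelengths this is a 2x2 linear system per channel
and time sample; the inverse is computed in closed form once per
channel because eps, d and DPF do not vary in time.

Default extinction coefficients are the widely used compiled molar
coefficients (Prahl's tabulation, see docs/methods.md), converted to
cm^-1 uM^-1; DPF defaults to 6.0 at both wavelengths.  Both are
overridable — concentrations are only in true uM if the supplied
constants match the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import DEFAULT_WAVELENGTHS, Event, RawRecording

__all__ = [
    "DEFAULT_EXTINCTION_UM_CM",
    "DEFAULT_DPF",
    "HemoTimeSeries",
    "extinction_matrix",
    "mbll_forward",
    "mbll_invert",
    "intensity_to_od",
]

#: eps[(wavelength_nm)] = (eps_HbO, eps_HbR) in cm^-1 uM^-1
#: (molar coefficients 710.04/1075.44 and 1058.0/691.32 cm^-1 M^-1 x 1e-6).
DEFAULT_EXTINCTION_UM_CM: dict[float, tuple[float, float]] = {
    780.0: (710.04e-6, 1075.44e-6),
    850.0: (1058.00e-6, 691.32e-6),
}

DEFAULT_DPF: dict[float, float] = {780.0: 6.0, 850.0: 6.0}


@dataclass
class HemoTimeSeries:
    """Hemoglobin concentration changes (uM) per channel over time."""

    subject_id: str
    session: int
    sampling_rate: float
    dhbo: np.ndarray  # (time, channel), uM
    dhbr: np.ndarray  # (time, channel), uM
    events: list[Event] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.dhbo.shape[0]

    @property
    def n_channels(self) -> int:
        return self.dhbo.shape[1]

    def task_onsets(self) -> list[int]:
        return [e.onset_sample for e in self.events if e.kind == "task_start"]

    def validate(self) -> "HemoTimeSeries":
        if self.dhbo.shape != self.dhbr.shape:
            raise ValueError("dHbO and dHbR must have the same shape")
        if not (np.all(np.isfinite(self.dhbo)) and np.all(np.isfinite(self.dhbr))):
            raise ValueError("concentration series contain non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        return self


def extinction_matrix(
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS,
    extinction: Mapping[float, tuple[float, float]] | None = None,
    dpf: Mapping[float, float] | None = None,
    distance_cm: float = 3.0,
) -> np.ndarray:
    """The 2x2 map M with dOD = M @ (dHbO, dHbR); rows are wavelengths."""
    extinction = DEFAULT_EXTINCTION_UM_CM if extinction is None else extinction
    dpf = DEFAULT_DPF if dpf is None else dpf
    if distance_cm <= 0:
        raise ValueError("distance_cm must be > 0")
    rows = []
    for wl in wavelengths:
        if wl not in extinction:
            raise KeyError(f"no extinction coefficients for {wl} nm")
        e_hbo, e_hbr = extinction[wl]
        rows.append([e_hbo * distance_cm * dpf[wl], e_hbr * distance_cm * dpf[wl]])
    return np.asarray(rows, dtype=float)


def mbll_forward(
    dhbo: np.ndarray,
    dhbr: np.ndarray,
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS,
    extinction: Mapping[float, tuple[float, float]] | None = None,
    dpf: Mapping[float, float] | None = None,
    distance_cm: float = 3.0,
) -> np.ndarray:
    """Concentrations (time, channel) -> optical density (time, channel, 2)."""
    m = extinction_matrix(wavelengths, extinction, dpf, distance_cm)
    conc = np.stack([dhbo, dhbr], axis=-1)  # (time, channel, 2)
    return conc @ m.T


def mbll_invert(
    rec: RawRecording,
    extinction: Mapping[float, tuple[float, float]] | None = None,
    dpf: Mapping[float, float] | None = None,
    distance_cm: float = 3.0,
    max_condition: float = 1e6,
) -> HemoTimeSeries:
    """Invert two-wavelength optical density to (dHbO, dHbR) in uM."""
    m = extinction_matrix(rec.wavelengths, extinction, dpf, distance_cm)
    cond = float(np.linalg.cond(m))
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"extinction system is ill-conditioned (condition number {cond:.3g} "
            f"exceeds bound {max_condition:.3g})")
    minv = np.linalg.inv(m)
    conc = rec.optical_density @ minv.T  # (time, channel, 2)
    return HemoTimeSeries(
        subject_id=rec.subject_id,
        session=rec.session,
        sampling_rate=rec.sampling_rate,
        dhbo=np.ascontiguousarray(conc[..., 0]),
        dhbr=np.ascontiguousarray(conc[..., 1]),
        events=list(rec.events),
    ).validate()


def intensity_to_od(intensity: np.ndarray,
                    sampling_rate: float,
                    baseline_s: float = 1.0) -> np.ndarray:
    """Raw light intensity -> optical-density change.

    dOD = -log10(I / I0) with I0 the mean intensity over the first
    ``baseline_s`` seconds of the recording (per channel/wavelength).
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("intensities must be strictly positive")
    n0 = max(1, int(np.floor(baseline_s * sampling_rate)))
    i0 = intensity[:n0].mean(axis=0)
    return -np.log10(intensity / i0)
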