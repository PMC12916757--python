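"""tACS stimulus waveform and quasi-uniform electric-field coupling.

The stimulation electric field is treated as spatially uniform over the
microcircuit (quasi-uniform approximation), oscillating sinusoidally at the
stimulation frequency.  The anodic half-cycle points along the cortical-depth
axis from layer 1 toward layer 6; with the pial surface at +z this is the
-z direction.  Amplitude in mA maps linearly onto field magnitude in mV/mm
with unit slope (1 mA -> 1 mV/mm).

Phase convention: 0 deg is the waveform peak (maximal anodic field),
180 deg the trough.  The waveform value is ``A * cos(phase)``.  Stimulation
starts at phase 270 deg (rising zero crossing) so onset is continuous.

``freq_hz == 0`` is accepted as a constant (DC) anodic field at the given
amplitude; it is used for subthreshold polarization measurements, where the
instantaneous phase is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgument, OutOfWindow

#: Unit vector of the anodic field direction (layer 1 -> layer 6; pia at +z).
FIELD_AXIS = np.array([0.0, 0.0, -1.0])

#: Field magnitude per unit stimulation current, (mV/mm) / mA.
FIELD_PER_MA = 1.0


@dataclass(frozen=True)
class TacsWaveform:
    """Sinusoidal tACS stimulus: frequency, amplitude and active window."""

    freq_hz: float
    amplitude_ma: float
    onset_ms: float
    offset_ms: float
    onset_phase_deg: float = 270.0

    def __post_init__(self) -> None:
        if self.amplitude_ma < 0:
            raise InvalidArgument("amplitude_ma must be >= 0")
        if self.freq_hz < 0:
            raise InvalidArgument("freq_hz must be >= 0")
        if self.offset_ms <= self.onset_ms:
            raise InvalidArgument("offset_ms must exceed onset_ms")

    @property
    def period_ms(self) -> float:
        if self.freq_hz == 0:
            return math.inf
        return 1000.0 / self.freq_hz


@dataclass(frozen=True)
class FieldVector:
    """Signed field magnitude along a fixed unit direction.

    Positive magnitude means the field points along ``direction`` (the anodic
    orientation by default).
    """

    magnitude_mv_per_mm: float
    direction: np.ndarray = field(default_factory=lambda: FIELD_AXIS.copy())

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            raise InvalidArgument("direction must be a unit vector")


def amplitude_to_field(amplitude_ma: float) -> float:
    """Map stimulation amplitude (mA) to field magnitude (mV/mm).

    Linear with unit slope: 1 mA corresponds to 1 mV/mm in the homogeneous
    volume the circuit is embedded in; other amplitudes rescale linearly.
    """
    if amplitude_ma < 0:
        raise InvalidArgument("amplitude_ma must be >= 0")
    return FIELD_PER_MA * amplitude_ma


def field_value(t_ms: float, waveform: TacsWaveform) -> float:
    """Instantaneous signed field magnitude (mV/mm) at time ``t_ms``.

    Zero outside [onset, offset].  For ``freq_hz == 0`` the field is a
    constant anodic step of the calibrated magnitude inside the window.
    """
    if t_ms < waveform.onset_ms or t_ms > waveform.offset_ms:
        return 0.0
    mag = amplitude_to_field(waveform.amplitude_ma)
    if waveform.freq_hz == 0:
        return mag
    phase = math.radians(waveform.onset_phase_deg) + (
        2.0 * math.pi * waveform.freq_hz * (t_ms - waveform.onset_ms) / 1000.0
    )
    return mag * math.cos(phase)


def field_at(t_ms: float, waveform: TacsWaveform) -> FieldVector:
    """Field vector at time ``t_ms`` (anodic direction, signed magnitude)."""
    return FieldVector(magnitude_mv_per_mm=field_value(t_ms, waveform))


def waveform_phase(t_ms, waveform: TacsWaveform):
    """Stimulus phase in degrees on [0, 360) at time(s) ``t_ms``.

    0 deg at each waveform peak, 180 deg at each trough; advances 360 deg per
    period.  Only defined inside the active window; times outside raise
    :class:`OutOfWindow`.
    """
    if waveform.freq_hz == 0:
        raise InvalidArgument("phase undefined for a DC (freq_hz == 0) field")
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < waveform.onset_ms) or np.any(t > waveform.offset_ms):
        raise OutOfWindow("t_ms outside the active stimulation window")
    phase = (
        waveform.onset_phase_deg
        + 360.0 * waveform.freq_hz * (t - waveform.onset_ms) / 1000.0
    ) % 360.0
    if np.isscalar(t_ms):
        return float(phase)
    return phase


def project_field(segment, field: FieldVector) -> float:
    """Component of the field along a segment's axis (mV/mm).

    ``E_par = magnitude * cos(angle between segment axis and field
    direction)``; the sign flips with field polarity.  ``segment`` is any
    object with ``start_xyz`` and ``end_xyz`` attributes in micrometres.
    """
    start = np.asarray(segment.start_xyz, dtype=float)
    end = np.asarray(segment.end_xyz, dtype=float)
    axis = end - start
    length = float(np.linalg.norm(axis))
    if length == 0.0:
        raise InvalidArgument("cannot project a field onto a zero-length segment")
    direction = np.asarray(field.direction, dtype=float)
    return field.magnitude_mv_per_mm * float(np.dot(axis / length, direction))


def extracellular_potential_coefficients(midpoints_um: np.ndarray) -> np.ndarray:
    """Per-compartment extracellular potential per unit field magnitude.

    Under the quasi-uniform approximation the extracellular potential is
    ``V_e(x) = -E . x``.  Returns mV per (mV/mm) for compartment midpoints in
    micrometres, i.e. ``-(d_hat . x) * 1e-3``.
    """
    pts = np.asarray(midpoints_um, dtype=float)
    return -(pts @ FIELD_AXIS) * 1e-3
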