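"""Line-source local field potential, band-pass filtering and spectra.

Each compartment's transmembrane current contributes
``V_e = I_mem / (4 pi r sigma)`` at the electrode, with ``r`` the distance
from the compartment midpoint and ``sigma`` the extracellular conductivity
(0.3 mS/mm).  The LFP is the sum over every compartment of every cell —
dominated in practice by the nearest cell, the L5 pyramidal, whose soma the
electrode sits 20 um away from.  With I_mem in nA, r in mm and sigma in
mS/mm the potential comes out in uV.

Band-pass filtering uses a second-order Butterworth applied forward and
backward (zero phase), so spike-phase relations against the stimulus are
not lagged by the filter: 9-11 Hz for the alpha band, 4-6 Hz for theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np
from scipy import signal as sps

from .errors import DataError, InvalidArgument

SIGMA_MS_PER_MM = 0.3
ELECTRODE_OFFSET_UM = (20.0, 0.0, 0.0)  # 20 um lateral of the L5 soma


@dataclass(frozen=True)
class Electrode:
    """Point recording electrode in an ohmic homogeneous medium."""

    position_um: np.ndarray = dfield(
        default_factory=lambda: np.asarray(ELECTRODE_OFFSET_UM, dtype=float))
    sigma_ms_per_mm: float = SIGMA_MS_PER_MM

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position_um", np.asarray(self.position_um, dtype=float))
        if self.sigma_ms_per_mm <= 0:
            raise InvalidArgument("conductivity must be positive")


@dataclass(frozen=True)
class LfpTrace:
    """Uniformly sampled extracellular potential trace."""

    t_ms: np.ndarray
    values_uv: np.ndarray
    band: Optional[str] = None
    filter_settings: Optional[dict] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        x = np.asarray(self.values_uv, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise InvalidArgument("time base and values must match, 1-D")
        if not np.all(np.isfinite(x)):
            raise DataError("non-finite LFP values")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise InvalidArgument("LFP trace must be uniformly sampled")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "values_uv", x)

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def fs_hz(self) -> float:
        return 1000.0 / self.dt_ms


def point_source_ve(i_mem_na, distance_mm, sigma_ms_per_mm: float = SIGMA_MS_PER_MM):
    """Extracellular potential (uV) of a point transmembrane current.

    ``V_e = I_mem / (4 pi r sigma)``: linear in the current, inversely
    proportional to distance.
    """
    if np.any(np.asarray(distance_mm) <= 0):
        raise InvalidArgument("distance must be positive")
    if sigma_ms_per_mm <= 0:
        raise InvalidArgument("conductivity must be positive")
    return np.asarray(i_mem_na, dtype=float) / (
        4.0 * math.pi * np.asarray(distance_mm, dtype=float) * sigma_ms_per_mm
    )


def compute_lfp(
    t_ms: np.ndarray,
    imem_na: np.ndarray,
    midpoints_um: np.ndarray,
    electrode: Optional[Electrode] = None,
) -> LfpTrace:
    """Sum the point-source contributions of all compartments.

    ``imem_na`` is the recorded per-compartment transmembrane current
    history ``[n_times, n_comp]``; ``midpoints_um`` the matching compartment
    midpoints (the line-source kernel evaluated at segment midpoints).
    """
    el = electrode or Electrode()
    imem = np.asarray(imem_na, dtype=float)
    if imem.ndim != 2:
        raise DataError("expected an [n_times, n_comp] current history")
    mids = np.asarray(midpoints_um, dtype=float)
    if mids.shape[0] != imem.shape[1]:
        raise DataError("compartment count mismatch between currents and geometry")
    r_mm = np.linalg.norm(mids - el.position_um[None, :], axis=1) * 1e-3
    if np.any(r_mm <= 1e-9):
        raise InvalidArgument("electrode coincides with a compartment midpoint")
    weights = 1.0 / (4.0 * math.pi * r_mm * el.sigma_ms_per_mm)
    return LfpTrace(t_ms=np.asarray(t_ms, dtype=float), values_uv=imem @ weights)


def bandpass(
    trace: LfpTrace,
    center_hz: float,
    halfwidth_hz: float = 1.0,
    order: int = 2,
    band: Optional[str] = None,
) -> LfpTrace:
    """Zero-phase Butterworth band-pass around ``center_hz``.

    Second order, applied forward-backward (``filtfilt``) so the effective
    attenuation is that of two passes and the phase response is zero.
    """
    lo = center_hz - halfwidth_hz
    hi = center_hz + halfwidth_hz
    nyq = trace.fs_hz / 2.0
    if lo <= 0 or hi >= nyq:
        raise InvalidArgument(f"band [{lo}, {hi}] Hz outside (0, {nyq}) Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=trace.fs_hz,
                     output="sos")
    y = sps.sosfiltfilt(sos, trace.values_uv)
    return LfpTrace(
        t_ms=trace.t_ms, values_uv=y,
        band=band or f"{center_hz:g}Hz",
        filter_settings={"type": "butterworth", "order": order,
                         "low_hz": lo, "high_hz": hi, "zero_phase": True},
    )


def psd(trace: LfpTrace, window_s: float = 2.0, overlap: float = 0.5):
    """Averaged-periodogram (Welch) power spectral density.

    2-s Hann windows with 50% overlap by default; returns
    ``(freq_hz, power)``.  Requires the trace to cover at least one window.
    """
    nper = int(round(window_s * trace.fs_hz))
    if trace.values_uv.size < nper:
        raise InvalidArgument("trace shorter than one PSD window")
    f, p = sps.welch(trace.values_uv, fs=trace.fs_hz, nperseg=nper,
                     noverlap=int(nper * overlap))
    return f, p


def peak_frequency(trace: LfpTrace, fmin_hz: float = 1.0,
                   fmax_hz: Optional[float] = None) -> float:
    """Frequency of the PSD maximum within [fmin, fmax]."""
    f, p = psd(trace)
    mask = f >= fmin_hz
    if fmax_hz is not None:
        mask &= f <= fmax_hz
    if not np.any(mask):
        raise InvalidArgument("no PSD bins in the requested range")
    return float(f[mask][np.argmax(p[mask])])
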