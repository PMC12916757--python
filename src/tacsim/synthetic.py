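"""Synthetic ground-truth generators for the entrainment-analysis pipeline.

Every analysis stage (PLV, PPC, circular statistics, filtering, coherence)
must be testable without running the biophysical simulator.  This module
provides three seeded generators with known ground truth:

* von Mises phase samples with controllable concentration ``kappa`` — the
  population PLV is the Bessel ratio ``I1(kappa)/I0(kappa)``;
* sinusoidally rate-modulated Poisson spike trains (intensity
  ``rate * (1 + mod_depth*cos)``, peak at phase 0) via thinning — the
  population PLV is ``mod_depth / 2``;
* narrow-band surrogate LFP traces (sinusoid plus white noise).

All angles at the interface are degrees on [0, 360); 0 deg is the waveform
peak, 180 deg the trough.  Each generator is a pure function of its
arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .errors import InvalidArgument

_KINDS = ("von_mises", "uniform", "modulated_poisson", "surrogate_lfp")


@dataclass(frozen=True)
class PhaseSample:
    """A sample of spike/stimulus phases in degrees on [0, 360)."""

    phases: np.ndarray
    n: int = 0

    def __post_init__(self) -> None:
        ph = np.asarray(self.phases, dtype=float)
        if ph.ndim != 1 or ph.size < 1:
            raise InvalidArgument("phases must be a non-empty 1-D sequence")
        if np.any(ph < 0) or np.any(ph >= 360.0):
            raise InvalidArgument("phases must lie in [0, 360)")
        object.__setattr__(self, "phases", ph)
        object.__setattr__(self, "n", int(ph.size))

    def radians(self) -> np.ndarray:
        return np.deg2rad(self.phases)


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of one synthetic data set."""

    kind: str
    mu_deg: float = 0.0
    kappa: float = 0.0
    rate_hz: float = 10.0
    mod_depth: float = 0.0
    freq_hz: float = 10.0
    duration_s: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise InvalidArgument(f"kind must be one of {_KINDS}")
        if self.kappa < 0:
            raise InvalidArgument("kappa must be >= 0")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise InvalidArgument("mod_depth must lie in [0, 1]")
        if self.duration_s <= 0:
            raise InvalidArgument("duration_s must be positive")


def sample_von_mises(mu_deg: float, kappa: float, n: int, seed: int) -> PhaseSample:
    """Draw ``n`` phases (degrees) from a von Mises law centred on ``mu_deg``.

    ``kappa = 0`` gives the circular uniform distribution; as ``kappa`` grows
    the sample concentrates at ``mu_deg`` and the sample PLV approaches
    ``I1(kappa)/I0(kappa)``.
    """
    if kappa < 0:
        raise InvalidArgument("kappa must be >= 0")
    if n < 1:
        raise InvalidArgument("n must be >= 1")
    rng = np.random.default_rng(seed)
    if kappa == 0:
        ang = rng.uniform(0.0, 2.0 * np.pi, size=n)
    else:
        ang = rng.vonmises(np.deg2rad(mu_deg), kappa, size=n)
    return PhaseSample(np.rad2deg(ang) % 360.0)


def sample_modulated_poisson(
    rate_hz: float,
    mod_depth: float,
    freq_hz: float,
    duration_s: float,
    seed: int,
) -> np.ndarray:
    """Spike times (ms) of an inhomogeneous Poisson process, by thinning.

    Intensity ``rate_hz * (1 + mod_depth * cos(2*pi*freq_hz*t))`` — the
    modulation peaks at t = 0, so spike phases taken relative to the
    modulation (0 deg at each peak) concentrate at 0 deg with population
    PLV ``mod_depth / 2``.  ``mod_depth = 0`` reduces to a homogeneous
    process sampled by exponential inter-arrival times.
    """
    if rate_hz <= 0:
        raise InvalidArgument("rate_hz must be positive")
    if not 0.0 <= mod_depth <= 1.0:
        raise InvalidArgument("mod_depth must lie in [0, 1]")
    if duration_s <= 0:
        raise InvalidArgument("duration_s must be positive")
    if mod_depth > 0 and duration_s * freq_hz < 1.0:
        raise InvalidArgument("duration must cover at least one modulation cycle")
    rng = np.random.default_rng(seed)
    lam_max = rate_hz * (1.0 + mod_depth)
    # Draw candidate homogeneous arrivals, then thin by the intensity ratio.
    n_cand = rng.poisson(lam_max * duration_s)
    t_cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
    if mod_depth == 0:
        return t_cand * 1000.0
    accept_p = (1.0 + mod_depth * np.cos(2.0 * np.pi * freq_hz * t_cand)) / (
        1.0 + mod_depth
    )
    keep = rng.uniform(size=n_cand) < accept_p
    return t_cand[keep] * 1000.0


def spike_phases(spike_times_ms: np.ndarray, freq_hz: float) -> PhaseSample:
    """Phases (deg, 0 = modulation peak) of spike times for ``freq_hz``."""
    t = np.asarray(spike_times_ms, dtype=float)
    if t.size < 1:
        raise InvalidArgument("no spikes to phase-stamp")
    return PhaseSample((360.0 * freq_hz * t / 1000.0) % 360.0)


def sample_surrogate_lfp(
    freq_hz: float,
    noise_sd: float,
    duration_s: float,
    dt_ms: float,
    seed: int,
):
    """Surrogate LFP: unit cosine at ``freq_hz`` (peak at t = 0) plus white noise.

    Returns ``(time_ms, values)`` uniformly sampled at ``dt_ms``.  The same
    seed yields a bit-identical trace.
    """
    if dt_ms <= 0 or duration_s <= 0:
        raise InvalidArgument("dt_ms and duration_s must be positive")
    nyquist = 1000.0 / (2.0 * dt_ms)
    if freq_hz >= nyquist:
        raise InvalidArgument(f"freq_hz must be below Nyquist ({nyquist} Hz)")
    rng = np.random.default_rng(seed)
    t_ms = np.arange(0.0, duration_s * 1000.0, dt_ms)
    x = np.cos(2.0 * np.pi * freq_hz * t_ms / 1000.0)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(t_ms.size)
    return t_ms, x


def generate(spec: SyntheticSpec):
    """Dispatch on ``spec.kind``; see the individual generators."""
    if spec.kind in ("von_mises", "uniform"):
        kappa = 0.0 if spec.kind == "uniform" else spec.kappa
        n = max(1, int(round(spec.rate_hz * spec.duration_s)))
        return sample_von_mises(spec.mu_deg, kappa, n, spec.seed)
    if spec.kind == "modulated_poisson":
        return sample_modulated_poisson(
            spec.rate_hz, spec.mod_depth, spec.freq_hz, spec.duration_s, spec.seed
        )
    return sample_surrogate_lfp(
        spec.freq_hz, spec.noise_sd, spec.duration_s, 1.0, spec.seed
    )
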