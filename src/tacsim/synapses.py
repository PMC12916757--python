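"""Dual-exponential conductance synapses, Poisson drive and event delivery.

The synaptic conductance after a presynaptic spike at ``t_s`` follows a
difference of exponentials with rise constant tau1 and decay constant tau2,
``I_syn(t) = g_syn(t) * (V(t) - E_syn)``.  The conductance is
peak-normalized: the weight ``g_max`` equals the true peak conductance.
(The unnormalized prefactor tau1*tau2/(tau1 - tau2) is negative for
tau1 < tau2 and so is the bracketed difference of exponentials; their
product is positive.  Normalizing by the peak makes the sign convention
explicit and the weight physically interpretable.)

Successive events sum linearly — static synapses, no saturation, depression
or facilitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield
from typing import List, Sequence

import numpy as np

from .errors import InvalidArgument, SchedulingError

RECEPTORS = ("AMPA_NMDA_like", "GABAA_like", "GABAB_like")

#: Receptor kinetics: (tau1_ms, tau2_ms, e_syn_mV).  The excitatory kinetics
#: (0 mV reversal, 2/10 ms) also parameterize the background Poisson drive;
#: GABA_B-like contacts are slow and strongly hyperpolarizing.
RECEPTOR_DEFAULTS = {
    "AMPA_NMDA_like": (2.0, 10.0, 0.0),
    "GABAA_like": (1.0, 8.0, -80.0),
    "GABAB_like": (20.0, 100.0, -95.0),
}


@dataclass(frozen=True)
class SynapseSpec:
    """One synaptic contact on a target segment."""

    target_segment: int
    g_max_us: float
    e_syn_mv: float
    tau1_ms: float
    tau2_ms: float
    receptor: str = "AMPA_NMDA_like"

    def __post_init__(self) -> None:
        if self.tau1_ms <= 0 or self.tau2_ms <= 0:
            raise InvalidArgument("time constants must be positive")
        if self.tau1_ms == self.tau2_ms:
            raise InvalidArgument(
                "tau1 == tau2 is the alpha-function limit; not silently substituted"
            )
        if self.g_max_us < 0:
            raise InvalidArgument("g_max must be >= 0")
        if self.receptor not in RECEPTORS:
            raise InvalidArgument(f"receptor must be one of {RECEPTORS}")

    @classmethod
    def for_receptor(cls, receptor: str, target_segment: int, g_max_us: float):
        tau1, tau2, e = RECEPTOR_DEFAULTS[receptor]
        return cls(target_segment, g_max_us, e, tau1, tau2, receptor)


@dataclass(frozen=True)
class Connection:
    """A directed synaptic connection: one or more contacts plus a delay."""

    pre_cell: str
    post_cell: str
    contacts: Sequence[SynapseSpec]
    delay_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.pre_cell == self.post_cell:
            raise InvalidArgument("autapses are not allowed")
        if len(self.contacts) < 1:
            raise InvalidArgument("a connection needs at least one contact")
        if self.delay_ms < 0:
            raise InvalidArgument("delay must be >= 0")


@dataclass(frozen=True)
class PoissonDrive:
    """Background excitatory drive: independent Poisson trains per contact."""

    cell_id: str
    target_segments: Sequence[int]
    mean_interval_ms: float
    weight_us: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_interval_ms <= 0:
            raise InvalidArgument("mean interval must be positive")
        if len(self.target_segments) < 3:
            raise InvalidArgument(
                "drive must target at least 3 dendritic branches"
            )


def peak_time(tau1_ms: float, tau2_ms: float) -> float:
    """Time to peak of the dual exponential: tau1*tau2/(tau2-tau1)*ln(tau2/tau1)."""
    if tau1_ms == tau2_ms:
        raise InvalidArgument("tau1 == tau2 not supported")
    return tau1_ms * tau2_ms / (tau2_ms - tau1_ms) * math.log(tau2_ms / tau1_ms)


def peak_norm_factor(tau1_ms: float, tau2_ms: float) -> float:
    """Factor making ``g_max`` the true peak of the dual exponential."""
    tp = peak_time(tau1_ms, tau2_ms)
    denom = math.exp(-tp / tau2_ms) - math.exp(-tp / tau1_ms)
    return 1.0 / denom


def dual_exp_conductance(t_since_spike_ms, spec: SynapseSpec):
    """Conductance (uS) ``t_since_spike_ms`` after one presynaptic spike.

    Zero at t = 0, rises to a single maximum equal to ``g_max`` at
    ``peak_time(tau1, tau2)`` and decays back to zero; nonnegative
    everywhere.  Symmetric in the ordering of tau1 and tau2.
    """
    t = np.asarray(t_since_spike_ms, dtype=float)
    if np.any(t < 0):
        raise InvalidArgument("t_since_spike must be >= 0")
    f = peak_norm_factor(spec.tau1_ms, spec.tau2_ms)
    g = spec.g_max_us * f * (np.exp(-t / spec.tau2_ms) - np.exp(-t / spec.tau1_ms))
    if np.isscalar(t_since_spike_ms):
        return float(g)
    return g


def synaptic_current(v_mv, conductance_us, e_syn_mv) -> float:
    """Ohmic synaptic current ``I = g (V - E_syn)`` in nA, outward positive.

    Zero at the reversal potential; for an excitatory synapse (E_syn = 0 mV)
    the current is inward (negative) at subthreshold potentials, driving
    depolarization.
    """
    return conductance_us * (np.asarray(v_mv, dtype=float) - e_syn_mv) \
        if not np.isscalar(v_mv) else float(conductance_us * (v_mv - e_syn_mv))


def poisson_drive_events(drive: PoissonDrive, duration_ms: float) -> List[np.ndarray]:
    """Seed-deterministic homogeneous Poisson event times per contact (ms).

    Each contact gets an independent train with the drive's mean
    inter-spike interval, generated by exponential inter-arrival sampling.
    """
    if duration_ms <= 0:
        raise InvalidArgument("duration must be positive")
    out = []
    for k in range(len(drive.target_segments)):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(drive.seed), int(k)))
        )
        # draw enough gaps to cover the window with margin, then trim
        n_exp = duration_ms / drive.mean_interval_ms
        n_draw = int(n_exp + 6.0 * math.sqrt(n_exp) + 16)
        t = np.cumsum(rng.exponential(drive.mean_interval_ms, size=n_draw))
        while t.size and t[-1] < duration_ms:
            t = np.concatenate(
                [t, t[-1] + np.cumsum(rng.exponential(drive.mean_interval_ms,
                                                      size=n_draw))]
            )
        out.append(t[t < duration_ms])
    return out


def deliver(connection: Connection, pre_spike_time_ms: float,
            current_time_ms: float = -math.inf):
    """Scheduled conductance events at the post contacts for one pre spike.

    Returns ``[(event_time_ms, contact), ...]`` with
    ``event_time = pre_spike_time + delay``.  Conductances from successive
    events sum linearly at the contact.  Scheduling an event before the
    current simulation time raises :class:`SchedulingError`.
    """
    t_ev = pre_spike_time_ms + connection.delay_ms
    if t_ev < current_time_ms:
        raise SchedulingError(
            f"event at {t_ev} ms is before current time {current_time_ms} ms"
        )
    return [(t_ev, c) for c in connection.contacts]
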