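"""Conductance-based multicompartment cable model with field coupling.

The membrane potential on the segment tree obeys the cable equation with an
extracellular forcing term: under the quasi-uniform field approximation each
compartment sees an extracellular potential ``V_e = -E(t) . x`` evaluated at
its midpoint, and gradients of ``V_e`` along the tree drive axial currents.
Integration is semi-implicit backward Euler (unconditionally stable) at
dt = 0.025 ms by default, with gating variables advanced by exponential
Euler.  Spiking uses Wang-Buzsaki fast-sodium / delayed-rectifier kinetics
on the soma and axon initial segment; dendrites are passive.

Transmembrane currents are recorded per compartment at a 1-ms cadence for
the line-source LFP; by charge conservation they equal the net axial current
into each compartment and sum to zero over a cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield, replace
from typing import List, Optional, Sequence

import numpy as np

from . import _engine
from .errors import InvalidArgument, NumericalFailure
from .field import TacsWaveform, extracellular_potential_coefficients
from .morphology import Morphology

DT_MS = 0.025          #: default integration step
INTEGRATION_THETA = 0.5  #: theta-method weight (0.5 = Crank-Nicolson)
RECORD_MS = 1.0        #: transmembrane-current recording cadence
V_THRESHOLD_MV = -10.0  #: somatic spike-detection threshold
REFRACTORY_MS = 3.0


@dataclass(frozen=True)
class MembraneParams:
    """Passive and spike-generating membrane parameters.

    Units: r_axial Ohm*cm, c_m uF/cm^2, conductance densities S/cm^2,
    potentials mV.  Spike channels (Wang-Buzsaki Na/K) are inserted on the
    compartment kinds in ``spike_kinds``; set the densities to zero for a
    fully passive cell.
    """

    r_axial_ohm_cm: float = 150.0
    c_m_uf_cm2: float = 1.0
    g_leak_s_cm2: float = 1.0 / 25000.0
    e_leak_mv: float = -65.0
    g_na_s_cm2: float = 0.08
    g_k_s_cm2: float = 0.02
    g_m_s_cm2: float = 0.004
    tau_m_current_ms: float = 100.0
    axon_density_mult: float = 3.0
    e_na_mv: float = 55.0
    e_k_mv: float = -90.0
    phi: float = 5.0
    spike_kinds: tuple = ("soma", "axon")

    def __post_init__(self) -> None:
        if self.c_m_uf_cm2 <= 0 or self.r_axial_ohm_cm <= 0:
            raise InvalidArgument("c_m and r_axial must be positive")
        for name in ("g_leak_s_cm2", "g_na_s_cm2", "g_k_s_cm2", "g_m_s_cm2"):
            if getattr(self, name) < 0:
                raise InvalidArgument(f"{name} must be >= 0")

    def passive(self) -> "MembraneParams":
        return replace(self, g_na_s_cm2=0.0, g_k_s_cm2=0.0, g_m_s_cm2=0.0)


@dataclass
class CableState:
    """Mutable integrator state: voltages, gates, synapse states, clocks."""

    v_mv: np.ndarray
    hh_h: np.ndarray
    hh_n: np.ndarray
    hh_p: np.ndarray
    syn_a: np.ndarray
    syn_b: np.ndarray
    last_spike_ms: np.ndarray
    t_ms: float = 0.0

    def copy(self) -> "CableState":
        return CableState(
            self.v_mv.copy(), self.hh_h.copy(), self.hh_n.copy(),
            self.hh_p.copy(), self.syn_a.copy(), self.syn_b.copy(),
            self.last_spike_ms.copy(), self.t_ms,
        )


def _segment_arrays(morph: Morphology, params: MembraneParams):
    """Flatten one morphology into per-compartment solver arrays."""
    segs = morph.segments
    n = len(segs)
    parent = np.full(n, -1, dtype=np.int64)
    ga = np.zeros(n)
    cap = np.zeros(n)
    gpas = np.zeros(n)
    gna = np.zeros(n)
    gk = np.zeros(n)
    gm = np.zeros(n)
    mid = np.zeros((n, 3))
    index_of = {s.id: i for i, s in enumerate(segs)}

    def half_res_mohm(s):
        # Ra * (L/2) / (pi r^2), converted to MOhm for um dimensions
        length = max(s.length_um, s.diameter_um)  # sphere-equivalent soma
        r_um = s.diameter_um / 2.0
        return params.r_axial_ohm_cm * (length / 2.0) * 0.01 / (math.pi * r_um**2)

    for i, s in enumerate(segs):
        area_cm2 = s.area_um2 * 1e-8
        cap[i] = params.c_m_uf_cm2 * area_cm2 * 1e3      # nF
        gpas[i] = params.g_leak_s_cm2 * area_cm2 * 1e6   # uS
        if s.kind in params.spike_kinds:
            mult = params.axon_density_mult if s.kind == "axon" else 1.0
            gna[i] = params.g_na_s_cm2 * area_cm2 * 1e6 * mult
            gk[i] = params.g_k_s_cm2 * area_cm2 * 1e6 * mult
            gm[i] = params.g_m_s_cm2 * area_cm2 * 1e6 * mult
        mid[i] = s.midpoint_um
        if s.parent is not None:
            p = index_of[s.parent]
            parent[i] = p
            ga[i] = 1.0 / (half_res_mohm(s) + half_res_mohm(segs[p]))

    # Hines ordering requires parent < child; builders emit segments in
    # creation order which satisfies this, but verify.
    if np.any(parent >= np.arange(n)):
        raise InvalidArgument("segments must be ordered parents-first")
    return parent, ga, cap, gpas, gna, gk, gm, mid


class CableSim:
    """A runnable compartmental model (one cell or a stacked network).

    Build with :func:`build_single_cell` or :func:`tacsim.circuit.assemble`.
    Synapses are registered at construction; external (Poisson) events are
    supplied per run.
    """

    def __init__(
        self,
        morphologies: Sequence[Morphology],
        params: Sequence[MembraneParams],
        dt_ms: float = DT_MS,
    ):
        if len(morphologies) != len(params):
            raise InvalidArgument("one MembraneParams per morphology")
        self.morphologies = list(morphologies)
        self.params = list(params)
        self.dt_ms = float(dt_ms)
        self.cell_ids = [m.cell_id for m in morphologies]

        blocks = [_segment_arrays(m, p) for m, p in zip(morphologies, params)]
        offs = np.cumsum([0] + [len(m) for m in morphologies])
        self.cell_offset = offs
        self.n_comp = int(offs[-1])
        self.parent = np.concatenate(
            [np.where(b[0] >= 0, b[0] + o, -1) for b, o in zip(blocks, offs)]
        ).astype(np.int64)
        self.ga = np.concatenate([b[1] for b in blocks])
        self.cap = np.concatenate([b[2] for b in blocks])
        self.gpas = np.concatenate([b[3] for b in blocks])
        self.gna = np.concatenate([b[4] for b in blocks])
        self.gk = np.concatenate([b[5] for b in blocks])
        self.gm = np.concatenate([b[6] for b in blocks])
        self.midpoints_um = np.concatenate([b[7] for b in blocks])
        self.ve_coef = extracellular_potential_coefficients(self.midpoints_um)
        self.epas = np.concatenate(
            [np.full(len(m), p.e_leak_mv) for m, p in zip(morphologies, params)]
        )
        p0 = params[0]
        for p in params:
            if (p.e_na_mv, p.e_k_mv, p.phi) != (p0.e_na_mv, p0.e_k_mv, p0.phi):
                raise InvalidArgument("spike-channel reversals must match across cells")
        self.ena = p0.e_na_mv
        self.ek = p0.e_k_mv
        self.phi = p0.phi
        self.tau_m_current = np.concatenate(
            [np.full(len(m), p.tau_m_current_ms)
             for m, p in zip(morphologies, params)]
        )
        self.soma_comp = np.array(
            [offs[i] + next(k for k, s in enumerate(m.segments)
                            if s.parent is None)
             for i, m in enumerate(morphologies)], dtype=np.int64)

        # synapse table (filled by add_synapse)
        self._syn_comp: List[int] = []
        self._syn_e: List[float] = []
        self._syn_tau1: List[float] = []
        self._syn_tau2: List[float] = []
        # outgoing network contacts, per source cell
        self._out: List[List[tuple]] = [[] for _ in morphologies]
        self.max_delay_ms = 0.0

    # -- construction ------------------------------------------------------
    def comp_index(self, cell: int, segment_id: int) -> int:
        morph = self.morphologies[cell]
        local = next(i for i, s in enumerate(morph.segments) if s.id == segment_id)
        return int(self.cell_offset[cell] + local)

    def add_synapse(self, cell: int, segment_id: int, e_syn_mv: float,
                    tau1_ms: float, tau2_ms: float) -> int:
        """Register a dual-exponential synapse; returns its global index."""
        if tau1_ms == tau2_ms or tau1_ms <= 0 or tau2_ms <= 0:
            raise InvalidArgument("need distinct positive time constants")
        self._syn_comp.append(self.comp_index(cell, segment_id))
        self._syn_e.append(e_syn_mv)
        self._syn_tau1.append(tau1_ms)
        self._syn_tau2.append(tau2_ms)
        return len(self._syn_comp) - 1

    def connect(self, pre_cell: int, syn_index: int, weight_us: float,
                delay_ms: float) -> None:
        """Deliver ``weight_us`` to ``syn_index`` ``delay_ms`` after each pre spike."""
        if delay_ms < self.dt_ms:
            raise InvalidArgument("delay must be at least one time step")
        self._out[pre_cell].append((syn_index, weight_us, delay_ms))
        self.max_delay_ms = max(self.max_delay_ms, delay_ms)

    @property
    def n_syn(self) -> int:
        return len(self._syn_comp)

    # -- state -------------------------------------------------------------
    def initial_state(self) -> CableState:
        v = self.epas.copy()
        h = np.zeros(self.n_comp)
        nn = np.zeros(self.n_comp)
        pp = np.zeros(self.n_comp)
        for j in range(self.n_comp):
            _, h_inf, _, n_inf, _ = _engine.wb_gates(v[j])
            h[j] = h_inf
            nn[j] = n_inf
            pp[j] = _engine.m_current_gate(v[j])
        return CableState(
            v_mv=v, hh_h=h, hh_n=nn, hh_p=pp,
            syn_a=np.zeros(self.n_syn), syn_b=np.zeros(self.n_syn),
            last_spike_ms=np.full(len(self.morphologies), -1e9),
            t_ms=0.0,
        )

    def _packed(self):
        from .synapses import peak_norm_factor

        syn_comp = np.asarray(self._syn_comp, dtype=np.int64)
        syn_e = np.asarray(self._syn_e, dtype=float)
        tau1 = np.asarray(self._syn_tau1, dtype=float)
        tau2 = np.asarray(self._syn_tau2, dtype=float)
        d1 = np.exp(-self.dt_ms / tau1) if tau1.size else np.zeros(0)
        d2 = np.exp(-self.dt_ms / tau2) if tau2.size else np.zeros(0)
        h1 = np.exp(-0.5 * self.dt_ms / tau1) if tau1.size else np.zeros(0)
        h2 = np.exp(-0.5 * self.dt_ms / tau2) if tau2.size else np.zeros(0)
        fac = np.array([peak_norm_factor(a, b) for a, b in zip(tau1, tau2)]) \
            if tau1.size else np.zeros(0)

        n_cells = len(self.morphologies)
        counts = [len(o) for o in self._out]
        out_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        flat = [item for o in self._out for item in o]
        out_syn = np.array([f[0] for f in flat], dtype=np.int64)
        out_w = np.array([f[1] for f in flat], dtype=float)
        out_delay = np.array(
            [max(1, int(round(f[2] / self.dt_ms))) for f in flat], dtype=np.int64
        )
        n_slots = int(out_delay.max()) + 1 if out_delay.size else 1
        return (syn_comp, syn_e, d1, d2, h1, h2, fac, out_ptr, out_syn,
                out_w, out_delay, n_slots)

    # -- running -----------------------------------------------------------
    def run(
        self,
        duration_ms: float,
        waveform: Optional[TacsWaveform] = None,
        events: Optional[tuple] = None,
        state: Optional[CableState] = None,
        record: bool = True,
        record_every_ms: float = RECORD_MS,
        pend: Optional[np.ndarray] = None,
    ):
        """Advance the model by ``duration_ms``.

        ``events`` is ``(times_ms, syn_indices, weights_us)`` sorted by time
        (external Poisson drive).  Returns ``(spikes, recording, state)``
        where ``spikes`` is a list of per-cell spike-time arrays (ms) and
        ``recording`` is ``(t_ms, imem_na[n_rec, n_comp], vsoma_mv)`` at the
        1-ms cadence (or None when ``record=False``).
        """
        st = state if state is not None else self.initial_state()
        n_steps = int(round(duration_ms / self.dt_ms))
        rec_every = int(round(record_every_ms / self.dt_ms)) if record else 0
        if record and rec_every < 1:
            raise InvalidArgument("recording cadence below the time step")

        (syn_comp, syn_e, d1, d2, h1, h2, fac, out_ptr, out_syn, out_w,
         out_delay, n_slots) = self._packed()
        if pend is None:
            pend = np.zeros((n_slots, max(self.n_syn, 1)))

        if events is None:
            ev_t = np.zeros(0)
            ev_s = np.zeros(0, dtype=np.int64)
            ev_w = np.zeros(0)
        else:
            ev_t = np.asarray(events[0], dtype=float)
            ev_s = np.asarray(events[1], dtype=np.int64)
            ev_w = np.asarray(events[2], dtype=float)
            if not np.all(np.diff(ev_t) >= 0):
                order = np.argsort(ev_t, kind="stable")
                ev_t, ev_s, ev_w = ev_t[order], ev_s[order], ev_w[order]

        if waveform is None:
            amp_field = 0.0
            freq = onset = offset = 0.0
            ph0 = 0.0
        else:
            from .field import amplitude_to_field
            amp_field = amplitude_to_field(waveform.amplitude_ma)
            freq = waveform.freq_hz
            onset = waveform.onset_ms
            offset = waveform.offset_ms
            ph0 = math.radians(waveform.onset_phase_deg)

        max_spikes = int(200.0 * duration_ms / 1000.0 + 50) * len(self.morphologies)
        spike_cell = np.zeros(max_spikes, dtype=np.int64)
        spike_t = np.zeros(max_spikes)

        n_spk, imem, vsoma, status = _engine.run(
            self.parent, self.ga, self.cap, self.gpas, self.epas,
            self.gna, self.gk, self.gm, self.tau_m_current, self.ve_coef,
            self.ena, self.ek, self.phi,
            self.soma_comp,
            syn_comp, syn_e, d1, d2, h1, h2, fac,
            ev_t, ev_s, ev_w,
            out_ptr, out_syn, out_w, out_delay,
            pend,
            st.v_mv, st.hh_h, st.hh_n, st.hh_p, st.syn_a, st.syn_b, st.last_spike_ms,
            st.t_ms, self.dt_ms, INTEGRATION_THETA, n_steps, rec_every,
            amp_field, freq, onset, offset, ph0,
            V_THRESHOLD_MV, REFRACTORY_MS,
            spike_cell, spike_t,
        )
        if status == _engine.STATUS_NAN:
            raise NumericalFailure("non-finite membrane potential; trial aborted")
        if status == _engine.STATUS_OVERFLOW:
            raise NumericalFailure("spike buffer overflow (runaway activity)")

        t_start = st.t_ms
        st.t_ms += n_steps * self.dt_ms
        spikes = [
            np.sort(spike_t[:n_spk][spike_cell[:n_spk] == c])
            for c in range(len(self.morphologies))
        ]
        recording = None
        if record:
            rec_t = t_start + record_every_ms * np.arange(1, imem.shape[0] + 1)
            recording = (rec_t, imem, vsoma)
        return spikes, recording, st

    def step(self, state: CableState, waveform=None, events=None,
             pend=None) -> CableState:
        """Advance the state by a single time step (contract-test surface)."""
        _, _, st = self.run(self.dt_ms, waveform=waveform, events=events,
                            state=state, record=False, pend=pend)
        return st


def build_single_cell(morph: Morphology, params: Optional[MembraneParams] = None,
                      dt_ms: float = DT_MS) -> CableSim:
    return CableSim([morph], [params or MembraneParams()], dt_ms=dt_ms)


def detect_spikes(
    v_trace_mv: np.ndarray,
    dt_ms: float,
    threshold_mv: float = V_THRESHOLD_MV,
    refractory_ms: float = REFRACTORY_MS,
    t0_ms: float = 0.0,
) -> np.ndarray:
    """Upward threshold crossings of a recorded somatic voltage trace.

    One spike per crossing with a refractory lockout; returns times in ms.
    """
    v = np.asarray(v_trace_mv, dtype=float)
    if v.ndim != 1:
        raise InvalidArgument("expected a 1-D voltage trace")
    above = v >= threshold_mv
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times = []
    last = -math.inf
    for i in crossings:
        t = t0_ms + i * dt_ms
        if t - last >= refractory_ms:
            times.append(t)
            last = t
    return np.asarray(times)


def somatic_polarization(
    morph: Morphology,
    params: Optional[MembraneParams] = None,
    field_mv_per_mm: float = 1.0,
    settle_ms: float = 300.0,
) -> float:
    """Steady-state somatic polarization (mV) under a DC anodic field.

    Measured on the passive membrane (spike channels removed) as the shift
    from the zero-field resting potential; the mechanistic driver of the
    pyramidal/interneuron entrainment asymmetry.
    """
    p = (params or MembraneParams()).passive()
    sim = build_single_cell(morph, p)
    wf = TacsWaveform(freq_hz=0.0, amplitude_ma=field_mv_per_mm,
                      onset_ms=0.0, offset_ms=settle_ms + 1.0)
    _, _, st = sim.run(settle_ms, waveform=wf, record=False)
    soma = sim.soma_comp[0]
    return float(st.v_mv[soma] - p.e_leak_mv)
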