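"""The five-cell cortical microcircuit: assembly, placement and calibration.

Cells (pia to white matter): L1 neurogliaform cell (slow-spiking
interneuron), L2/3 pyramidal cell, L4 large basket cell (fast-spiking
interneuron), L5 thick-tufted pyramidal cell, L6 tufted pyramidal cell.
The default connectivity is 14 directed connections: pyramidal cells excite
each other and the interneurons; interneurons inhibit pyramidal cells (the
basket cell through GABA_A-like contacts only, the neurogliaform cell
through both GABA_A- and slow GABA_B-like contacts).  Interneurons therefore
receive only excitation, pyramidal cells both excitation and inhibition.

Endogenous activity comes from independent per-contact Poisson drive on the
basal dendrites (10-ms mean inter-spike interval per contact).  The drive
weight is the calibration knob: per-cell target firing rates are
(5, 10, 30, 10, 10) Hz for the alpha condition and 5 Hz for every cell in
the theta condition, matched by bisection on the disconnected cell.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dfield, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .cable import CableSim, MembraneParams
from .errors import CalibrationFailure, ConfigError, InvalidArgument
from .field import TacsWaveform
from .morphology import LAYER_LABELS, build_reduced_morphology
from .synapses import RECEPTOR_DEFAULTS

#: Per-cell endogenous target rates (Hz) for the two oscillatory conditions.
TARGET_RATES = {
    "alpha": {"L1_NGC": 5.0, "L23_PC": 10.0, "L4_LBC": 30.0,
              "L5_PC": 10.0, "L6_PC": 10.0},
    "theta": {lab: 5.0 for lab in LAYER_LABELS},
}

#: Stimulation frequency per condition (Hz).
CONDITION_FREQ = {"alpha": 10.0, "theta": 5.0}

#: Soma placement (um): x/y lateral scatter, z cortical depth (pia at +z).
CELL_POSITIONS = {
    "L1_NGC": (-80.0, 40.0, 1150.0),
    "L23_PC": (60.0, -50.0, 700.0),
    "L4_LBC": (-60.0, -60.0, 350.0),
    "L5_PC": (0.0, 0.0, 0.0),
    "L6_PC": (70.0, 60.0, -450.0),
}

#: Poisson-drive geometry: contacts per cell, 10-ms mean ISI per contact.
#: The densely arborized L1 neurogliaform cell carries twice the contact
#: density of the other cells.
N_DRIVE_CONTACTS = {"L1_NGC": 96, "L23_PC": 48, "L4_LBC": 48,
                    "L5_PC": 48, "L6_PC": 48}
DRIVE_INTERVAL_MS = 10.0

#: Default drive weights (uS per contact), calibrated to the target rates
#: on the disconnected cells; recomputed by ``calibrate_drive``.
DEFAULT_DRIVE_WEIGHTS = {
    "alpha": {"L1_NGC": 9.0178e-06, "L23_PC": 6.7345e-05, "L4_LBC": 3.3957e-05,
              "L5_PC": 7.1468e-05, "L6_PC": 7.1468e-05},
    "theta": {"L1_NGC": 9.6469e-06, "L23_PC": 2.4696e-05, "L4_LBC": 3.7683e-06,
              "L5_PC": 3.1139e-05, "L6_PC": 2.9528e-05},
}

#: Membrane parameters: pyramidal cells adapt strongly (regular slow
#: firing); the fast-spiking basket cell adapts weakly.
MEMBRANE = {
    "L1_NGC": MembraneParams(g_m_s_cm2=0.1),
    "L23_PC": MembraneParams(g_na_s_cm2=0.12, g_k_s_cm2=0.03, g_m_s_cm2=0.1),
    "L4_LBC": MembraneParams(g_m_s_cm2=0.02),
    "L5_PC": MembraneParams(g_na_s_cm2=0.12, g_k_s_cm2=0.03, g_m_s_cm2=0.1),
    "L6_PC": MembraneParams(g_na_s_cm2=0.12, g_k_s_cm2=0.03, g_m_s_cm2=0.1),
}

#: The 14-connection default table:
#: (pre, post, receptor, n_contacts, weight_uS_per_contact, delay_ms).
DEFAULT_CONNECTIONS = [
    ("L23_PC", "L5_PC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L23_PC", "L6_PC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L23_PC", "L4_LBC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L23_PC", "L1_NGC", "AMPA_NMDA_like", 3, 5.0e-06, 1.0),
    ("L5_PC", "L23_PC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L5_PC", "L6_PC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L5_PC", "L4_LBC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L6_PC", "L5_PC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L6_PC", "L23_PC", "AMPA_NMDA_like", 3, 2.0e-05, 1.0),
    ("L6_PC", "L1_NGC", "AMPA_NMDA_like", 3, 5.0e-06, 1.0),
    ("L1_NGC", "L23_PC", "GABAA_like+GABAB_like", 3, 1.0e-05, 1.0),
    ("L1_NGC", "L5_PC", "GABAA_like+GABAB_like", 3, 1.0e-05, 1.0),
    ("L4_LBC", "L23_PC", "GABAA_like", 3, 1.0e-05, 1.0),
    ("L4_LBC", "L5_PC", "GABAA_like", 3, 1.0e-05, 1.0),
]


@dataclass(frozen=True)
class CircuitSpec:
    """Declarative description of the microcircuit.

    ``drive_weights`` maps layer label -> uS per drive contact; defaults to
    the pre-calibrated values for the condition.  ``connections`` is a list
    of table rows as in :data:`DEFAULT_CONNECTIONS`.
    """

    condition: str = "alpha"
    connected: bool = True
    connections: Sequence[tuple] = dfield(
        default_factory=lambda: list(DEFAULT_CONNECTIONS))
    drive_weights: Optional[Dict[str, float]] = None
    dt_ms: float = 0.025

    def __post_init__(self) -> None:
        if self.condition not in TARGET_RATES:
            raise InvalidArgument("condition must be 'alpha' or 'theta'")
        for row in self.connections:
            pre, post = row[0], row[1]
            if pre not in LAYER_LABELS or post not in LAYER_LABELS:
                raise ConfigError(f"dangling cell reference in table: {row}")

    @property
    def freq_hz(self) -> float:
        return CONDITION_FREQ[self.condition]

    def weights(self) -> Dict[str, float]:
        return dict(self.drive_weights or DEFAULT_DRIVE_WEIGHTS[self.condition])


class Circuit:
    """An assembled, runnable microcircuit (wraps :class:`CableSim`)."""

    def __init__(self, spec: CircuitSpec, labels: Sequence[str]):
        self.spec = spec
        self.labels = list(labels)
        self.morphologies = [
            build_reduced_morphology(lab).translate(CELL_POSITIONS[lab])
            for lab in self.labels
        ]
        self.sim = CableSim(
            self.morphologies,
            [MEMBRANE[lab] for lab in self.labels],
            dt_ms=spec.dt_ms,
        )
        self.drive_syn: List[List[int]] = []   # per cell, per contact
        self._add_drives()
        self.n_connections = 0
        if spec.connected:
            self._add_connections()

    # -- assembly ----------------------------------------------------------
    def _basal_targets(self, cell_index: int, n: int) -> List[int]:
        m = self.morphologies[cell_index]
        basal = [s.id for s in m.by_kind("basal")]
        return [basal[i % len(basal)] for i in range(n)]

    def _add_drives(self) -> None:
        weights = self.spec.weights()
        self.drive_weight = [weights[lab] for lab in self.labels]
        tau1, tau2, e = RECEPTOR_DEFAULTS["AMPA_NMDA_like"]
        for ci in range(len(self.labels)):
            targets = self._basal_targets(
                ci, N_DRIVE_CONTACTS[self.labels[ci]])
            self.drive_syn.append(
                [self.sim.add_synapse(ci, t, e, tau1, tau2) for t in targets]
            )

    def _add_connections(self) -> None:
        index = {lab: i for i, lab in enumerate(self.labels)}
        for pre, post, receptor, n_contacts, weight, delay in self.spec.connections:
            if pre not in index or post not in index:
                raise ConfigError(f"connection references absent cell {pre}->{post}")
            ci_pre, ci_post = index[pre], index[post]
            receptors = receptor.split("+")
            post_m = self.morphologies[ci_post]
            basal = [s.id for s in post_m.by_kind("basal")]
            soma = post_m.root.id
            for k in range(int(n_contacts)):
                rec = receptors[k % len(receptors)]
                tau1, tau2, e = RECEPTOR_DEFAULTS[rec]
                # inhibitory GABA_A contacts target the soma, everything
                # else distributes over basal dendrites
                seg = soma if rec == "GABAA_like" else basal[k % len(basal)]
                syn = self.sim.add_synapse(ci_post, seg, e, tau1, tau2)
                self.sim.connect(ci_pre, syn, float(weight), float(delay))
            self.n_connections += 1

    # -- drive events ------------------------------------------------------
    def drive_events(self, duration_ms: float, base_seed: int, trial: int):
        """Poisson drive for all cells: ``(times, syn_indices, weights)``.

        Each contact's train derives from ``(base_seed, condition, trial,
        cell_label, contact)`` so a cell's drive is identical whether it is
        simulated alone or inside the circuit, connected or not.
        """
        cond_code = 0 if self.spec.condition == "alpha" else 1
        ev_t, ev_s, ev_w = [], [], []
        for ci, lab in enumerate(self.labels):
            lab_code = LAYER_LABELS.index(lab)
            w = self.drive_weight[ci]
            for k, syn in enumerate(self.drive_syn[ci]):
                rng = np.random.default_rng(np.random.SeedSequence(
                    (int(base_seed), cond_code, int(trial), lab_code, k)))
                n_mean = duration_ms / DRIVE_INTERVAL_MS
                n_draw = int(n_mean + 6.0 * math.sqrt(n_mean) + 16)
                t = np.cumsum(rng.exponential(DRIVE_INTERVAL_MS, size=n_draw))
                while t.size and t[-1] < duration_ms:
                    t = np.concatenate([t, t[-1] + np.cumsum(
                        rng.exponential(DRIVE_INTERVAL_MS, size=n_draw))])
                t = t[t < duration_ms]
                ev_t.append(t)
                ev_s.append(np.full(t.size, syn, dtype=np.int64))
                ev_w.append(np.full(t.size, w))
        ev_t = np.concatenate(ev_t)
        ev_s = np.concatenate(ev_s)
        ev_w = np.concatenate(ev_w)
        order = np.argsort(ev_t, kind="stable")
        return ev_t[order], ev_s[order], ev_w[order]

    def run_trial_raw(self, duration_ms: float, waveform: Optional[TacsWaveform],
                      base_seed: int, trial: int, record: bool = True):
        events = self.drive_events(duration_ms, base_seed, trial)
        return self.sim.run(duration_ms, waveform=waveform, events=events,
                            record=record)


def assemble(spec: CircuitSpec) -> Circuit:
    """Instantiate the runnable circuit described by ``spec``.

    ``spec.connected = False`` yields five cells with Poisson drive only
    (the disconnected ablation); their spike trains are then bit-identical
    to running each cell alone with the same seeds.
    """
    return Circuit(spec, LAYER_LABELS)


def single_cell_circuit(layer_label: str, spec: Optional[CircuitSpec] = None,
                        drive_weight: Optional[float] = None) -> Circuit:
    """One cell of the circuit in isolation (used for calibration)."""
    base = spec or CircuitSpec(connected=False)
    weights = base.weights()
    if drive_weight is not None:
        weights[layer_label] = drive_weight
    solo = replace(base, connected=False, drive_weights=weights)
    return Circuit(solo, [layer_label])


def measure_rate(layer_label: str, drive_weight: float, condition: str,
                 seed_set: Sequence[int], duration_ms: float = 4000.0,
                 discard_ms: float = 500.0, dt_ms: float = 0.025) -> float:
    """Mean firing rate (Hz) of an isolated cell over a seed set."""
    spec = CircuitSpec(condition=condition, connected=False, dt_ms=dt_ms)
    circ = single_cell_circuit(layer_label, spec, drive_weight)
    rates = []
    for s in seed_set:
        spikes, _, _ = circ.run_trial_raw(duration_ms, None, s, 0, record=False)
        n = np.count_nonzero(spikes[0] > discard_ms)
        rates.append(n / ((duration_ms - discard_ms) / 1000.0))
    return float(np.mean(rates))


def calibrate_drive(
    layer_label: str,
    target_rate_hz: float,
    tolerance_hz: float = 0.25,
    seed_set: Sequence[int] = (0, 1, 2),
    condition: str = "alpha",
    w_lo: float = 5e-7,
    w_hi: float = 3.2e-4,
    duration_ms: float = 4000.0,
    max_iter: int = 24,
) -> float:
    """Drive weight (uS/contact) giving the target rate on the isolated cell.

    Monotone bisection on the drive weight at the fixed 10-ms mean input
    interval; the search bounds must bracket the target (the upper bound
    stays below the depolarization-block regime).  Deterministic given
    ``seed_set``.
    """
    if target_rate_hz <= 0 or tolerance_hz <= 0:
        raise InvalidArgument("target and tolerance must be positive")
    r_lo = measure_rate(layer_label, w_lo, condition, seed_set, duration_ms)
    if r_lo > target_rate_hz:
        raise CalibrationFailure(
            f"lower bound already exceeds {target_rate_hz} Hz "
            f"(rate({w_lo}) = {r_lo:.2f})"
        )
    # geometric scan for an upper bracket; the rate-weight curve rises
    # monotonically up to the depolarization-block regime, where it falls
    # again, so stop as soon as the rate decreases
    w, r_prev = w_lo, r_lo
    lo, hi = w_lo, None
    while w < w_hi:
        w = min(w * 1.6, w_hi)
        r = measure_rate(layer_label, w, condition, seed_set, duration_ms)
        if r >= target_rate_hz:
            hi = w
            break
        if r < r_prev - max(1.0, 0.2 * target_rate_hz):
            break  # entering depolarization block without bracketing
        lo, r_prev = w, r
    if hi is None:
        raise CalibrationFailure(
            f"search bounds do not bracket {target_rate_hz} Hz below the "
            f"depolarization-block regime (last rate {r_prev:.2f} Hz)"
        )
    best_w, best_err = lo, abs(r_prev - target_rate_hz)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = measure_rate(layer_label, mid, condition, seed_set, duration_ms)
        err = abs(r - target_rate_hz)
        if err < best_err:
            best_w, best_err = mid, err
        if err <= tolerance_hz:
            return mid
        if r < target_rate_hz:
            lo = mid
        else:
            hi = mid
    if best_err <= 2 * tolerance_hz:
        return best_w
    raise CalibrationFailure(
        f"no weight within {tolerance_hz} Hz of {target_rate_hz} Hz after "
        f"{max_iter} bisection steps (best error {best_err:.2f} Hz)"
    )


def calibrate_condition(condition: str, tolerance_hz: float = 0.25,
                        seed_set: Sequence[int] = (0, 1, 2),
                        duration_ms: float = 4000.0) -> Dict[str, float]:
    """Calibrated drive weights for all five cells of one condition."""
    return {
        lab: calibrate_drive(lab, TARGET_RATES[condition][lab],
                             tolerance_hz, seed_set, condition,
                             duration_ms=duration_ms)
        for lab in LAYER_LABELS
    }


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def write_connection_table(rows: Sequence[tuple], path) -> None:
    """Write the connectivity table as delimited text."""
    lines = ["pre\tpost\treceptor\tn_contacts\tweight_us\tdelay_ms"]
    for pre, post, rec, n, w, d in rows:
        lines.append(f"{pre}\t{post}\t{rec}\t{n}\t{w:g}\t{d:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_connection_table(path) -> List[tuple]:
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or i == 0:
            continue
        pre, post, rec, n, w, d = line.split("\t")
        rows.append((pre, post, rec, int(n), float(w), float(d)))
    return rows


def spec_to_json(spec: CircuitSpec, path) -> None:
    Path(path).write_text(json.dumps({
        "condition": spec.condition,
        "connected": spec.connected,
        "connections": [list(r) for r in spec.connections],
        "drive_weights": spec.weights(),
        "dt_ms": spec.dt_ms,
    }, indent=2) + "\n")


def spec_from_json(path) -> CircuitSpec:
    d = json.loads(Path(path).read_text())
    return CircuitSpec(
        condition=d["condition"],
        connected=d["connected"],
        connections=[tuple(r) for r in d["connections"]],
        drive_weights=d.get("drive_weights"),
        dt_ms=d.get("dt_ms", 0.025),
    )
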