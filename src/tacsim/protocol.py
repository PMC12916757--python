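"""Experimental protocol: epoch structure, amplitude sweep, seeded replicates.

The reference trial lasts 15 s: 2.5 s pre-stimulation, 10 s of active
stimulation, 2.5 s post-stimulation, with amplitudes swept from 0 to 2 mA
and 20 independent replicates per amplitude (each with fresh Poisson-drive
seeds).  A desk-scale variant (shorter epochs, fewer amplitudes and trials)
ships alongside for quick runs; it preserves the trial anatomy.

Trial randomness is a pure function of ``(base_seed, condition, trial)``,
so grids can be run in any order or resumed without changing results.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .circuit import Circuit, CircuitSpec, assemble
from .errors import InvalidArgument, NumericalFailure
from .field import TacsWaveform, waveform_phase
from .lfp import Electrode, LfpTrace, compute_lfp

DEFAULT_AMPLITUDES = tuple(round(0.1 * k, 1) for k in range(0, 21))


@dataclass(frozen=True)
class StimulusProtocol:
    """Trial anatomy and sweep structure."""

    pre_ms: float = 2500.0
    stim_ms: float = 10000.0
    post_ms: float = 2500.0
    amplitudes_ma: Sequence[float] = DEFAULT_AMPLITUDES
    freq_hz: float = 10.0
    n_trials: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise InvalidArgument("n_trials must be >= 1")
        if any(a < 0 for a in self.amplitudes_ma):
            raise InvalidArgument("amplitudes must be >= 0")
        if min(self.pre_ms, self.stim_ms, self.post_ms) < 0 or self.stim_ms <= 0:
            raise InvalidArgument("epoch durations must be positive")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.stim_ms + self.post_ms

    @property
    def stim_window_ms(self) -> tuple:
        return (self.pre_ms, self.pre_ms + self.stim_ms)

    def waveform(self, amplitude_ma: float) -> Optional[TacsWaveform]:
        if amplitude_ma == 0.0:
            return None  # baseline: a full trial without any field
        return TacsWaveform(
            freq_hz=self.freq_hz, amplitude_ma=amplitude_ma,
            onset_ms=self.pre_ms, offset_ms=self.pre_ms + self.stim_ms,
        )

    @classmethod
    def paper_scale(cls, condition_freq_hz: float = 10.0,
                    base_seed: int = 0) -> "StimulusProtocol":
        return cls(freq_hz=condition_freq_hz, base_seed=base_seed)

    @classmethod
    def desk_scale(cls, condition_freq_hz: float = 10.0, base_seed: int = 0,
                   amplitudes=(0.0, 0.5, 1.0, 2.0),
                   n_trials: int = 5) -> "StimulusProtocol":
        """Scaled-down grid: 1-s flanks, 6-s stimulation, fewer replicates."""
        return cls(pre_ms=1000.0, stim_ms=6000.0, post_ms=1000.0,
                   amplitudes_ma=tuple(amplitudes), freq_hz=condition_freq_hz,
                   n_trials=n_trials, base_seed=base_seed)


@dataclass
class TrialRecord:
    """Observables of one simulated trial."""

    condition: str
    amplitude_ma: float
    freq_hz: float
    connected: bool
    trial: int
    base_seed: int
    spikes_ms: Dict[str, np.ndarray]
    lfp: LfpTrace
    stim_phase_deg: np.ndarray    # NaN outside the active window
    stim_window_ms: tuple
    total_ms: float

    def stim_spike_phases(self, cell: str) -> np.ndarray:
        """Stimulus phases (deg) of a cell's spikes inside the active window."""
        lo, hi = self.stim_window_ms
        s = self.spikes_ms[cell]
        s = s[(s >= lo) & (s < hi)]
        if s.size == 0 or self.amplitude_ma == 0.0:
            return np.zeros(0)
        wf = TacsWaveform(freq_hz=self.freq_hz, amplitude_ma=self.amplitude_ma,
                          onset_ms=lo, offset_ms=hi)
        return np.atleast_1d(waveform_phase(s, wf))

    def rate_hz(self, cell: str, window: Optional[tuple] = None) -> float:
        lo, hi = window or self.stim_window_ms
        s = self.spikes_ms[cell]
        n = np.count_nonzero((s >= lo) & (s < hi))
        return n / ((hi - lo) / 1000.0)


def run_trial(circuit: Circuit, protocol: StimulusProtocol,
              amplitude_ma: float, trial_index: int,
              electrode: Optional[Electrode] = None) -> TrialRecord:
    """Simulate one seeded trial and derive its observables.

    Deterministic for fixed ``(protocol.base_seed, circuit condition,
    trial_index)``; the field is active only during the stimulation window
    (an amplitude of 0 mA runs the whole trial with no field at all).
    """
    if trial_index >= protocol.n_trials:
        raise InvalidArgument("trial_index beyond protocol.n_trials")
    wf = protocol.waveform(amplitude_ma)
    spikes, recording, _ = circuit.run_trial_raw(
        protocol.total_ms, wf, protocol.base_seed, trial_index, record=True)
    t_ms, imem, _vsoma = recording
    lfp = compute_lfp(t_ms, imem, circuit.sim.midpoints_um, electrode)
    phase = np.full(t_ms.size, np.nan)
    if wf is not None:
        lo, hi = protocol.stim_window_ms
        mask = (t_ms >= lo) & (t_ms <= hi)
        phase[mask] = waveform_phase(t_ms[mask], wf)
    return TrialRecord(
        condition=circuit.spec.condition,
        amplitude_ma=amplitude_ma,
        freq_hz=protocol.freq_hz,
        connected=circuit.spec.connected,
        trial=trial_index,
        base_seed=protocol.base_seed,
        spikes_ms={lab: s for lab, s in zip(circuit.labels, spikes)},
        lfp=lfp,
        stim_phase_deg=phase,
        stim_window_ms=protocol.stim_window_ms,
        total_ms=protocol.total_ms,
    )


# ---------------------------------------------------------------------------
# Grid running with persistence
# ---------------------------------------------------------------------------

def _record_paths(out_dir: Path, amplitude_ma: float, trial: int):
    tag = f"amp{amplitude_ma:g}_trial{trial:02d}"
    return out_dir / f"spikes_{tag}.tsv", out_dir / f"lfp_{tag}.tsv"


def save_record(rec: TrialRecord, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spike_path, lfp_path = _record_paths(out_dir, rec.amplitude_ma, rec.trial)
    with open(spike_path, "w") as fh:
        fh.write("cell_id\ttime_ms\n")
        for lab, s in rec.spikes_ms.items():
            for t in s:
                fh.write(f"{lab}\t{t:.4f}\n")
    with open(lfp_path, "w") as fh:
        fh.write("time_ms\tlfp_uv\tstim_phase_deg\n")
        for t, v, p in zip(rec.lfp.t_ms, rec.lfp.values_uv, rec.stim_phase_deg):
            fh.write(f"{t:.3f}\t{v:.6e}\t{p:.3f}\n")


def run_grid(
    spec: CircuitSpec,
    protocol: StimulusProtocol,
    out_dir,
    electrode: Optional[Electrode] = None,
    log=None,
) -> dict:
    """Run the amplitude x trial grid and persist per-trial text records.

    Writes a JSON manifest listing every completed record with its seeds
    and condition; completed records found on disk are skipped, so an
    interrupted grid resumes idempotently.  Trials that fail numerically
    are flagged in the manifest and excluded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    manifest = {"condition": spec.condition, "connected": spec.connected,
                "base_seed": protocol.base_seed,
                "freq_hz": protocol.freq_hz,
                "epochs_ms": [protocol.pre_ms, protocol.stim_ms, protocol.post_ms],
                "records": {}, "failed": {}}
    if manifest_path.exists():
        manifest.update(json.loads(manifest_path.read_text()))
    circuit = assemble(spec)
    for amp in protocol.amplitudes_ma:
        for trial in range(protocol.n_trials):
            key = f"amp{amp:g}_trial{trial:02d}"
            spike_path, lfp_path = _record_paths(out_dir, amp, trial)
            if key in manifest["records"] and spike_path.exists():
                continue
            t0 = _time.time()
            try:
                rec = run_trial(circuit, protocol, amp, trial, electrode)
            except NumericalFailure as exc:
                manifest["failed"][key] = str(exc)
                manifest_path.write_text(json.dumps(manifest, indent=2))
                continue
            save_record(rec, out_dir)
            manifest["records"][key] = {
                "amplitude_ma": amp, "trial": trial,
                "seed": [protocol.base_seed, spec.condition, trial],
                "spikes": spike_path.name, "lfp": lfp_path.name,
                "wall_s": round(_time.time() - t0, 2),
            }
            manifest_path.write_text(json.dumps(manifest, indent=2))
            if log is not None:
                log(f"{key}: {manifest['records'][key]['wall_s']} s")
    return manifest


def load_spikes(path) -> Dict[str, np.ndarray]:
    out: Dict[str, list] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if i == 0 or not line.strip():
            continue
        lab, t = line.split("\t")
        out.setdefault(lab, []).append(float(t))
    return {k: np.asarray(v) for k, v in out.items()}


def load_lfp(path):
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    return LfpTrace(t_ms=data[:, 0], values_uv=data[:, 1]), data[:, 2]
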