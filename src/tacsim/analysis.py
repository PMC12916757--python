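"""Study-level procedures built on the metrics pipeline.

These functions run the reduced circuit over a protocol grid in memory and
condense it into the quantities the analyses report: per-cell firing-rate
invariance under stimulation, aggregated PLV versus intensity with per-cell
regressions, squared-PLV-versus-PPC consistency on synthetic phase samples,
and epoch-wise LFP cross-correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .circuit import CircuitSpec, assemble
from .errors import InvalidArgument
from .metrics import (
    EntrainmentSummary,
    aggregate_phases,
    linfit,
    plv,
    ppc,
    summarize_phases,
)
from .morphology import PYRAMIDAL
from .protocol import StimulusProtocol, TrialRecord, run_trial
from .synthetic import sample_von_mises


def run_condition_grid(
    spec: CircuitSpec,
    protocol: StimulusProtocol,
) -> List[TrialRecord]:
    """All trial records of the amplitude x trial grid, kept in memory."""
    circuit = assemble(spec)
    out = []
    for amp in protocol.amplitudes_ma:
        for trial in range(protocol.n_trials):
            out.append(run_trial(circuit, protocol, amp, trial))
    return out


def rates_by_amplitude(records: Sequence[TrialRecord]) -> Dict[float, Dict[str, np.ndarray]]:
    """Per-amplitude, per-cell arrays of single-trial stimulation-window rates."""
    table: Dict[float, Dict[str, list]] = {}
    for rec in records:
        cell_map = table.setdefault(rec.amplitude_ma, {})
        for cell in rec.spikes_ms:
            cell_map.setdefault(cell, []).append(rec.rate_hz(cell))
    return {a: {c: np.asarray(v) for c, v in m.items()} for a, m in table.items()}


def max_rate_change_percent(records: Sequence[TrialRecord],
                            baseline_ma: float = 0.0,
                            stim_ma: Optional[float] = None) -> float:
    """Largest per-cell |percent change| of mean rate vs the 0-mA baseline.

    Rates are normalized to the mean rate across baseline trials, as in the
    firing-rate-invariance analysis.
    """
    rates = rates_by_amplitude(records)
    if baseline_ma not in rates:
        raise InvalidArgument("no baseline (0 mA) records in the grid")
    if stim_ma is None:
        stim_ma = max(rates)
    worst = 0.0
    for cell, base in rates[baseline_ma].items():
        base_mean = float(np.mean(base))
        if base_mean <= 0:
            raise InvalidArgument(f"zero baseline rate for {cell}")
        change = abs(np.mean(rates[stim_ma][cell]) / base_mean - 1.0) * 100.0
        worst = max(worst, float(change))
    return worst


def entrainment_by_amplitude(
    records: Sequence[TrialRecord],
) -> Dict[float, Dict[str, EntrainmentSummary]]:
    """Aggregate stimulation-window spike phases over trials, per cell/amplitude.

    Phases from all replicates of a condition are pooled before computing a
    single PLV / preferred phase per cell and amplitude.
    """
    pooled: Dict[float, Dict[str, list]] = {}
    for rec in records:
        if rec.amplitude_ma == 0.0:
            continue
        cell_map = pooled.setdefault(rec.amplitude_ma, {})
        for cell in rec.spikes_ms:
            ph = rec.stim_spike_phases(cell)
            if ph.size:
                cell_map.setdefault(cell, []).append(ph)
    out: Dict[float, Dict[str, EntrainmentSummary]] = {}
    for amp, cell_map in pooled.items():
        band = records[0].condition
        out[amp] = {
            cell: summarize_phases(aggregate_phases(chunks), cell=cell,
                                   amplitude_ma=amp, band=band)
            for cell, chunks in cell_map.items()
        }
    return out


def plv_intensity_regression(
    summaries: Dict[float, Dict[str, EntrainmentSummary]],
    cells: Sequence[str] = PYRAMIDAL,
    min_amplitude_ma: float = 0.4,
) -> Dict[str, tuple]:
    """Per-cell OLS of aggregated PLV on stimulation amplitude.

    Restricted to amplitudes at and above ``min_amplitude_ma`` (the linear
    regime; below it, cells whose endogenous preferred phase disagrees with
    the stimulus can transiently desynchronize).  Returns
    ``cell -> (slope, intercept, r_squared)``.
    """
    amps = sorted(a for a in summaries if a >= min_amplitude_ma)
    if len(amps) < 3:
        raise InvalidArgument("need at least 3 amplitudes above the threshold")
    out = {}
    for cell in cells:
        y = [summaries[a][cell].plv for a in amps]
        out[cell] = linfit(np.asarray(amps), np.asarray(y))
    return out


@dataclass(frozen=True)
class PpcPlvRegression:
    slope: float
    intercept: float
    r_squared: float
    n_samples: int


def ppc_plv_consistency(
    kappas: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
    n_per_sample: int = 1000,
    seeds: Sequence[int] = (0, 1),
    mu_deg: float = 315.0,
) -> PpcPlvRegression:
    """Regress squared PLV on PPC over synthetic von Mises phase samples.

    The two statistics agree up to an O(1/n) sample-size correction
    (``PLV**2 = PPC + (1 - PPC)/n``), so the regression has slope just
    below 1, intercept of order 1/n and R^2 near 1 — the check that PLV
    estimates are not biased by limited spike counts.
    """
    xs, ys = [], []
    for seed in seeds:
        for i, k in enumerate(kappas):
            sample = sample_von_mises(mu_deg, k, n_per_sample,
                                      seed=1000 * (seed + 1) + i)
            xs.append(ppc(sample))
            ys.append(plv(sample) ** 2)
    slope, intercept, r2 = linfit(np.asarray(xs), np.asarray(ys))
    return PpcPlvRegression(slope, intercept, r2, len(xs))


def theta_stim_spike_count(
    records: Sequence[TrialRecord], cell: str = "L5_PC"
) -> float:
    """Mean spike count of one cell inside the active stimulation window."""
    counts = []
    for rec in records:
        lo, hi = rec.stim_window_ms
        s = rec.spikes_ms[cell]
        counts.append(int(np.count_nonzero((s >= lo) & (s < hi))))
    return float(np.mean(counts))
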