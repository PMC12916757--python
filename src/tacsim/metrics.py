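"""Entrainment quantification: cross-correlation, phase coherence, PLV, PPC,
circular statistics, hypothesis tests and the summary regressions.

Conventions
-----------
* All phases at the interface are degrees; 0 deg = stimulus-waveform peak.
* PLV is the modulus of the mean unit phasor of spike phases, in [0, 1].
* PPC is the mean cosine of all pairwise phase differences, in [-1, 1];
  it is the sample-size-unbiased counterpart of PLV**2 and satisfies
  ``PPC = (n*PLV**2 - 1)/(n - 1)`` exactly (used as a cross-check, not as
  the implementation, which sums pairs directly).
* A 15-s trial splits into six half-open 2.5-s epochs: pre-stimulation,
  four active stimulation epochs, post-stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .errors import InvalidArgument, UndefinedStatistic
from .synthetic import PhaseSample


# ---------------------------------------------------------------------------
# Summary containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntrainmentSummary:
    """Per cell/amplitude/band phase-locking summary."""

    cell: str
    amplitude_ma: float
    band: str
    plv: float
    ppc: float
    preferred_phase_deg: float
    circ_sd_deg: float
    n_spikes: int
    rayleigh_p: float


@dataclass(frozen=True)
class EpochCorrelation:
    """Six per-epoch zero-lag correlations for one trace pair."""

    pair: tuple
    r: np.ndarray  # length 6: pre, stim1..4, post

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (6,):
            raise InvalidArgument("expected exactly 6 epoch correlations")
        object.__setattr__(self, "r", r)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def zero_lag_xcorr(x: np.ndarray, y: np.ndarray) -> float:
    """Zero-lag cross-correlation (Pearson form), in [-1, 1].

    1 means identical temporal patterns, -1 perfectly inverse ones.
    Raises :class:`UndefinedStatistic` for a zero-variance input rather than
    silently returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidArgument("x and y must be equal-length 1-D arrays, n >= 2")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        raise UndefinedStatistic("correlation undefined for zero-variance input")
    return float(np.clip((xd @ yd) / denom, -1.0, 1.0))


def epoch_xcorr(
    traces: Sequence[np.ndarray],
    dt_ms: float = 1.0,
    epoch_len_ms: float = 2500.0,
    n_epochs: int = 6,
) -> list[EpochCorrelation]:
    """Per-epoch zero-lag correlations for every pair of trial traces.

    Each trace is cut into ``n_epochs`` consecutive half-open windows of
    ``epoch_len_ms`` (pre, active epochs, post for the default protocol) and
    correlated window-by-window with every other trace: C(n, 2) pairs.
    """
    n_samp = int(round(epoch_len_ms / dt_ms))
    need = n_samp * n_epochs
    arrs = [np.asarray(t, dtype=float) for t in traces]
    for a in arrs:
        if a.size < need:
            raise InvalidArgument(
                f"trace of length {a.size} cannot cover {n_epochs} epochs "
                f"of {n_samp} samples"
            )
    out = []
    for i, j in combinations(range(len(arrs)), 2):
        r = np.empty(n_epochs)
        for e in range(n_epochs):
            sl = slice(e * n_samp, (e + 1) * n_samp)
            r[e] = zero_lag_xcorr(arrs[i][sl], arrs[j][sl])
        if n_epochs == 6:
            out.append(EpochCorrelation(pair=(i, j), r=r))
        else:  # non-default epoching used by scaled protocols
            ec = EpochCorrelation.__new__(EpochCorrelation)
            object.__setattr__(ec, "pair", (i, j))
            object.__setattr__(ec, "r", r)
            out.append(ec)
    return out


# ---------------------------------------------------------------------------
# Phase-based metrics
# ---------------------------------------------------------------------------

def _as_phase_array(sample) -> np.ndarray:
    if isinstance(sample, PhaseSample):
        return sample.phases
    ph = np.asarray(sample, dtype=float)
    if ph.ndim != 1 or ph.size < 1:
        raise InvalidArgument("phase sample must be a non-empty 1-D sequence")
    return ph % 360.0


def phase_coherence(theta_tacs_deg: np.ndarray, theta_lfp_deg: np.ndarray) -> float:
    """Modulus of the mean phasor of the phase difference, in [0, 1].

    1 iff the stimulus-to-signal phase difference is constant over the
    window; for independent uniform phases the null level decays as
    ``n**-0.5``.
    """
    a = np.asarray(theta_tacs_deg, dtype=float)
    b = np.asarray(theta_lfp_deg, dtype=float)
    if a.size == 0 or a.shape != b.shape:
        raise InvalidArgument("phase series must be equal-length and non-empty")
    d = np.deg2rad(a - b)
    return float(np.abs(np.exp(1j * d).mean()))


def sliding_phase_coherence(
    theta_tacs_deg: np.ndarray,
    theta_lfp_deg: np.ndarray,
    dt_ms: float = 1.0,
    window_ms: float = 2500.0,
    step_ms: float = 100.0,
):
    """Windowed phase coherence (2.5-s window, 0.1-s steps by default).

    Returns ``(window_start_ms, coherence)`` arrays, one value per step.
    """
    a = np.asarray(theta_tacs_deg, dtype=float)
    b = np.asarray(theta_lfp_deg, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgument("phase series must be equal length")
    w = int(round(window_ms / dt_ms))
    s = int(round(step_ms / dt_ms))
    if w < 1 or w > a.size:
        raise InvalidArgument("window longer than the phase series")
    starts = np.arange(0, a.size - w + 1, s)
    coh = np.array([phase_coherence(a[i : i + w], b[i : i + w]) for i in starts])
    return starts * dt_ms, coh


def plv(sample) -> float:
    """Phase-locking value: modulus of the mean unit phasor, in [0, 1]."""
    ph = _as_phase_array(sample)
    return float(np.abs(np.exp(1j * np.deg2rad(ph)).mean()))


def ppc(sample) -> float:
    """Pairwise phase consistency: mean cosine of all pairwise differences.

    Computed by direct summation over the N(N-1)/2 pairs (chunked for large
    samples); in [-1, 1], 0 for uniform phases, 1 for perfect locking.
    """
    ph = _as_phase_array(sample)
    n = ph.size
    if n < 2:
        raise InvalidArgument("PPC requires at least 2 phases")
    rad = np.deg2rad(ph)
    total = 0.0
    chunk = 2000
    for i0 in range(0, n, chunk):
        block = rad[i0 : i0 + chunk]
        # pairs within the block (upper triangle)
        d = block[:, None] - block[None, :]
        total += float(np.cos(d[np.triu_indices(block.size, k=1)]).sum())
        # pairs between this block and everything after it
        rest = rad[i0 + block.size :]
        if rest.size:
            total += float(np.cos(block[:, None] - rest[None, :]).sum())
    return 2.0 * total / (n * (n - 1))


def ppc_from_plv(plv_value: float, n: int) -> float:
    """Algebraic identity ``(n*PLV**2 - 1)/(n - 1)`` (cross-check route)."""
    if n < 2:
        raise InvalidArgument("identity requires n >= 2")
    return (n * plv_value**2 - 1.0) / (n - 1.0)


def preferred_phase(sample) -> float:
    """Circular mean of the phases, degrees in [0, 360).

    Undefined (raises) when the resultant vector length is zero.
    """
    ph = _as_phase_array(sample)
    z = np.exp(1j * np.deg2rad(ph)).mean()
    if np.abs(z) < 1e-12:
        raise UndefinedStatistic("preferred phase undefined for PLV = 0")
    mean = float(np.rad2deg(np.angle(z)) % 360.0)
    return 0.0 if mean >= 360.0 else mean


def circ_sd(sample) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` in degrees."""
    ph = _as_phase_array(sample)
    if ph.size < 2:
        raise InvalidArgument("circular SD requires n >= 2")
    return float(
        np.rad2deg(spstats.circstd(np.deg2rad(ph), high=2 * np.pi, low=0.0))
    )


def rayleigh_test(sample) -> float:
    """Rayleigh test p-value for non-uniformity of a circular sample.

    ``Z = n * PLV**2`` with the standard series approximation
    ``p = exp(-Z) * (1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2))``.
    """
    ph = _as_phase_array(sample)
    n = ph.size
    if n < 2:
        raise InvalidArgument("Rayleigh test requires n >= 2")
    z = n * plv(ph) ** 2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(min(max(p, 0.0), 1.0))


def summarize_phases(
    sample, cell: str = "", amplitude_ma: float = 0.0, band: str = ""
) -> EntrainmentSummary:
    """Full circular summary of one phase sample."""
    ph = _as_phase_array(sample)
    v = plv(ph)
    return EntrainmentSummary(
        cell=cell,
        amplitude_ma=amplitude_ma,
        band=band,
        plv=v,
        ppc=ppc(ph) if ph.size >= 2 else float("nan"),
        preferred_phase_deg=preferred_phase(ph) if v > 1e-12 else float("nan"),
        circ_sd_deg=circ_sd(ph) if ph.size >= 2 else float("nan"),
        n_spikes=int(ph.size),
        rayleigh_p=rayleigh_test(ph) if ph.size >= 2 else float("nan"),
    )


def aggregate_phases(samples: Sequence) -> PhaseSample:
    """Pool spike phases across trials by concatenation.

    Phases from independent trials of one condition are aggregated into a
    single sample before computing PLV/PPC, equivalent to the length-weighted
    resultant-vector combination of per-trial statistics.
    """
    arrays = [_as_phase_array(s) for s in samples if np.asarray(s).size > 0]
    if not arrays:
        raise InvalidArgument("no phases to aggregate")
    return PhaseSample(np.concatenate(arrays))


# ---------------------------------------------------------------------------
# Hypothesis tests and regressions
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    paired_a, paired_b, zero_method: str = "wilcox"
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (``wilcox``; ``pratt`` available), ties get
    mid-ranks.  All-zero differences are a degenerate test and raise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgument("paired samples must be equal-length 1-D arrays")
    if np.all(a == b):
        raise UndefinedStatistic("all paired differences are zero")
    res = spstats.wilcoxon(a, b, zero_method=zero_method, alternative="two-sided")
    return float(res.pvalue)


def normalized_firing_rate(trial_rates, baseline_mean: float) -> np.ndarray:
    """Rates divided by the 0-mA baseline mean; 1.0 means unchanged."""
    if baseline_mean <= 0:
        raise InvalidArgument("baseline mean rate must be positive")
    return np.asarray(trial_rates, dtype=float) / float(baseline_mean)


def percent_change(ratio) -> np.ndarray:
    """Normalized-rate ratio expressed as percent change from baseline."""
    return (np.asarray(ratio, dtype=float) - 1.0) * 100.0


def linfit(x, y):
    """Ordinary least squares of y on x: ``(slope, intercept, r_squared)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InvalidArgument("linfit requires equal-length arrays with n >= 3")
    if np.ptp(x) == 0:
        raise InvalidArgument("x must not be constant")
    res = spstats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def polar_to_cartesian(summaries: Sequence[EntrainmentSummary]):
    """(x, y) = (r cos(theta), r sin(theta)) for each summary's (phase, PLV).

    Summaries with an undefined preferred phase are skipped.  Returns
    ``(amplitudes, x, y)`` arrays suitable for per-axis regression against
    stimulation intensity.
    """
    amps, xs, ys = [], [], []
    for s in summaries:
        if not np.isfinite(s.preferred_phase_deg):
            continue
        th = math.radians(s.preferred_phase_deg)
        amps.append(s.amplitude_ma)
        xs.append(s.plv * math.cos(th))
        ys.append(s.plv * math.sin(th))
    return np.asarray(amps), np.asarray(xs), np.asarray(ys)


def cartesian_to_polar(x: float, y: float):
    """Inverse of the Cartesian conversion: ``(theta_deg, r)``."""
    return float(np.rad2deg(math.atan2(y, x)) % 360.0), float(math.hypot(x, y))


def polar_histogram(sample, n_bins: int = 36):
    """Counts of phases in half-open bins over [0, 360), first bin at 0.

    Returns ``(bin_edges_deg, counts)``; counts sum to n.
    """
    if n_bins < 1:
        raise InvalidArgument("n_bins must be >= 1")
    ph = _as_phase_array(sample)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(ph, bins=edges)
    return edges, counts


# ---------------------------------------------------------------------------
# LFP phase extraction (analytic signal)
# ---------------------------------------------------------------------------

def instantaneous_phase(trace: np.ndarray) -> np.ndarray:
    """Instantaneous phase (deg, 0 = local peak) via the Hilbert transform.

    Apply to a band-passed trace; the analytic-signal angle is 0 at each
    oscillation peak, matching the stimulus phase convention.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 4:
        raise InvalidArgument("trace too short for phase extraction")
    return np.rad2deg(np.angle(sps.hilbert(x - x.mean()))) % 360.0
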