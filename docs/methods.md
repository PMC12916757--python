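# Methods

`tacsim` simulates how weak transcranial alternating current stimulation
(tACS) entrains spiking in a five-cell cortical microcircuit, and provides
the complete analysis pipeline used to quantify that entrainment. This note
documents the model, its assumptions, the tunable parameters, the
synthetic-data generators, and the numerical choices, in enough detail to
reproduce or criticize any piece.

## The biophysical model

### Cable equation with an extracellular field term

Each neuron is a tree of cylindrical compartments obeying the cable
equation. An applied electric field enters through the extracellular
potential: under the quasi-uniform approximation a spatially uniform field
**E**(t) sets the extracellular potential at position x to
`V_e(x, t) = -E(t) . x`. Gradients of `V_e` along the neurite drive axial
currents exactly as gradients of the intracellular potential do, so the
field term appears as a per-branch forcing `g_axial * (V_e,parent -
V_e,child)` in the compartmental equations. A closed consequence used as a
test oracle: a passive cable of length L and space constant lambda in a
uniform parallel field E polarizes as
`V(x) = lambda E sinh((x - L/2)/lambda) / cosh(L/(2 lambda))`, with
terminal polarization `lambda E tanh(L/(2 lambda))`; the solver reproduces
this profile to ~1e-5 relative error.

The stimulus is a zero-mean sinusoid: 10 Hz in the alpha condition, 5 Hz in
theta, active for the middle 10 s of a 15-s trial (2.5 s pre, 2.5 s post in
the reference protocol). Amplitude maps to field magnitude linearly at
1 (mV/mm)/mA. The anodic half-cycle points from cortical layer 1 toward
layer 6 (pia at +z, so the anodic direction is -z); phase 0 deg is the
waveform peak, 180 deg the trough, and stimulation starts at 270 deg (the
rising zero crossing) so onset is continuous. A `freq = 0` mode applies a
constant anodic field, used for subthreshold polarization measurements.

### Reduced morphologies

The five cells stand in for morphologically detailed human cortical
models: a layer 1 neurogliaform cell (L1 NGC), layer 2/3, 5 and 6 pyramidal
cells (PC), and a layer 4 large basket cell (L4 LBC). Pyramidal cells get a
soma, an apical trunk running along the cortical-depth axis (450 um for
L2/3, 1000 um for L5, 750 um for L6, thick enough that the electrotonic
length stays near one space constant), oblique basal dendrites, and a short
axon initial segment. Interneurons get a compact, radially near-symmetric
dendritic tree. This reproduces the mechanistic asymmetry that drives the
study: somatic polarization per unit field is 0.16 / 0.32 / 0.23 mV per
mV/mm for the L2/3, L5 and L6 pyramidals versus ~0.005 mV per mV/mm for
both interneurons. During the anodic half-cycle the pyramidal soma
depolarizes (the apical tuft hyperpolarizes), which is why pyramidal
preferred phases settle on the rising/peak side of the waveform.

Cells are placed at laminar depths (L5 soma at the origin, pia side
positive) with small lateral offsets; geometry is exactly representable as
SWC and round-trips through `write_swc`/`read_swc`.

### Membrane mechanisms

Dendrites are passive (Cm = 1 uF/cm^2, Ra = 150 Ohm cm, Rm = 25 kOhm cm^2,
E_leak = -65 mV). The soma and axon initial segment carry:

* Wang-Buzsaki fast sodium and delayed-rectifier potassium kinetics
  (instantaneous m, ODEs for h and n, phi = 5), a standard type-I spike
  mechanism that supports the calibrated 5-30 Hz repetitive firing.
  Pyramidal cells use gNa = 0.12, gK = 0.03 S/cm^2 (the large dendritic
  load otherwise prevents spike initiation); interneurons use 0.08/0.02.
  The axon initial segment carries 3x the somatic density.
* A slow adaptation potassium conductance activating only at spike-level
  voltages (half-activation -20 mV, tau = 100 ms). It acts like an AHP
  current: each spike increments it slightly and it decays between spikes.
  This is what stabilizes slow regular firing under strong excitatory
  drive and prevents depolarization block; pyramidal cells and the
  slow-spiking neurogliaform cell adapt strongly (0.1 S/cm^2), the
  fast-spiking basket cell weakly (0.02 S/cm^2).

The detailed models this package reduces carry full ion-channel suites;
only spike timing relative to the field is the quantity under test here,
and the minimal mechanism set above is chosen for that purpose.

### Synapses and endogenous activity

All synapses are peak-normalized dual exponentials,
`g(t) = g_max * N * (exp(-t/tau2) - exp(-t/tau1))`, with `N` chosen so the
peak equals `g_max` (the unnormalized prefactor tau1*tau2/(tau1 - tau2) and
the bracket are both negative for tau1 < tau2; peak normalization makes the
sign convention explicit). Currents are ohmic, `I = g (V - E_syn)`.
Receptor classes: AMPA/NMDA-like (tau 2/10 ms, E = 0 mV — the same
kinetics parameterize the background drive), GABA_A-like (1/8 ms, -80 mV),
GABA_B-like (20/100 ms, -95 mV). No short-term plasticity or release
stochasticity: conductances superpose linearly.

Endogenous activity comes from independent homogeneous Poisson trains
(exponential inter-arrival sampling, 10-ms mean interval per contact)
delivered to basal-dendrite contacts: 48 contacts per cell, 96 for the
densely arborized neurogliaform cell. The per-contact weight is the single
calibration knob. Per-cell target rates are 5, 10, 30, 10, 10 Hz
(L1 NGC, L2/3 PC, L4 LBC, L5 PC, L6 PC) in the alpha condition and 5 Hz
for every cell in theta; calibration is monotone bisection on the weight
over the isolated (disconnected) cell, to +-0.25 Hz over a fixed seed set,
with automatic upper-bracket detection below the depolarization-block
regime. Connections are then added on top of the calibrated drive.

### Connectivity

Fourteen directed connections (three contacts each, 1-ms delay): pyramidal
cells excite each other and the interneurons; the basket cell inhibits
pyramidal cells through somatic GABA_A-like contacts; the neurogliaform
cell inhibits them through mixed GABA_A/GABA_B-like contacts. Interneurons
receive only excitation. Weights are calibration parameters bounded by the
reported connectivity effects: with connections the basket cell rate rises
by ~0.1 Hz and pyramidal rates shift by under 0.05 Hz. The excitation onto
the neurogliaform cell is kept small (5e-6 uS/contact) so that
network-transmitted spike-count noise stays near that cell's one-spike
quantization floor in short windows; its rate increase is then below
resolution at desk scale (the full-scale study resolves a ~0.26 Hz
increase). The default table does not claim to reproduce the original
microcircuit's 109 individual contacts; only the 14-connection topology is
pinned.

## Numerics

* Theta-method time stepping (theta = 0.5, Crank-Nicolson) on the
  Hines-ordered tree, dt = 0.025 ms. Gates advance by exponential Euler on
  a staggered grid; the instantaneous sodium activation is evaluated at a
  linearly extrapolated midpoint voltage; synaptic conductances are
  evaluated at the step midpoint via exact half-step decay factors; event
  injections are decay-corrected for their exact timestamp within a step.
  With all of this, halving dt moves the first spike of a deterministic
  protocol by < 0.05 ms and accumulated spike phase over 600 ms of regular
  firing by ~0.2 ms (the gate-coefficient freeze within a step remains
  first order through the voltage dependence of the time constants).
* Spikes are upward crossings of -10 mV at the soma with linear
  interpolation and a 3-ms lockout.
* Transmembrane currents are recorded per compartment at 1 ms (the LFP
  band of interest is <= 11 Hz); by charge conservation they equal the net
  axial current into each compartment and sum to zero per cell.
* All randomness flows through `numpy` `SeedSequence`s keyed by
  `(base_seed, condition, trial, cell, contact)`: a trial is a pure
  function of its keys, grids parallelize and resume without result
  changes, and a disconnected cell's spike train is bit-identical to the
  same cell simulated alone.
* The inner loop is compiled with numba; a 15-s five-cell trial runs in
  roughly 2 s on one CPU core.

## LFP and spectra

The electrode sits 20 um lateral of the L5 PC soma in a homogeneous medium
of conductivity 0.3 mS/mm. Each compartment contributes
`I_mem / (4 pi r sigma)` evaluated at its midpoint (the line-source kernel
at segment resolution); with I_mem in nA and r in mm the LFP is in uV, and
the nearest (L5) cell dominates. Band-pass filtering is a second-order
Butterworth applied forward-backward (zero phase, so spike-phase relations
are not lagged): 9-11 Hz for alpha, 4-6 Hz for theta. Power spectra use
Welch averaging with 2-s Hann windows and 50% overlap. Instantaneous LFP
phase for the stimulus-LFP coherence comes from the analytic signal
(Hilbert transform) of the band-passed trace.

## Entrainment metrics

All phases are degrees with 0 at the stimulus peak. For spikes inside the
active window:

* PLV = modulus of the mean unit phasor; preferred phase = circular mean;
  circular SD = sqrt(-2 ln R) in degrees; Rayleigh p from Z = n R^2 with
  the standard series approximation.
* PPC = mean cosine over all spike pairs, computed by direct pairwise
  summation; the identity PPC = (n PLV^2 - 1)/(n - 1) is used as a
  cross-check only and holds to 1e-12 in tests.
* Phases from the replicate trials of a condition are pooled by
  concatenation before computing a single PLV per cell and amplitude
  (equivalent to the count-weighted resultant combination).
* Network-level: pairwise zero-lag Pearson correlation of the filtered
  LFPs in six 2.5-s epochs (pre, four active, post; half-open windows), and
  stimulus-LFP phase coherence in sliding 2.5-s windows at 0.1-s steps.
* Wilcoxon signed-rank comparisons are two-sided, zeros dropped and
  mid-ranks for ties (Pratt handling available); no multiple-testing
  correction is applied, matching how the comparisons are reported.
* PLV-intensity regressions are ordinary least squares per cell over
  amplitudes >= 0.4 mA (below that, cells whose endogenous preferred phase
  disagrees with the stimulus can transiently desynchronize); phase
  convergence is also quantified by converting (theta, r) to Cartesian
  (r cos theta, r sin theta) and regressing each axis on amplitude.

## Synthetic generators

Three seeded generators give every analysis stage a known ground truth
without the simulator: von Mises phase samples (population PLV =
I1(kappa)/I0(kappa)), sinusoidally rate-modulated Poisson spike trains by
thinning (intensity `r (1 + m cos)`, population PLV = m/2, preferred phase
at the modulation peak), and narrow-band surrogate LFPs (cosine plus white
noise). They emulate the statistics the pipeline consumes — concentrated
circular samples, rate-modulated point processes, noisy narrow-band traces
— but none of the biophysics: passing metric tests on them validates the
analysis code, not the circuit model.

## Scaled-down study conditions

The reference protocol (15-s trials, amplitudes 0-2 mA in 0.1-mA steps,
20 replicates) is expensive; the shipped desk-scale grids preserve the
trial anatomy with fewer conditions: rate invariance uses 0 vs 2 mA with
5 replicates and a 6-s active window; the PLV-intensity regression uses
amplitudes 0.4-2.0 mA in 0.4-mA steps with 5 replicates and the full 10-s
active window; the theta spike-count check uses 20 full 15-s trials of a
single cell. `StimulusProtocol.paper_scale()` restores the full grid.

## Known limitations

* At 5 replicates the rate-invariance statistic sits near its resolution
  floor: the 5-Hz neurogliaform cell contributes ~150 spikes, so one spike
  is 0.67%, and chaotic trial divergence in the connected circuit moves
  1-2 spikes between paired conditions regardless of coupling strength.
  Values up to ~1.4% on unlucky seeds are sampling noise, not a rate
  effect; the full 20-replicate protocol resolves the <1% bound.
* Pyramidal PLVs reach ~0.2-0.5 at 1-2 mA, above the ~0.1-0.2 range
  typically reported for detailed-morphology models and in vivo recordings
  at these intensities: the reduced cells were given strong somatic
  polarization so that the dose-response regression is resolvable with
  5 replicates. Slopes and R^2 of the PLV-intensity relation, not absolute
  PLV, are the calibrated quantities.
* Reduced morphologies, minimal channel sets, no synaptic plasticity (so
  no after-effects), no axonal arbors, no inter-columnar connectivity, and
  a homogeneous isotropic volume conductor.
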