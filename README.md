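# tacsim

Desk-scale simulation of intensity-dependent tACS entrainment in a cortical
microcircuit, with the complete entrainment-analysis pipeline.

Transcranial alternating current stimulation (tACS) applies a weak
sinusoidal current to the scalp, inducing an intracranial electric field on
the order of 1 mV/mm per mA. Fields this small barely change firing rates;
what they do change is spike *timing*: spikes concentrate at particular
phases of the stimulus waveform (neural entrainment). `tacsim` is for
computational neuroscientists who want to study that effect mechanistically
at the microcircuit level without a heavyweight simulator stack: it couples
reduced multicompartment conductance-based neurons to a quasi-uniform
field, drives them with Poisson synaptic input, connects them into a
five-cell cortical column (three pyramidal cells, two interneurons, 14
synaptic connections), records line-source local field potentials, and
quantifies entrainment with the standard circular statistics.

## Model and metrics in brief

* **Field coupling.** The membrane potential obeys the cable equation with
  an extracellular forcing term: a uniform field **E**(t) sets
  `V_e = -E . x` at each compartment, and gradients of `V_e` along the tree
  drive axial currents. Pyramidal cells, with long apical trunks aligned to
  the cortical axis, polarize 30-60x more per unit field than the compact
  interneurons — the mechanistic core of the cell-type asymmetry in
  entrainment.
* **Stimulus.** `E(t) = A * cos(phase)`, 10 Hz (alpha) or 5 Hz (theta),
  amplitudes 0-2 mA at 1 (mV/mm)/mA, active for 10 s inside a 15-s trial.
  Phase 0 deg = waveform peak, 180 deg = trough.
* **Entrainment metrics.** For spike phases theta_k relative to the
  stimulus: the phase-locking value `PLV = |mean(exp(i theta_k))|`, the
  pairwise phase consistency
  `PPC = 2/(N(N-1)) * sum_{j<k} cos(theta_j - theta_k)` (the
  sample-size-unbiased counterpart of PLV^2), the circular mean (preferred
  phase), circular SD, and the Rayleigh test. Network-level: pairwise
  zero-lag LFP correlations per 2.5-s epoch and sliding-window
  stimulus-LFP phase coherence.

See `docs/methods.md` for the full model description, parameter tables and
numerical choices.

## Worked example

```python
from tacsim.circuit import CircuitSpec, assemble
from tacsim.protocol import StimulusProtocol, run_trial
from tacsim.metrics import aggregate_phases, summarize_phases

circuit = assemble(CircuitSpec(condition="alpha", connected=True))
proto = StimulusProtocol.desk_scale(10.0, base_seed=0,
                                    amplitudes=(1.0,), n_trials=5)
phases = []
for trial in range(proto.n_trials):
    rec = run_trial(circuit, proto, 1.0, trial)
    phases.append(rec.stim_spike_phases("L5_PC"))
s = summarize_phases(aggregate_phases(phases), cell="L5_PC",
                     amplitude_ma=1.0, band="alpha")
print(f"n={s.n_spikes} PLV={s.plv:.3f} phase={s.preferred_phase_deg:.0f} deg"
      f" rayleigh_p={s.rayleigh_p:.2e}")
```

Output:

```
n=298 PLV=0.423 phase=306 deg rayleigh_p=8.51e-24
```

Five seeded 8-s trials of the connected alpha circuit at 1 mA yield 298
L5-pyramidal spikes in the active windows; their stimulus phases
concentrate strongly (PLV 0.42, Rayleigh p ~ 1e-23) on the rising anodic
phase just before the waveform peak (306 deg) — the cell is entrained. At
0 mA the same analysis gives PLV near the finite-sample floor and a
non-significant Rayleigh test.

The same machinery is scriptable from a shell:

```bash
tacsim simulate --condition alpha --out runs/alpha --scale desk --seed 0
tacsim analyze --in runs/alpha --out results/alpha
tacsim simulate --condition alpha --out runs/ablate --disconnect --seed 0
```

`simulate` writes per-trial spike and LFP tables plus a manifest (resuming
is idempotent); `analyze` produces per-cell/amplitude entrainment tables,
polar-histogram data and epoch-wise LFP cross-correlations.

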