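"""Numba kernels for the compartmental network integrator.

One theta-method step (theta = 0.5: Crank-Nicolson; theta = 1: backward
Euler) of the cable equation on a tree of cylindrical compartments, with:

* axial coupling between compartment centres (Hines-ordered tree solve:
  parent index < child index, one elimination sweep + back-substitution);
* the extracellular field entering through per-compartment extracellular
  potentials ``V_e = e(t) * ve_coef`` (quasi-uniform approximation), which
  force the axial current terms;
* Wang-Buzsaki spike currents (instantaneous m, ODEs for h and n) on
  flagged compartments, conductances frozen within a step at the
  exponential-Euler-advanced gate values (semi-implicit, as in standard
  compartmental solvers);
* dual-exponential synapses integrated exactly between events via two
  decaying states a (rise) and b (decay), ``g = fac * (b - a)``, evaluated
  at the step midpoint for second-order accuracy;
* spike detection by upward somatic threshold crossing with linear
  interpolation and refractory lockout, and cross-cell event delivery
  through a circular pending-weight buffer.

Units: mV, ms, nA, uS, nF.  All arrays are flat across cells; each cell is
a contiguous block whose root (soma) has parent -1, so the single global
elimination sweep never mixes cells.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NAN = 1
STATUS_OVERFLOW = 2


@njit(cache=True)
def wb_gates(v):
    """Wang-Buzsaki gate targets at voltage v: (m_inf, h_inf, tau_h, n_inf, tau_n).

    tau values are for phi = 1; divide by phi outside.
    """
    x = v + 35.0
    if abs(x) < 1e-7:
        a_m = 1.0
    else:
        a_m = 0.1 * x / (1.0 - np.exp(-x / 10.0))
    b_m = 4.0 * np.exp(-(v + 60.0) / 18.0)
    m_inf = a_m / (a_m + b_m)

    a_h = 0.07 * np.exp(-(v + 58.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    h_inf = a_h / (a_h + b_h)
    tau_h = 1.0 / (a_h + b_h)

    y = v + 34.0
    if abs(y) < 1e-7:
        a_n = 0.1
    else:
        a_n = 0.01 * y / (1.0 - np.exp(-y / 10.0))
    b_n = 0.125 * np.exp(-(v + 44.0) / 80.0)
    n_inf = a_n / (a_n + b_n)
    tau_n = 1.0 / (a_n + b_n)
    return m_inf, h_inf, tau_h, n_inf, tau_n


@njit(cache=True)
def m_current_gate(v):
    """Slow adaptation-K activation target; tau is constant.

    Activates at spike-level voltages only (half-activation -20 mV), so the
    conductance builds up a little with each spike and decays between
    spikes, like an AHP current.  This spike-frequency adaptation stabilizes
    slow repetitive firing under sustained excitatory drive and prevents
    depolarization block.
    """
    return 1.0 / (1.0 + np.exp(-(v + 20.0) / 6.0))


@njit(cache=True)
def run(
    # topology / passive properties (per compartment)
    parent, ga, cap, gpas, epas, gna, gk, gm, tau_m_ms, ve_coef,
    ena, ek, phi,
    soma_comp,                       # per cell: somatic compartment index
    # synapses (per synapse)
    syn_comp, syn_e, syn_d1, syn_d2, syn_h1, syn_h2, syn_fac,
    # externally scheduled events, sorted by time
    ev_time, ev_syn, ev_w,
    # outgoing network contacts per cell (CSR layout)
    out_ptr, out_syn, out_w, out_delay_steps,
    pend,                            # (n_slots, n_syn) pending-weight buffer
    # state (updated in place)
    v, hh_h, hh_n, hh_p, syn_a, syn_b, last_spike,
    # stepping
    t0, dt, theta, n_steps, rec_every,
    # stimulus
    amp_field, freq_hz, onset_ms, offset_ms, onset_phase_rad,
    # spike detection
    v_thresh, refr_ms,
    spike_cell, spike_t,
):
    n_comp = v.size
    n_cells = soma_comp.size
    n_syn = syn_comp.size
    n_slots = pend.shape[0]
    max_spikes = spike_t.size
    n_rec = n_steps // rec_every if rec_every > 0 else 0
    imem_rec = np.zeros((n_rec, n_comp))
    vsoma_rec = np.zeros((n_rec, n_cells))

    diag = np.empty(n_comp)
    rhs = np.empty(n_comp)
    ve = np.empty(n_comp)
    v_prev = v.copy()
    v_old_save = v.copy()
    # per-compartment adaptation update factors (tau_m_ms is per comp)
    dmf = np.empty(n_comp)
    for j in range(n_comp):
        dmf[j] = 1.0 - np.exp(-dt / tau_m_ms[j])
    # decay rates 1/tau recovered from the per-step decay factors
    lam1 = np.empty(n_syn)
    lam2 = np.empty(n_syn)
    for s in range(n_syn):
        lam1[s] = -np.log(syn_d1[s]) / dt
        lam2[s] = -np.log(syn_d2[s]) / dt
    gd = np.empty(n_comp)
    b = np.empty(n_comp)
    mv = np.empty(n_comp)
    gsyn_on = np.zeros(n_comp)
    gesyn_on = np.zeros(n_comp)

    vs_old = np.empty(n_cells)
    for c in range(n_cells):
        vs_old[c] = v[soma_comp[c]]

    # advance the external-event pointer past anything at or before t0
    ev_i = 0
    n_ev = ev_time.size
    while ev_i < n_ev and ev_time[ev_i] <= t0:
        ev_i += 1

    n_spk = 0
    status = STATUS_OK
    two_pi_f = 2.0 * np.pi * freq_hz / 1000.0

    for step in range(n_steps):
        t_new = t0 + (step + 1) * dt
        cur_slot = step % n_slots

        # --- synapse states: inject events landing in this step; the
        # states then represent the step start and decay at the step end
        for s in range(n_syn):
            w = pend[cur_slot, s]
            if w != 0.0:
                syn_a[s] += w
                syn_b[s] += w
                pend[cur_slot, s] = 0.0
        # pre-scheduled (Poisson drive) events; the injected amount is
        # decay-corrected so the post-event trajectory is exact for an
        # event timestamp inside the step
        t_start = t_new - dt
        while ev_i < n_ev and ev_time[ev_i] <= t_new:
            s = ev_syn[ev_i]
            delta = ev_time[ev_i] - t_start
            if delta > 0.0:
                syn_a[s] += ev_w[ev_i] * np.exp(delta * lam1[s])
                syn_b[s] += ev_w[ev_i] * np.exp(delta * lam2[s])
            else:
                syn_a[s] += ev_w[ev_i]
                syn_b[s] += ev_w[ev_i]
            ev_i += 1

        # --- stimulus field value at the step midpoint (2nd order)
        t_mid = t_new - 0.5 * dt
        if amp_field != 0.0 and onset_ms <= t_mid <= offset_ms:
            if freq_hz == 0.0:
                e_t = amp_field
            else:
                e_t = amp_field * np.cos(
                    onset_phase_rad + two_pi_f * (t_mid - onset_ms)
                )
        else:
            e_t = 0.0

        # --- assemble the theta-method system:
        #     (C/dt + theta*M) v' = (C/dt)v - (1-theta)*(M v) + b
        # with M the conductance matrix (membrane diag + axial couplings)
        # and b the reversal-weighted sources plus the field forcing.
        for j in range(n_comp):
            ve[j] = e_t * ve_coef[j]
            gd[j] = gpas[j]
            b[j] = gpas[j] * epas[j]
            gsyn_on[j] = 0.0
            gesyn_on[j] = 0.0

        # spike channels: h/n/p advance by exponential Euler on a staggered
        # grid; the instantaneous m gate is evaluated at a linearly
        # extrapolated midpoint voltage for second-order accuracy
        for j in range(n_comp):
            if gna[j] > 0.0 or gk[j] > 0.0:
                _, h_inf, tau_h, n_inf, tau_n = wb_gates(v[j])
                hh_h[j] += (h_inf - hh_h[j]) * (1.0 - np.exp(-dt * phi / tau_h))
                hh_n[j] += (n_inf - hh_n[j]) * (1.0 - np.exp(-dt * phi / tau_n))
                v_mid = 1.5 * v[j] - 0.5 * v_prev[j]
                m_inf, _, _, _, _ = wb_gates(v_mid)
                g_na = gna[j] * m_inf * m_inf * m_inf * hh_h[j]
                g_k = gk[j] * hh_n[j] ** 4
                gd[j] += g_na + g_k
                b[j] += g_na * ena + g_k * ek
            if gm[j] > 0.0:
                hh_p[j] += (m_current_gate(v[j]) - hh_p[j]) * dmf[j]
                g_m = gm[j] * hh_p[j]
                gd[j] += g_m
                b[j] += g_m * ek

        # synaptic conductances at the step midpoint (exact half-decay)
        for s in range(n_syn):
            g = syn_fac[s] * (syn_b[s] * syn_h2[s] - syn_a[s] * syn_h1[s])
            if g != 0.0:
                j = syn_comp[s]
                gsyn_on[j] += g
                gesyn_on[j] += g * syn_e[s]
        for j in range(n_comp):
            gd[j] += gsyn_on[j]
            b[j] += gesyn_on[j]

        # axial couplings and extracellular-field forcing
        for j in range(n_comp):
            p = parent[j]
            if p >= 0:
                gd[j] += ga[j]
                gd[p] += ga[j]
                drive = ga[j] * (ve[p] - ve[j])
                b[j] += drive
                b[p] -= drive

        # rhs = (C/dt) v - (1-theta) (M v) + b ; M v uses the couplings
        for j in range(n_comp):
            v_old_save[j] = v[j]
            mv[j] = gd[j] * v[j]
        for j in range(n_comp):
            p = parent[j]
            if p >= 0:
                mv[j] -= ga[j] * v[p]
                mv[p] -= ga[j] * v[j]
        for j in range(n_comp):
            diag[j] = cap[j] / dt + theta * gd[j]
            rhs[j] = cap[j] / dt * v[j] - (1.0 - theta) * mv[j] + b[j]

        # --- Hines solve (parents precede children); couplings scaled by theta
        for j in range(n_comp - 1, -1, -1):
            p = parent[j]
            if p >= 0:
                gat = theta * ga[j]
                f = gat / diag[j]
                diag[p] -= f * gat
                rhs[p] += f * rhs[j]
        for j in range(n_comp):
            p = parent[j]
            if p < 0:
                v[j] = rhs[j] / diag[j]
            else:
                v[j] = (rhs[j] + theta * ga[j] * v[p]) / diag[j]

        # --- spike detection & event delivery
        for c in range(n_cells):
            vs = v[soma_comp[c]]
            if (
                vs >= v_thresh
                and vs_old[c] < v_thresh
                and (t_new - last_spike[c]) >= refr_ms
            ):
                frac = (v_thresh - vs_old[c]) / (vs - vs_old[c])
                t_sp = t_new - dt + dt * frac
                last_spike[c] = t_new
                if n_spk >= max_spikes:
                    status = STATUS_OVERFLOW
                else:
                    spike_cell[n_spk] = c
                    spike_t[n_spk] = t_sp
                    n_spk += 1
                for k in range(out_ptr[c], out_ptr[c + 1]):
                    slot = (cur_slot + out_delay_steps[k]) % n_slots
                    pend[slot, out_syn[k]] += out_w[k]
            vs_old[c] = vs

        for j in range(n_comp):
            v_prev[j] = v_old_save[j]

        # --- synapse states decay exactly over the step
        for s in range(n_syn):
            syn_a[s] *= syn_d1[s]
            syn_b[s] *= syn_d2[s]

        # --- recording at the declared cadence
        if rec_every > 0 and (step + 1) % rec_every == 0:
            r = (step + 1) // rec_every - 1
            for j in range(n_comp):
                imem_rec[r, j] = 0.0
            for j in range(n_comp):
                p = parent[j]
                if p >= 0:
                    i_ax = ga[j] * ((v[p] + ve[p]) - (v[j] + ve[j]))
                    imem_rec[r, j] += i_ax
                    imem_rec[r, p] -= i_ax
            for c in range(n_cells):
                vsoma_rec[r, c] = v[soma_comp[c]]
            # numerical health check at the recording cadence
            for c in range(n_cells):
                if not np.isfinite(vsoma_rec[r, c]):
                    status = STATUS_NAN
            if status != STATUS_OK and status != STATUS_OVERFLOW:
                return n_spk, imem_rec, vsoma_rec, status

    return n_spk, imem_rec, vsoma_rec, status
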