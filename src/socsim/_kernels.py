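"""Numba kernels for fixed-step RK4 integration of cell populations.

Design notes
------------
* Gate kinetics enter the kernels as dense lookup tables (steady state and
  time constant per gate, 0.025 mV grid, linear interpolation) built from
  the exact closed forms in :mod:`socsim.gating`.  This removes all
  transcendental calls from the hot loop.
* Synaptic conductances are linear filters driven by impulses, so they are
  propagated *exactly* between grid points with precomputed decay factors
  and treated as known time functions inside each RK4 step.  Presynaptic
  arrival times are snapped to the nearest grid point by the caller.
* All gate time constants are floored at TAU_FLOOR_MS: the MSO Na-activation
  time constant shrinks exponentially above ~0 mV and would destabilize an
  explicit method; the floor is dt-independent so dt-refinement studies
  compare the same dynamics.
* Spike detection (upward threshold crossing, linearly interpolated time,
  detection refractory window) runs inline; each cell's spike count is
  bounded by duration / refractory + 1.

State layout per cell: V followed by the gate variables (bushy: m h n p w z r;
MSO: m h w z r).  Gates are clamped to [0, 1] after every step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TAU_FLOOR_MS = 0.004

# indices into the bushy parameter vector
# [Cm, Erest, gl, gNa, gKHT, gKLT, gh, ENa, EK, Eh, Eex]
# indices into the MSO parameter vector
# [Cm, Erest, gl, gNa, gKLT, gh, ENa, EK, Eh, Eex, Ein]


@njit(cache=True, inline="always")
def _lerp(tab, row, v, v_min, inv_dv, n_pts):
    x = (v - v_min) * inv_dv
    if x <= 0.0:
        return tab[row, 0]
    if x >= n_pts - 1:
        return tab[row, n_pts - 1]
    i = int(x)
    f = x - i
    return tab[row, i] * (1.0 - f) + tab[row, i + 1] * f


@njit(cache=True, inline="always")
def _bushy_dv(v, g, p, g_exc, i_ext):
    # g: gates array [m,h,n,p,w,z,r]
    i_ion = (
        p[2] * (v - p[1])
        + p[3] * g[0] ** 3 * g[1] * (v - p[7])
        + p[4] * (0.85 * g[2] ** 2 + 0.15 * g[3]) * (v - p[8])
        + p[5] * g[4] ** 4 * g[5] * (v - p[8])
        + p[6] * g[6] * (v - p[9])
        + g_exc * (v - p[10])
    )
    return (-i_ion + i_ext) / p[0]


@njit(cache=True, inline="always")
def _mso_dv(v, g, p, g_exc, g_inh, i_ext):
    # g: gates array [m,h,w,z,r]
    i_ion = (
        p[2] * (v - p[1])
        + p[3] * g[0] ** 3 * g[1] * (v - p[6])
        + p[4] * g[2] ** 4 * g[3] * (v - p[7])
        + p[5] * g[4] * (v - p[8])
        + g_exc * (v - p[9])
        + g_inh * (v - p[10])
    )
    return (-i_ion + i_ext) / p[0]


@njit(cache=True)
def _run_bushy_pop(
    dt,
    n_steps,
    p,
    tab,
    v_min,
    inv_dv,
    exc_idx,
    exc_ptr,
    a_exc,
    tau_exc,
    i_ext_amp,
    i_ext_start,
    i_ext_end,
    v_init,
    gates_init,
    spike_thr,
    det_refrac,
    spike_times,
    spike_counts,
    max_spikes,
    record_state,
    v_rec,
    gates_rec,
):
    n_cells = len(exc_ptr) - 1
    n_pts = tab.shape[1]
    n_gates = 7
    dec_h = np.exp(-0.5 * dt / tau_exc)
    dec_f = dec_h * dec_h
    k1 = np.empty(n_gates + 1)
    k2 = np.empty(n_gates + 1)
    k3 = np.empty(n_gates + 1)
    k4 = np.empty(n_gates + 1)
    g1 = np.empty(n_gates)
    for c in range(n_cells):
        v = v_init
        gates = gates_init.copy()
        gsyn = 0.0
        ep = exc_ptr[c]
        ep_end = exc_ptr[c + 1]
        last_spike = -1.0e9
        nsp = 0
        if record_state and c == 0:
            v_rec[0] = v
            for j in range(n_gates):
                gates_rec[0, j] = gates[j]
        for step in range(n_steps):
            t = step * dt
            while ep < ep_end and exc_idx[ep] == step:
                gsyn += a_exc
                ep += 1
            g0 = gsyn
            gh_ = gsyn * dec_h
            gf_ = gsyn * dec_f
            ie0 = i_ext_amp if (i_ext_start <= t < i_ext_end) else 0.0
            th = t + 0.5 * dt
            ieh = i_ext_amp if (i_ext_start <= th < i_ext_end) else 0.0
            tf = t + dt
            ief = i_ext_amp if (i_ext_start <= tf < i_ext_end) else 0.0

            # stage 1
            k1[0] = _bushy_dv(v, gates, p, g0, ie0)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v, v_min, inv_dv, n_pts)
                k1[1 + j] = (inf - gates[j]) / tau
            # stage 2
            v2 = v + 0.5 * dt * k1[0]
            for j in range(n_gates):
                g1[j] = gates[j] + 0.5 * dt * k1[1 + j]
            k2[0] = _bushy_dv(v2, g1, p, gh_, ieh)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v2, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v2, v_min, inv_dv, n_pts)
                k2[1 + j] = (inf - g1[j]) / tau
            # stage 3
            v3 = v + 0.5 * dt * k2[0]
            for j in range(n_gates):
                g1[j] = gates[j] + 0.5 * dt * k2[1 + j]
            k3[0] = _bushy_dv(v3, g1, p, gh_, ieh)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v3, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v3, v_min, inv_dv, n_pts)
                k3[1 + j] = (inf - g1[j]) / tau
            # stage 4
            v4 = v + dt * k3[0]
            for j in range(n_gates):
                g1[j] = gates[j] + dt * k3[1 + j]
            k4[0] = _bushy_dv(v4, g1, p, gf_, ief)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v4, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v4, v_min, inv_dv, n_pts)
                k4[1 + j] = (inf - g1[j]) / tau

            v_new = v + dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
            for j in range(n_gates):
                x = gates[j] + dt / 6.0 * (
                    k1[1 + j] + 2.0 * k2[1 + j] + 2.0 * k3[1 + j] + k4[1 + j]
                )
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                gates[j] = x
            if not np.isfinite(v_new):
                return -(step + 1)  # blow-up marker; caller reports time
            if v < spike_thr <= v_new:
                t_cross = t + dt * (spike_thr - v) / (v_new - v)
                if t_cross - last_spike >= det_refrac:
                    if nsp < max_spikes:
                        spike_times[c * max_spikes + nsp] = t_cross
                        nsp += 1
                    last_spike = t_cross
            v = v_new
            gsyn = gf_
            if record_state and c == 0:
                v_rec[step + 1] = v
                for j in range(n_gates):
                    gates_rec[step + 1, j] = gates[j]
        spike_counts[c] = nsp
    return 0


@njit(cache=True)
def _run_mso_pop(
    dt,
    n_steps,
    p,
    tab,
    v_min,
    inv_dv,
    exc_idx,
    exc_ptr,
    a_exc,
    tau_exc,
    inh_idx,
    inh_ptr,
    a_inh,
    tau_inh_rise,
    tau_inh_decay,
    periodic_freq_hz,
    periodic_a,
    i_ext_amp,
    i_ext_start,
    i_ext_end,
    v_init,
    gates_init,
    spike_thr,
    det_refrac,
    spike_times,
    spike_counts,
    max_spikes,
    record_state,
    v_rec,
    gates_rec,
):
    n_cells = len(exc_ptr) - 1
    n_pts = tab.shape[1]
    n_gates = 5
    # alpha-function excitation: y1' = -y1/tau, y2' = (y1 - y2)/tau, g = y2
    e_h = np.exp(-0.5 * dt / tau_exc)
    e_f = e_h * e_h
    rh = 0.5 * dt / tau_exc
    rf = dt / tau_exc
    # double-exponential inhibition: two decays, g = slow - fast
    df_h = np.exp(-0.5 * dt / tau_inh_rise)
    df_f = df_h * df_h
    ds_h = np.exp(-0.5 * dt / tau_inh_decay)
    ds_f = ds_h * ds_h
    period_ms = 0.0
    if periodic_freq_hz > 0.0:
        period_ms = 1000.0 / periodic_freq_hz
    k1 = np.empty(n_gates + 1)
    k2 = np.empty(n_gates + 1)
    k3 = np.empty(n_gates + 1)
    k4 = np.empty(n_gates + 1)
    g1 = np.empty(n_gates)
    for c in range(n_cells):
        v = v_init
        gates = gates_init.copy()
        y1 = 0.0
        y2 = 0.0
        sf = 0.0
        ss = 0.0
        ep = exc_ptr[c]
        ep_end = exc_ptr[c + 1]
        ip = inh_ptr[c]
        ip_end = inh_ptr[c + 1]
        last_spike = -1.0e9
        nsp = 0
        if record_state and c == 0:
            v_rec[0] = v
            for j in range(n_gates):
                gates_rec[0, j] = gates[j]
        for step in range(n_steps):
            t = step * dt
            while ep < ep_end and exc_idx[ep] == step:
                y1 += a_exc
                ep += 1
            while ip < ip_end and inh_idx[ip] == step:
                sf += a_inh
                ss += a_inh
                ip += 1
            # synaptic conductance at the three stage times (event-driven part
            # propagated exactly; periodic closed-form drive added on top)
            gef_ev = (y2 + y1 * rf) * e_f
            ge0 = y2
            geh = (y2 + y1 * rh) * e_h
            gef = gef_ev
            gi0 = ss - sf
            gih = ss * ds_h - sf * df_h
            gif = ss * ds_f - sf * df_f
            if period_ms > 0.0:
                x0 = t - period_ms * np.floor(t / period_ms)
                ge0 += periodic_a * (x0 / tau_exc) * np.exp(-x0 / tau_exc)
                xh = (t + 0.5 * dt) - period_ms * np.floor((t + 0.5 * dt) / period_ms)
                geh += periodic_a * (xh / tau_exc) * np.exp(-xh / tau_exc)
                xf = (t + dt) - period_ms * np.floor((t + dt) / period_ms)
                gef += periodic_a * (xf / tau_exc) * np.exp(-xf / tau_exc)
            ie0 = i_ext_amp if (i_ext_start <= t < i_ext_end) else 0.0
            th = t + 0.5 * dt
            ieh = i_ext_amp if (i_ext_start <= th < i_ext_end) else 0.0
            tf = t + dt
            ief = i_ext_amp if (i_ext_start <= tf < i_ext_end) else 0.0

            k1[0] = _mso_dv(v, gates, p, ge0, gi0, ie0)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v, v_min, inv_dv, n_pts)
                k1[1 + j] = (inf - gates[j]) / tau
            v2 = v + 0.5 * dt * k1[0]
            for j in range(n_gates):
                g1[j] = gates[j] + 0.5 * dt * k1[1 + j]
            k2[0] = _mso_dv(v2, g1, p, geh, gih, ieh)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v2, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v2, v_min, inv_dv, n_pts)
                k2[1 + j] = (inf - g1[j]) / tau
            v3 = v + 0.5 * dt * k2[0]
            for j in range(n_gates):
                g1[j] = gates[j] + 0.5 * dt * k2[1 + j]
            k3[0] = _mso_dv(v3, g1, p, geh, gih, ieh)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v3, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v3, v_min, inv_dv, n_pts)
                k3[1 + j] = (inf - g1[j]) / tau
            v4 = v + dt * k3[0]
            for j in range(n_gates):
                g1[j] = gates[j] + dt * k3[1 + j]
            k4[0] = _mso_dv(v4, g1, p, gef, gif, ief)
            for j in range(n_gates):
                inf = _lerp(tab, 2 * j, v4, v_min, inv_dv, n_pts)
                tau = _lerp(tab, 2 * j + 1, v4, v_min, inv_dv, n_pts)
                k4[1 + j] = (inf - g1[j]) / tau

            v_new = v + dt / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
            for j in range(n_gates):
                x = gates[j] + dt / 6.0 * (
                    k1[1 + j] + 2.0 * k2[1 + j] + 2.0 * k3[1 + j] + k4[1 + j]
                )
                if x < 0.0:
                    x = 0.0
                elif x > 1.0:
                    x = 1.0
                gates[j] = x
            if not np.isfinite(v_new):
                return -(step + 1)
            if v < spike_thr <= v_new:
                t_cross = t + dt * (spike_thr - v) / (v_new - v)
                if t_cross - last_spike >= det_refrac:
                    if nsp < max_spikes:
                        spike_times[c * max_spikes + nsp] = t_cross
                        nsp += 1
                    last_spike = t_cross
            v = v_new
            y2 = gef_ev
            y1 *= e_f
            sf *= df_f
            ss *= ds_f
            if record_state and c == 0:
                v_rec[step + 1] = v
                for j in range(n_gates):
                    gates_rec[step + 1, j] = gates[j]
        spike_counts[c] = nsp
    return 0
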