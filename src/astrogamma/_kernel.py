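"""Fused numba integration core.

The whole coupled state (interneuron and pyramidal Hodgkin-Huxley variables,
glutamate, astrocytic Ca2+/IP3/z) is advanced by classical fixed-step RK4 in
one jitted loop.  The per-module reference implementations (hh, synapses,
drive, astrocyte) define the model; this kernel mirrors them exactly and is
cross-checked against them in the test suite.

State layout: a (12, n) float64 array with rows
    0 V_int   1 m_int  2 n_int  3 h_int
    4 V_pyr   5 m_pyr  6 n_pyr  7 h_pyr
    8 G (glutamate)
    9 Ca     10 IP3   11 z

Conventions baked in here (documented in the owning modules):
  * synaptic driving force sign (corrected (E - V) vs printed (V - E)),
  * astrocyte/glutamate rates rescaled by 1e-3 on the millisecond grid,
  * Poisson pulses held piecewise-constant within an RK4 step,
  * small negative/overshoot excursions of bounded states clipped after each
    step only within CLIP_TOL; larger violations abort with a status code.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Status codes returned by run_kernel
OK = 0
DIVERGED = 1
STATE_VIOLATION = 2
SPIKE_OVERFLOW = 3

CLIP_TOL = 1e-6
SING_EPS = 1e-6

# Modulation targets (mirror synapses.ModulationTarget)
MOD_NONE = 0
MOD_INHIBITORY = 1
MOD_EXCITATORY = 2


@njit(cache=True, fastmath=True, inline="always")
def _linexp(v, scale, k):
    # scale * v / (1 - exp(-v/k)) with the analytic limit at v = 0
    if abs(v) < SING_EPS:
        return scale * k
    return scale * v / (1.0 - np.exp(-v / k))


@njit(cache=True, fastmath=True, inline="always")
def _sigmoid(x):
    # IEEE-safe: exp overflow -> inf -> gate 0
    return 1.0 / (1.0 + np.exp(-x))


# Lookup-table sampling of the voltage-dependent nonlinearities
# (six gating rates, the presynaptic gate and the glutamate-release gate):
# columns 0..5 = alpha_m, beta_m, alpha_n, beta_n, alpha_h, beta_h,
# 6 = sigmoid(V/k_syn), 7 = sigmoid(V/0.5).  Linear interpolation on a
# 0.005-mV grid over [-150, 80] mV; the exact expressions are used instead
# when ``exact`` is set (oracle mode for the tests).
TAB_VMIN = -150.0
TAB_VMAX = 80.0
TAB_STEP = 0.005


def build_tables(k_syn: float = 0.2) -> np.ndarray:
    """Precompute the (n_grid, 8) interpolation table for one gate slope."""
    V = TAB_VMIN + TAB_STEP * np.arange(
        int(round((TAB_VMAX - TAB_VMIN) / TAB_STEP)) + 1
    )

    def linexp(v, scale, k):
        small = np.abs(v) < SING_EPS
        safe = np.where(small, 1.0, v)
        with np.errstate(over="ignore"):
            out = scale * safe / (1.0 - np.exp(-safe / k))
        return np.where(small, scale * k, out)

    with np.errstate(over="ignore"):
        tab = np.empty((V.size, 8))
        tab[:, 0] = linexp(V + 35.0, 0.182, 9.0)
        tab[:, 1] = linexp(-(V + 35.0), 0.124, 9.0)
        tab[:, 2] = linexp(V - 25.0, 0.02, 9.0)
        tab[:, 3] = linexp(-(V - 25.0), 0.002, 9.0)
        tab[:, 4] = 0.25 * np.exp(-(V + 90.0) / 12.0)
        tab[:, 5] = 0.25 * np.exp((V + 62.0) / 6.0 - (V + 90.0) / 12.0)
        tab[:, 6] = 1.0 / (1.0 + np.exp(-V / k_syn))
        tab[:, 7] = 1.0 / (1.0 + np.exp(-V / 0.5))
    # a presynaptic gate below 1e-30 is physically zero; storing exact zeros
    # lets the kernel skip silent cells when accumulating synaptic input
    tab[tab[:, 6] < 1e-30, 6] = 0.0
    return tab


@njit(cache=True, fastmath=True, inline="always")
def _tab8(tab, V):
    u = (V - TAB_VMIN) / TAB_STEP
    if u < 0.0:
        u = 0.0
    nmax = tab.shape[0] - 2
    if u > nmax:
        u = float(nmax)
    j = int(u)
    t = u - j
    r0 = tab[j]
    r1 = tab[j + 1]
    return (r0[0] + (r1[0] - r0[0]) * t,
            r0[1] + (r1[1] - r0[1]) * t,
            r0[2] + (r1[2] - r0[2]) * t,
            r0[3] + (r1[3] - r0[3]) * t,
            r0[4] + (r1[4] - r0[4]) * t,
            r0[5] + (r1[5] - r0[5]) * t,
            r0[6] + (r1[6] - r0[6]) * t,
            r0[7] + (r1[7] - r0[7]) * t)


@njit(cache=True, fastmath=True)
def _deriv(Y, dY, ip_amp, indptr, indices,
           g_syn, g_syn_P, k_syn, E_inh, E_exc, sign,
           C, gNa, gK, gL, ENa, EK, EL, Iapp,
           mod_target, g_astro, ca_thr, clamp,
           astro_on, ap, alphaG, betaG,
           tab, exact,
           accumulate, acc_iexc):
    n = Y.shape[1]

    # presynaptic gates; summed inhibitory input S[i] is accumulated by
    # scattering each active presynaptic gate along its outgoing edges
    gate_i = np.empty(n)
    gate_p = np.empty(n)
    S = np.zeros(n)
    for i in range(n):
        if exact:
            gate_i[i] = _sigmoid(Y[0, i] / k_syn)
            gate_p[i] = _sigmoid(Y[4, i] / k_syn)
        else:
            gate_i[i] = _tab8(tab, Y[0, i])[6]
            gate_p[i] = _tab8(tab, Y[4, i])[6]
    for j in range(n):
        g = gate_i[j]
        if g > 0.0:
            for kk in range(indptr[j], indptr[j + 1]):
                S[indices[kk]] += g

    # interneurons
    for i in range(n):
        V = Y[0, i]
        m = Y[1, i]
        nn = Y[2, i]
        h = Y[3, i]

        s = S[i]

        f_inh = 1.0
        f_exc = 1.0
        if astro_on and mod_target != MOD_NONE:
            ca = Y[9, i]
            if ca >= ca_thr:
                f = 1.0 + g_astro * ca
                if clamp and f < 0.0:
                    f = 0.0
                if mod_target == MOD_INHIBITORY:
                    f_inh = f
                else:
                    f_exc = f

        I_inh = g_syn * f_inh * s * sign * (E_inh - V)
        I_exc = g_syn_P * f_exc * gate_p[i] * sign * (E_exc - V)
        if accumulate:
            acc_iexc[i] += abs(I_exc)

        I_channel = (gNa * m * m * m * h * (ENa - V)
                     + gK * nn * (EK - V) + gL * (EL - V))
        dY[0, i] = (I_channel + Iapp + I_inh + I_exc) / C

        if exact:
            am = _linexp(V + 35.0, 0.182, 9.0)
            bm = _linexp(-(V + 35.0), 0.124, 9.0)
            an = _linexp(V - 25.0, 0.02, 9.0)
            bn = _linexp(-(V - 25.0), 0.002, 9.0)
            ah = 0.25 * np.exp(-(V + 90.0) / 12.0)
            bh = 0.25 * np.exp((V + 62.0) / 6.0 - (V + 90.0) / 12.0)
        else:
            am, bm, an, bn, ah, bh, _g1, _g2 = _tab8(tab, V)
        dY[1, i] = am * (1.0 - m) - bm * m
        dY[2, i] = an * (1.0 - nn) - bn * nn
        dY[3, i] = ah * (1.0 - h) - bh * h

    # pyramidal cells (drive-only layer: no synaptic input)
    for i in range(n):
        V = Y[4, i]
        m = Y[5, i]
        nn = Y[6, i]
        h = Y[7, i]
        I_channel = (gNa * m * m * m * h * (ENa - V)
                     + gK * nn * (EK - V) + gL * (EL - V))
        dY[4, i] = (I_channel + Iapp + ip_amp[i]) / C
        if exact:
            am = _linexp(V + 35.0, 0.182, 9.0)
            bm = _linexp(-(V + 35.0), 0.124, 9.0)
            an = _linexp(V - 25.0, 0.02, 9.0)
            bn = _linexp(-(V - 25.0), 0.002, 9.0)
            ah = 0.25 * np.exp(-(V + 90.0) / 12.0)
            bh = 0.25 * np.exp((V + 62.0) / 6.0 - (V + 90.0) / 12.0)
            glu_gate = _sigmoid(V / 0.5)
        else:
            am, bm, an, bn, ah, bh, _g1, glu_gate = _tab8(tab, V)
        dY[5, i] = am * (1.0 - m) - bm * m
        dY[6, i] = an * (1.0 - nn) - bn * nn
        dY[7, i] = ah * (1.0 - h) - bh * h

        # glutamate released by pyramidal cell i (rates s^-1 -> ms^-1)
        dY[8, i] = 1e-3 * (-alphaG * Y[8, i] + betaG * glu_gate)

    # astrocytes
    if astro_on:
        (c0, c1, v1, v2, v3, v4, v5, v6, k1, k2, k3, k4, a2,
         d1, d2, d3, d5, alpha, tau_ip3, ip3_star, d_ca, d_ip3,
         a_glu) = (ap[0], ap[1], ap[2], ap[3], ap[4], ap[5], ap[6],
                   ap[7], ap[8], ap[9], ap[10], ap[11], ap[12],
                   ap[13], ap[14], ap[15], ap[16], ap[17], ap[18],
                   ap[19], ap[20], ap[21], ap[22])
        for i in range(n):
            ca = Y[9, i]
            ip3 = Y[10, i]
            z = Y[11, i]
            il = i - 1 if i > 0 else n - 1
            ir = i + 1 if i < n - 1 else 0

            er_drive = c0 / c1 - (1.0 + 1.0 / c1) * ca
            q = ip3 * ca * z / ((ip3 + d1) * (ca + d5))
            J_ER = c1 * v1 * q * q * q * er_drive
            J_pump = v3 * ca * ca / (k3 * k3 + ca * ca)
            J_leak = c1 * v2 * er_drive
            J_in = v5 + v6 * ip3 * ip3 / (k2 * k2 + ip3 * ip3)
            J_out = k1 * ca
            J_cadiff = d_ca * (Y[9, il] + Y[9, ir] - 2.0 * ca)
            dY[9, i] = 1e-3 * (J_ER - J_pump + J_leak + J_in - J_out
                               + J_cadiff)

            J_plc = v4 * (ca + (1.0 - alpha) * k4) / (ca + k4)
            J_diff = d_ip3 * (Y[10, il] + Y[10, ir] - 2.0 * ip3)
            J_glu = a_glu * _sigmoid((Y[8, i] - 0.25) / 0.01)
            dY[10, i] = 1e-3 * ((ip3_star - ip3) / tau_ip3
                                + J_plc + J_diff + J_glu)

            dY[11, i] = 1e-3 * a2 * (d2 * (ip3 + d1) / (ip3 + d3)
                                     * (1.0 - z) - ca * z)
    else:
        for i in range(n):
            dY[9, i] = 0.0
            dY[10, i] = 0.0
            dY[11, i] = 0.0


@njit(cache=True, fastmath=True, inline="always")
def _clip_row(Y, row, lo, hi, tol):
    """Clip small integrator overshoots; return False on a large violation."""
    n = Y.shape[1]
    for i in range(n):
        x = Y[row, i]
        if x < lo:
            if x < lo - tol:
                return False
            Y[row, i] = lo
        elif x > hi:
            if x > hi + tol:
                return False
            Y[row, i] = hi
    return True


@njit(cache=True, fastmath=True)
def run_kernel(Y, dt, n_steps, discard_step,
               indptr, indices,
               ev_indptr, ev_onset, ev_amp, dur_steps,
               g_syn, g_syn_P, k_syn, E_inh, E_exc, sign,
               C, gNa, gK, gL, ENa, EK, EL, Iapp,
               mod_target, g_astro, ca_thr, clamp,
               astro_on, ap, alphaG, betaG,
               tab, exact,
               rec_every, rec_ca_full,
               spike_cap):
    """Integrate the full network in place and collect observables.

    Returns (status, fail_step, spike_t, spike_id, n_spikes, ca_mean,
    ca_full, ip3_full, z_full, acc_iexc, n_acc).  ``Y`` is modified in place and holds the
    final state.  ``acc_iexc`` accumulates |I_exc| per interneuron over all
    steps >= discard_step (evaluated at step start).
    """
    n = Y.shape[1]
    inf = np.float64(np.inf)

    spike_t = np.empty(spike_cap)
    spike_id = np.empty(spike_cap, dtype=np.int32)
    n_spikes = 0

    n_rec = n_steps // rec_every + 1
    ca_mean = np.zeros(n_rec)
    if rec_ca_full:
        ca_full = np.zeros((n_rec, n))
        ip3_full = np.zeros((n_rec, n))
        z_full = np.zeros((n_rec, n))
    else:
        ca_full = np.zeros((1, 1))
        ip3_full = np.zeros((1, 1))
        z_full = np.zeros((1, 1))

    acc_iexc = np.zeros(n)
    n_acc = 0

    ip_amp = np.zeros(n)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    for i in range(n):
        lo[i] = ev_indptr[i]
        hi[i] = ev_indptr[i]

    k1 = np.empty_like(Y)
    k2 = np.empty_like(Y)
    k3 = np.empty_like(Y)
    k4 = np.empty_like(Y)
    Yt = np.empty_like(Y)
    V_prev = np.empty(n)
    dummy = np.zeros(1)

    # record initial Ca
    if astro_on:
        s0 = 0.0
        for i in range(n):
            s0 += Y[9, i]
        ca_mean[0] = s0 / n
        if rec_ca_full:
            for i in range(n):
                ca_full[0, i] = Y[9, i]
                ip3_full[0, i] = Y[10, i]
                z_full[0, i] = Y[11, i]
    rec_idx = 1

    for step in range(n_steps):
        # drive currents, piecewise-constant over the step
        for i in range(n):
            end = ev_indptr[i + 1]
            while hi[i] < end and ev_onset[hi[i]] <= step:
                hi[i] += 1
            while lo[i] < hi[i] and ev_onset[lo[i]] + dur_steps <= step:
                lo[i] += 1
            a = 0.0
            for kk in range(lo[i], hi[i]):
                a += ev_amp[kk]
            ip_amp[i] = a

        for i in range(n):
            V_prev[i] = Y[0, i]

        acc = step >= discard_step
        if acc:
            n_acc += 1

        _deriv(Y, k1, ip_amp, indptr, indices,
               g_syn, g_syn_P, k_syn, E_inh, E_exc, sign,
               C, gNa, gK, gL, ENa, EK, EL, Iapp,
               mod_target, g_astro, ca_thr, clamp,
               astro_on, ap, alphaG, betaG, tab, exact, acc, acc_iexc)
        for r in range(12):
            for i in range(n):
                Yt[r, i] = Y[r, i] + 0.5 * dt * k1[r, i]
        _deriv(Yt, k2, ip_amp, indptr, indices,
               g_syn, g_syn_P, k_syn, E_inh, E_exc, sign,
               C, gNa, gK, gL, ENa, EK, EL, Iapp,
               mod_target, g_astro, ca_thr, clamp,
               astro_on, ap, alphaG, betaG, tab, exact, False, dummy)
        for r in range(12):
            for i in range(n):
                Yt[r, i] = Y[r, i] + 0.5 * dt * k2[r, i]
        _deriv(Yt, k3, ip_amp, indptr, indices,
               g_syn, g_syn_P, k_syn, E_inh, E_exc, sign,
               C, gNa, gK, gL, ENa, EK, EL, Iapp,
               mod_target, g_astro, ca_thr, clamp,
               astro_on, ap, alphaG, betaG, tab, exact, False, dummy)
        for r in range(12):
            for i in range(n):
                Yt[r, i] = Y[r, i] + dt * k3[r, i]
        _deriv(Yt, k4, ip_amp, indptr, indices,
               g_syn, g_syn_P, k_syn, E_inh, E_exc, sign,
               C, gNa, gK, gL, ENa, EK, EL, Iapp,
               mod_target, g_astro, ca_thr, clamp,
               astro_on, ap, alphaG, betaG, tab, exact, False, dummy)
        c = dt / 6.0
        for r in range(12):
            for i in range(n):
                Y[r, i] = Y[r, i] + c * (k1[r, i] + 2.0 * k2[r, i]
                                         + 2.0 * k3[r, i] + k4[r, i])

        # bounded-state guards
        ok = True
        for r in (1, 2, 3, 5, 6, 7, 11):
            ok = ok and _clip_row(Y, r, 0.0, 1.0, CLIP_TOL)
        for r in (8, 9, 10):
            ok = ok and _clip_row(Y, r, 0.0, inf, CLIP_TOL)
        if not ok:
            return (STATE_VIOLATION, step, spike_t, spike_id, n_spikes,
                    ca_mean, ca_full, ip3_full, z_full, acc_iexc, n_acc)

        # spike detection: upward crossing of 0 mV
        t_now = (step + 1) * dt
        for i in range(n):
            if V_prev[i] < 0.0 and Y[0, i] >= 0.0:
                if n_spikes >= spike_cap:
                    return (SPIKE_OVERFLOW, step, spike_t, spike_id,
                            n_spikes, ca_mean, ca_full, ip3_full, z_full, acc_iexc, n_acc)
                spike_t[n_spikes] = t_now
                spike_id[n_spikes] = i
                n_spikes += 1

        # divergence check
        if step % 200 == 199:
            for i in range(n):
                if not (np.isfinite(Y[0, i]) and np.isfinite(Y[4, i])):
                    return (DIVERGED, step, spike_t, spike_id, n_spikes,
                            ca_mean, ca_full, ip3_full, z_full, acc_iexc, n_acc)
                if abs(Y[0, i]) > 1000.0 or abs(Y[4, i]) > 1000.0:
                    return (DIVERGED, step, spike_t, spike_id, n_spikes,
                            ca_mean, ca_full, ip3_full, z_full, acc_iexc, n_acc)

        # recording
        if (step + 1) % rec_every == 0 and rec_idx < n_rec:
            if astro_on:
                s0 = 0.0
                for i in range(n):
                    s0 += Y[9, i]
                ca_mean[rec_idx] = s0 / n
                if rec_ca_full:
                    for i in range(n):
                        ca_full[rec_idx, i] = Y[9, i]
                        ip3_full[rec_idx, i] = Y[10, i]
                        z_full[rec_idx, i] = Y[11, i]
            rec_idx += 1

    return (OK, -1, spike_t, spike_id, n_spikes, ca_mean, ca_full,
            ip3_full, z_full, acc_iexc, n_acc)
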