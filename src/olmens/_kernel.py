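"""Batched compartmental integration kernel (numba).

One kernel call integrates a batch of models that share a discretized
morphology and passive properties but differ in per-compartment maximal
conductances, bias currents, and step amplitudes.

Scheme: Crank-Nicolson (theta = 1/2) on the membrane/cable terms with the
tree system solved exactly by Hines elimination (parent index < child
index), and staggered gating-variable updates via the exponential
(analytic first-order) update x <- x_inf + (x - x_inf) exp(-dt/tau).
Voltage-dependent x_inf and exp(-dt/tau) are linearly interpolated from
tables precomputed on a uniform voltage grid.

Units: V mV, t ms, conductance uS, capacitance nF, current nA, Ca mM.
"""

import numpy as np
from numba import njit

V_GUARD = 200.0  # |V| beyond this marks numerical divergence


@njit(cache=True)
def _lerp(tab, g, x, nt):
    if x < 0.0:
        x = 0.0
    elif x > nt - 1.001:
        x = nt - 1.001
    ix = int(x)
    w = x - ix
    return tab[g, ix] * (1.0 - w) + tab[g, ix + 1] * w


@njit(cache=True)
def integrate_batch(
    V, gates, ca,                 # state: (B,n), (B,G,n), (B,n) — updated
    parent, a_par, total_ax,      # (n,) topology/axial uS
    c_dt,                         # (n,) C_i/dt, nF/ms
    gl, gkl, el, ek,              # leak arrays (n,), reversals
    gbar,                         # (B,C,n) uS
    erev,                         # (C,)
    is_ca_chan,                   # (C,) uint8
    chan_ptr,                     # (C+1,) gate index ranges per channel
    gate_exp,                     # (G,)
    gate_is_ca, gate_kd2, gate_qca,   # (G,)
    inf_tab, q_tab, vmin, dv_inv,     # tables (G,NT)
    area,                         # (n,) cm^2
    ca_phi, ca_tau, ca_rest,      # calcium pool scalars
    bias,                         # (B,) nA at soma (comp 0), whole run
    step_amp, step_comp,          # (B,) nA, (B,) comp index
    i_on, i_off,                  # step window in integration steps
    clamp_g, clamp_v,             # soma voltage clamp (uS, mV); g<=0 = off
    dt, n_steps, stride,
    rec_sites,                    # (S,)
    out,                          # (B,S,K) preallocated
    out_iclamp,                   # (B,K) clamp current nA (if clamp on)
    status,                       # (B,) uint8: 0 ok, 1 diverged
):
    B, n = V.shape
    C = gbar.shape[1]
    nt = inf_tab.shape[1]
    S = rec_sites.shape[0]
    theta = 0.5

    gtot = np.empty(n)
    ge = np.empty(n)
    flux = np.empty(n)
    d = np.empty(n)
    rhs = np.empty(n)

    for b in range(B):
        if status[b] != 0:
            continue
        k_out = 0
        for step in range(n_steps):
            if step % stride == 0:
                for s in range(S):
                    out[b, s, k_out] = V[b, rec_sites[s]]
                if clamp_g > 0.0:
                    out_iclamp[b, k_out] = clamp_g * (clamp_v - V[b, 0])
                k_out += 1
            step_on = (step >= i_on) and (step < i_off)

            # membrane conductances + gate updates (staggered)
            for i in range(n):
                v = V[b, i]
                x = (v - vmin) * dv_inv
                g_t = gl[i] + gkl[i]
                g_e = gl[i] * el + gkl[i] * ek
                i_ca = 0.0
                for c in range(C):
                    gb = gbar[b, c, i]
                    if gb > 0.0:
                        gp = 1.0
                        for g in range(chan_ptr[c], chan_ptr[c + 1]):
                            if gate_is_ca[g] != 0:
                                cai = ca[b, i]
                                xinf = cai * cai / (cai * cai + gate_kd2[g])
                                q = gate_qca[g]
                            else:
                                xinf = _lerp(inf_tab, g, x, nt)
                                q = _lerp(q_tab, g, x, nt)
                            xs = xinf + (gates[b, g, i] - xinf) * q
                            gates[b, g, i] = xs
                            for _ in range(gate_exp[g]):
                                gp *= xs
                        gch = gb * gp
                        g_t += gch
                        g_e += gch * erev[c]
                        if is_ca_chan[c] != 0:
                            i_ca += gch * (v - erev[c])
                gtot[i] = g_t
                ge[i] = g_e
                # calcium pool (explicit; tau >> dt)
                if area[i] > 0.0:
                    ica_dens = i_ca * 1e-6 / area[i]  # mA/cm^2
                    dca = (-ca_phi * ica_dens
                           - (ca[b, i] - ca_rest) / ca_tau)
                    ca[b, i] = ca[b, i] + dca * dt
                    if ca[b, i] < 0.0:
                        ca[b, i] = 0.0

            if clamp_g > 0.0:
                gtot[0] += clamp_g
                ge[0] += clamp_g * clamp_v

            # axial flux at time t
            for i in range(n):
                flux[i] = 0.0
            for i in range(1, n):
                p = parent[i]
                f = a_par[i] * (V[b, i] - V[b, p])
                flux[i] += f
                flux[p] -= f

            for i in range(n):
                d[i] = c_dt[i] + theta * (gtot[i] + total_ax[i])
                r = (c_dt[i] * V[b, i]
                     - (1.0 - theta) * (gtot[i] * V[b, i] - ge[i] + flux[i])
                     + theta * ge[i])
                rhs[i] = r
            rhs[0] += bias[b]
            if step_on:
                rhs[step_comp[b]] += step_amp[b]

            # Hines elimination (parents precede children)
            for i in range(n - 1, 0, -1):
                p = parent[i]
                o = -theta * a_par[i]
                f = o / d[i]
                d[p] -= f * o
                rhs[p] -= f * rhs[i]
            V[b, 0] = rhs[0] / d[0]
            for i in range(1, n):
                o = -theta * a_par[i]
                V[b, i] = (rhs[i] - o * V[b, parent[i]]) / d[i]

            if abs(V[b, 0]) > V_GUARD:
                status[b] = 1
                break
            if n > 1 and step % 40 == 0:
                bad = False
                for i in range(n):
                    if abs(V[b, i]) > V_GUARD:
                        bad = True
                if bad:
                    status[b] = 1
                    break
        if status[b] == 0 and k_out < out.shape[2]:
            for s in range(S):
                out[b, s, k_out] = V[b, rec_sites[s]]
            if clamp_g > 0.0:
                out_iclamp[b, k_out] = clamp_g * (clamp_v - V[b, 0])
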