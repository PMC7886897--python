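"""Numba inner loop of the compartmental solver.

Everything the kernel touches is a flat numpy array prepared by
:mod:`stellate.solver`.  The integration scheme is the theta method on
the tree-structured cable equation (theta=1 backward Euler, theta=0.5
Crank-Nicolson) with channel gates advanced by exact exponential
integration against their (steady state, tau) and calcium pools by exact
exponential relaxation.  The linear system is solved directly on the
tree (Hines elimination), so cost is linear in compartment count.

Synaptic release follows the Tsodyks-Markram recursion applied at event
times; receptor conductances are single-exponential (AMPA/GABA-A) or
rise/decay two-state (NMDA, with sigmoidal Mg block evaluated at the
lagged voltage).
"""

import numpy as np
from numba import njit

# gate kinds (mirrors stellate.channels)
KIND_VOLTAGE = 0
KIND_CA_HILL = 1
KIND_BK = 2

E_CA = 137.5  # mV, fixed Ca reversal (ohmic driving force)
SPIKE_THRESHOLD = -20.0  # mV, upward-crossing detector
SPIKE_REFRACTORY = 1.0  # ms

MAX_PENDING = 64


@njit(cache=True, fastmath=True, error_model="numpy")
def _gate_inf_tau(kind, vh, k, tmin, tamp, vt, s1, s2, kd, hilln, v, ca):
    if kind == KIND_CA_HILL:
        can = ca**hilln
        inf = can / (can + kd**hilln)
        return inf, tmin
    vhe = vh
    if kind == KIND_BK:
        c = ca
        if c < 1e-9:
            c = 1e-9
        vhe = vh - kd * np.log10(c / hilln)
    inf = 1.0 / (1.0 + np.exp((vhe - v) / k))
    if tamp == 0.0:
        return inf, tmin
    x = v - vt
    tau = tmin + tamp / (np.exp(x / s1) + np.exp(-x / s2))
    return inf, tau


@njit(cache=True, fastmath=True, error_model="numpy")
def _tm_release(s, te, tlast, u, r, syn_p, syn_tr, syn_tf):
    dt_ev = te - tlast[s]
    if dt_ev < 0.0:
        dt_ev = 0.0
    if syn_tf[s] > 0.0:
        uu = u[s] * np.exp(-dt_ev / syn_tf[s])
    else:
        uu = 0.0
    if syn_tr[s] > 0.0:
        rr = 1.0 - (1.0 - r[s]) * np.exp(-dt_ev / syn_tr[s])
    else:
        rr = 1.0
    uu = uu + syn_p[s] * (1.0 - uu)
    rel = uu * rr
    r[s] = rr - rel
    u[s] = uu
    tlast[s] = te
    return rel


@njit(cache=True, fastmath=True, error_model="numpy")
def run_kernel(
    # topology / passive
    parent,  # i8[n], parent[i] < i, -1 for root
    c_nf,  # f8[n] capacitance, nF
    gax,  # f8[n] coupling conductance to parent, uS
    gax_sum,  # f8[n] total axial conductance touching i (static)
    v,  # f8[n] voltage state, modified in place
    # channel instances
    inst_comp,
    inst_g,  # uS
    inst_e,  # mV
    inst_isca,  # u1
    inst_g0,
    inst_ng,
    # gates
    gp,  # f8[G, 11]: kind vh k tmin tamp vt s1 s2 kd hilln exponent
    gate_comp,
    gates,  # f8[G] state, modified in place
    # calcium
    ca,  # f8[n] state
    ca_rest,
    ca_tau,
    ca_coef,  # mM/ms per nA (0 -> static pool)
    # synapses
    syn_comp,
    syn_kind,  # 0 single-exp, 1 two-exp NMDA
    syn_g,  # uS
    syn_e,
    syn_taur,
    syn_taud,
    syn_norm,
    syn_mg,  # premultiplied [Mg]/scale
    syn_vsens,
    syn_sat,
    syn_p,
    syn_tr,
    syn_tf,
    ev_t,  # f8[E] stimulus event times, grouped by synapse
    ev_off,  # i8[S+1]
    # network
    src_comp,  # i8[K] spike-source compartments
    con_src,  # i8[C] index into src
    con_syn,  # i8[C] synapse driven by this connection
    con_delay,  # f8[C] ms
    # stimuli
    stim_comp,
    stim_t0,
    stim_t1,
    stim_amp,  # nA
    # clamp
    clamp_comp,  # int, -1 = none
    clamp_v,
    clamp_v2,  # command after clamp_switch_step (ignored if < 0 steps)
    clamp_switch_step,
    # control
    dt,
    n_steps,
    theta,
    # recording
    rec_v_idx,
    rec_ca_idx,
    rec_stride,
    v_out,  # f8[nrec, len(rec_v_idx)]
    ca_out,
    ic_out,  # f8[nrec] clamp current, nA
    spk_t,  # f8[K, max_spikes]
    spk_n,  # i8[K] spike counts per source, modified in place
):
    n = parent.shape[0]
    n_inst = inst_comp.shape[0]
    n_gates = gp.shape[0]
    n_syn = syn_comp.shape[0]
    n_con = con_src.shape[0]
    n_stim = stim_comp.shape[0]
    n_src = src_comp.shape[0]
    max_spk = spk_t.shape[1] if n_src > 0 else 0

    r_state = np.ones(n_syn)
    u_state = np.zeros(n_syn)
    tlast = np.full(n_syn, -1e18)
    a_state = np.zeros(n_syn)
    b_state = np.zeros(n_syn)
    evp = np.empty(n_syn, dtype=np.int64)
    for s in range(n_syn):
        evp[s] = ev_off[s]
    pend_t = np.zeros((max(n_syn, 1), MAX_PENDING))
    pend_n = np.zeros(max(n_syn, 1), dtype=np.int64)
    last_spike = np.full(max(n_src, 1), -1e18)
    v_prev_src = np.empty(max(n_src, 1))
    for k in range(n_src):
        v_prev_src[k] = v[src_comp[k]]

    gion = np.empty(n)
    bion = np.empty(n)
    ica = np.empty(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    ax_flux = np.empty(n)

    if clamp_comp >= 0:
        v[clamp_comp] = clamp_v

    rec_i = 0
    for step in range(n_steps):
        t = step * dt
        tn = t + dt

        # --- synaptic events due in (t, t+dt]
        for s in range(n_syn):
            while evp[s] < ev_off[s + 1] and ev_t[evp[s]] <= t:
                te = ev_t[evp[s]]
                evp[s] += 1
                rel = _tm_release(s, te, tlast, u_state, r_state, syn_p, syn_tr, syn_tf)
                if syn_sat[s] == 1:
                    w = (b_state[s] - a_state[s]) * syn_norm[s]
                    if w < 0.0:
                        w = 0.0
                    elif w > 1.0:
                        w = 1.0
                    rel = rel * (1.0 - w)
                b_state[s] += rel
                if syn_kind[s] == 1:
                    a_state[s] += rel
            k = 0
            while k < pend_n[s]:
                if pend_t[s, k] <= t:
                    te = pend_t[s, k]
                    pend_n[s] -= 1
                    pend_t[s, k] = pend_t[s, pend_n[s]]
                    rel = _tm_release(
                        s, te, tlast, u_state, r_state, syn_p, syn_tr, syn_tf
                    )
                    if syn_sat[s] == 1:
                        w = (b_state[s] - a_state[s]) * syn_norm[s]
                        if w < 0.0:
                            w = 0.0
                        elif w > 1.0:
                            w = 1.0
                        rel = rel * (1.0 - w)
                    b_state[s] += rel
                    if syn_kind[s] == 1:
                        a_state[s] += rel
                else:
                    k += 1

        # --- gates: exact exponential update at current V, Ca
        for g in range(n_gates):
            c = gate_comp[g]
            inf, tau = _gate_inf_tau(
                int(gp[g, 0]),
                gp[g, 1],
                gp[g, 2],
                gp[g, 3],
                gp[g, 4],
                gp[g, 5],
                gp[g, 6],
                gp[g, 7],
                gp[g, 8],
                gp[g, 9],
                v[c],
                ca[c],
            )
            gates[g] += (inf - gates[g]) * (1.0 - np.exp(-dt / tau))

        # --- channel conductances
        for i in range(n):
            gion[i] = 0.0
            bion[i] = 0.0
            ica[i] = 0.0
        for m in range(n_inst):
            c = inst_comp[m]
            popen = 1.0
            for gi in range(inst_ng[m]):
                g = inst_g0[m] + gi
                x = gates[g]
                e = int(gp[g, 10])
                for _ in range(e):
                    popen *= x
            gg = inst_g[m] * popen
            gion[c] += gg
            bion[c] += gg * inst_e[m]
            if inst_isca[m] == 1:
                ica[c] += gg * (v[c] - E_CA)

        # --- synaptic conductances (decay, then contribute)
        for s in range(n_syn):
            c = syn_comp[s]
            if syn_kind[s] == 0:
                b_state[s] *= np.exp(-dt / syn_taud[s])
                gs = syn_g[s] * b_state[s]
            else:
                a_state[s] *= np.exp(-dt / syn_taur[s])
                b_state[s] *= np.exp(-dt / syn_taud[s])
                w = (b_state[s] - a_state[s]) * syn_norm[s]
                mgf = 1.0 / (1.0 + syn_mg[s] * np.exp(-syn_vsens[s] * v[c]))
                gs = syn_g[s] * w * mgf
            gion[c] += gs
            bion[c] += gs * syn_e[s]

        # --- injected currents
        for q in range(n_stim):
            if stim_t0[q] <= t < stim_t1[q]:
                bion[stim_comp[q]] += stim_amp[q]

        # --- assemble theta-method system on the tree
        for i in range(n):
            ax_flux[i] = 0.0
        for i in range(n):
            p = parent[i]
            if p >= 0:
                f = gax[i] * (v[i] - v[p])
                ax_flux[i] += f
                ax_flux[p] -= f
        for i in range(n):
            diag[i] = c_nf[i] / dt + theta * (gion[i] + gax_sum[i])
            rhs[i] = (
                c_nf[i] / dt * v[i]
                + bion[i]
                - (1.0 - theta) * (gion[i] * v[i] + ax_flux[i])
            )
        if clamp_comp >= 0:
            v_cmd = clamp_v
            if clamp_switch_step >= 0 and step >= clamp_switch_step:
                v_cmd = clamp_v2
            diag[clamp_comp] += 1e12
            rhs[clamp_comp] += 1e12 * v_cmd

        # Hines elimination (children have larger indices than parents)
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = theta * gax[i]
            diag[p] -= f * f / diag[i]
            rhs[p] += f * rhs[i] / diag[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + theta * gax[i] * v[parent[i]]) / diag[i]

        # --- clamp current (membrane + axial at the pinned node)
        i_clamp = 0.0
        if clamp_comp >= 0:
            cc = clamp_comp
            i_clamp = gion[cc] * v[cc] - bion[cc]
            p = parent[cc]
            if p >= 0:
                i_clamp += gax[cc] * (v[cc] - v[p])
            for j in range(n):
                if parent[j] == cc:
                    i_clamp += gax[j] * (v[cc] - v[j])

        # --- calcium pools (exact relaxation toward influx fixed point)
        for i in range(n):
            if ca_coef[i] > 0.0:
                j_in = -ica[i] * ca_coef[i]
                if j_in < 0.0:
                    j_in = 0.0
                target = ca_rest[i] + j_in * ca_tau[i]
                ca[i] = target + (ca[i] - target) * np.exp(-dt / ca_tau[i])
                if ca[i] < 0.0:
                    ca[i] = 0.0

        # --- spike detection and network propagation
        for ksrc in range(n_src):
            c = src_comp[ksrc]
            if (
                v_prev_src[ksrc] < SPIKE_THRESHOLD
                and v[c] >= SPIKE_THRESHOLD
                and tn - last_spike[ksrc] >= SPIKE_REFRACTORY
            ):
                last_spike[ksrc] = tn
                if spk_n[ksrc] < max_spk:
                    spk_t[ksrc, spk_n[ksrc]] = tn
                    spk_n[ksrc] += 1
                for cidx in range(n_con):
                    if con_src[cidx] == ksrc:
                        s = con_syn[cidx]
                        if pend_n[s] < MAX_PENDING:
                            pend_t[s, pend_n[s]] = tn + con_delay[cidx]
                            pend_n[s] += 1
            v_prev_src[ksrc] = v[c]

        # --- recording
        if step % rec_stride == 0:
            for k in range(rec_v_idx.shape[0]):
                v_out[rec_i, k] = v[rec_v_idx[k]]
            for k in range(rec_ca_idx.shape[0]):
                ca_out[rec_i, k] = ca[rec_ca_idx[k]]
            if ic_out.shape[0] > 0:
                ic_out[rec_i] = i_clamp
            rec_i += 1

        if step % 2000 == 0:
            for i in range(n):
                if not np.isfinite(v[i]):
                    return step
    return -1
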