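"""Implicit (backward Euler) integration kernel for the branched cable.

Units inside the kernel: mV, ms, uS, nA, nF (so C/dt carries uS and
conductance*voltage carries nA).  The tree is solved exactly per step by
parent-ordered Gaussian elimination (Hines ordering: parent index < child
index), one O(N) sweep per step.  Gating variables use an
exponential-Euler update evaluated at the previous-step voltage; synaptic
double-exponential conductances and the Ornstein-Uhlenbeck background use
exact per-step analytic updates.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _trap(x, y):
    # x / (1 - exp(-x/y)) with its x->0 limit
    if abs(x) < 1e-6 * y:
        return y + 0.5 * x
    return x / (1.0 - np.exp(-x / y))


@njit(cache=True)
def _na_m_rates(v):
    am = 0.1 * _trap(v + 35.0, 10.0)
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    return am, bm


@njit(cache=True)
def _na_h_rates(v):
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    return ah, bh


@njit(cache=True)
def _k_rates(v):
    an = 0.01 * _trap(v + 34.0, 10.0)
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return an, bn


@njit(cache=True)
def simulate_kernel(
        parent, gax, cdt, gpas, epas,
        gna, gk, gh,
        ena, ek, eh, vshift_na, vshift_h, vshift_k, phi, phi_m, ih_vh, ih_k, ih_tau,
        syn_comp, syn_g, syn_e, syn_fr, syn_fd,
        on_step, on_syn,
        clamp_idx, g_clamp, vcmd,
        inj_idx, inj_na,
        iinj_static,
        noise_idx, ge_m, gi_m, fe, fi, se, si, e_e, e_i, xi,
        v0, dt, nsteps, rec_idx):
    n = parent.shape[0]
    nsyn = syn_comp.shape[0]
    nrec = rec_idx.shape[0]

    V = v0.copy()
    m = np.zeros(n)
    h = np.zeros(n)
    ng = np.zeros(n)
    q = np.zeros(n)
    for i in range(n):
        am, bm = _na_m_rates(V[i] - vshift_na)
        m[i] = am / (am + bm)
        ah, bh = _na_h_rates(V[i] - vshift_h)
        h[i] = ah / (ah + bh)
        an, bn = _k_rates(V[i] - vshift_k)
        ng[i] = an / (an + bn)
        q[i] = 1.0 / (1.0 + np.exp((V[i] - ih_vh) / ih_k))

    a_s = np.zeros(nsyn)
    b_s = np.zeros(nsyn)
    ge = ge_m
    gi = gi_m

    d = np.empty(n)
    r = np.empty(n)
    vrec = np.empty((nrec, nsteps + 1))
    ielec = np.zeros(nsteps + 1)
    for k in range(nrec):
        vrec[k, 0] = V[rec_idx[k]]

    ptr = 0
    non = on_step.shape[0]
    for step in range(nsteps):
        # background conductances (exact OU update)
        if noise_idx >= 0:
            ge = ge_m + (ge - ge_m) * fe + se * xi[step, 0]
            gi = gi_m + (gi - gi_m) * fi + si * xi[step, 1]

        # synaptic state: decay, then fire the onsets scheduled for this step
        for s in range(nsyn):
            a_s[s] *= syn_fr[s]
            b_s[s] *= syn_fd[s]
        while ptr < non and on_step[ptr] == step:
            a_s[on_syn[ptr]] += 1.0
            b_s[on_syn[ptr]] += 1.0
            ptr += 1

        # gating variables at the previous voltage
        for i in range(n):
            if gna[i] > 0.0:
                am, bm = _na_m_rates(V[i] - vshift_na)
                sm = am + bm
                m[i] += (am / sm - m[i]) * (1.0 - np.exp(-dt * phi * phi_m * sm))
                ah, bh = _na_h_rates(V[i] - vshift_h)
                sh = ah + bh
                h[i] += (ah / sh - h[i]) * (1.0 - np.exp(-dt * phi * sh))
            if gk[i] > 0.0:
                an, bn = _k_rates(V[i] - vshift_k)
                sn = an + bn
                ng[i] += (an / sn - ng[i]) * (1.0 - np.exp(-dt * phi * sn))
            if gh[i] > 0.0:
                qi = 1.0 / (1.0 + np.exp((V[i] - ih_vh) / ih_k))
                q[i] += (qi - q[i]) * (1.0 - np.exp(-dt / ih_tau))

        # assemble diagonal and right-hand side
        for i in range(n):
            di = cdt[i] + gpas[i]
            ri = cdt[i] * V[i] + gpas[i] * epas[i] + iinj_static[i]
            if gna[i] > 0.0:
                g = gna[i] * m[i] * m[i] * m[i] * h[i]
                di += g
                ri += g * ena
            if gk[i] > 0.0:
                g = gk[i] * ng[i] * ng[i] * ng[i] * ng[i]
                di += g
                ri += g * ek
            if gh[i] > 0.0:
                g = gh[i] * q[i]
                di += g
                ri += g * eh
            d[i] = di
            r[i] = ri
        for s in range(nsyn):
            g = syn_g[s] * (b_s[s] - a_s[s])
            i = syn_comp[s]
            d[i] += g
            r[i] += g * syn_e[s]
        if noise_idx >= 0:
            gep = ge if ge > 0.0 else 0.0
            gip = gi if gi > 0.0 else 0.0
            d[noise_idx] += gep + gip
            r[noise_idx] += gep * e_e + gip * e_i
        if clamp_idx >= 0:
            d[clamp_idx] += g_clamp
            r[clamp_idx] += g_clamp * vcmd[step]
        if inj_idx >= 0:
            r[inj_idx] += inj_na[step]

        # axial coupling and parent-ordered elimination
        for i in range(1, n):
            d[i] += gax[i]
            d[parent[i]] += gax[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = gax[i] / d[i]
            d[p] -= f * gax[i]
            r[p] += f * r[i]
        V[0] = r[0] / d[0]
        for i in range(1, n):
            V[i] = (r[i] + gax[i] * V[parent[i]]) / d[i]

        for k in range(nrec):
            vrec[k, step + 1] = V[rec_idx[k]]
        if clamp_idx >= 0:
            ielec[step + 1] = g_clamp * (vcmd[step] - V[clamp_idx])

    return vrec, ielec
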