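"""Numba kernel for the double-cable axon: backward-Euler block-tridiagonal stepping.

State per compartment is the axolemma voltage ``Vm`` (mV, relative to the
periaxonal space) and the sheath voltage ``Vx`` (periaxonal space relative
to the applied extracellular potential).  Each backward-Euler step solves
a block-tridiagonal system with 2x2 blocks (one block per compartment) by
block Thomas elimination; nodal channel gating is advanced first with an
exponential update read from per-timestep lookup tables, which keeps the
per-step system linear.

All quantities use NEURON-like units: mV, ms, uS, nF, nA.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_plan(
    # morphology constants, shape (ncomp,) / (ncomp-1,)
    cm, cx, gmy, gion_pas, src_pas, ga, gp, sga, sgp,
    node_idx, gna, gnap, gk, gl, ena, ek, el,
    # drive: unit-field axial source terms (nA per unit scale), (ncomp, nb)
    ave1, ave2,
    # integration plan
    seg_nsteps, seg_dt, seg_table, seg_pulse,
    pulse_width, scale, t_start,
    # gating lookup tables: (ntab, 4, nv) for A and B of m,h,p,s
    vmin, dv, tabA, tabB,
    # state, modified in place: (ncomp, nb) and (nnode, nb)
    Vm, Vx, m, h, p, s,
    # spike detection
    rec_idx, thr, lockout, spike_times, spike_counts,
    # probe recording (batch column 0 only)
    probe_idx, probe_vm, probe_t, record_probes,
):
    ncomp, nb = Vm.shape
    nnode = node_idx.shape[0]
    nv = tabA.shape[2]

    Gion = np.empty((ncomp, nb))
    Src = np.empty((ncomp, nb))
    for i in range(ncomp):
        for b in range(nb):
            Gion[i, b] = gion_pas[i]
            Src[i, b] = src_pas[i]

    D11 = np.empty((ncomp, nb)); D12 = np.empty((ncomp, nb))
    D21 = np.empty((ncomp, nb)); D22 = np.empty((ncomp, nb))
    R1 = np.empty((ncomp, nb)); R2 = np.empty((ncomp, nb))

    vprev = np.empty(nb)
    for b in range(nb):
        vprev[b] = Vm[rec_idx, b]
    last_spike = np.full(nb, -1e9)

    t = t_start
    step_counter = 0
    for si in range(seg_nsteps.shape[0]):
        dt = seg_dt[si]
        tab = seg_table[si]
        pulsed = seg_pulse[si]
        inv_dt = 1.0 / dt
        for k in range(seg_nsteps[si]):
            t_new = t + dt
            sdr = 0.0
            if pulsed and (k + 0.5) * dt < pulse_width:
                sdr = scale

            # --- gating update (exponential integrator, frozen V) ---
            for jn in range(nnode):
                i = node_idx[jn]
                for b in range(nb):
                    u = (Vm[i, b] - vmin) / dv
                    if u < 0.0:
                        u = 0.0
                    if u > nv - 1.001:
                        u = nv - 1.001
                    i0 = int(u)
                    f = u - i0
                    Am = tabA[tab, 0, i0] * (1 - f) + tabA[tab, 0, i0 + 1] * f
                    Bm = tabB[tab, 0, i0] * (1 - f) + tabB[tab, 0, i0 + 1] * f
                    Ah = tabA[tab, 1, i0] * (1 - f) + tabA[tab, 1, i0 + 1] * f
                    Bh = tabB[tab, 1, i0] * (1 - f) + tabB[tab, 1, i0 + 1] * f
                    Ap = tabA[tab, 2, i0] * (1 - f) + tabA[tab, 2, i0 + 1] * f
                    Bp = tabB[tab, 2, i0] * (1 - f) + tabB[tab, 2, i0 + 1] * f
                    As = tabA[tab, 3, i0] * (1 - f) + tabA[tab, 3, i0 + 1] * f
                    Bs = tabB[tab, 3, i0] * (1 - f) + tabB[tab, 3, i0 + 1] * f
                    mv = Am * m[jn, b] + Bm
                    hv = Ah * h[jn, b] + Bh
                    pv = Ap * p[jn, b] + Bp
                    sv = As * s[jn, b] + Bs
                    m[jn, b] = mv
                    h[jn, b] = hv
                    p[jn, b] = pv
                    s[jn, b] = sv
                    gnav = gna[jn] * mv * mv * mv * hv
                    gnapv = gnap[jn] * pv * pv * pv
                    gkv = gk[jn] * sv
                    Gion[i, b] = gnav + gnapv + gkv + gl[jn]
                    Src[i, b] = (gnav + gnapv) * ena + gkv * ek + gl[jn] * el

            # --- forward elimination ---
            for i in range(ncomp):
                for b in range(nb):
                    a11 = cm[i] * inv_dt + Gion[i, b] + sga[i]
                    a12 = sga[i]
                    a21 = sga[i]
                    a22 = cx[i] * inv_dt + gmy[i] + sga[i] + sgp[i]
                    r1 = cm[i] * inv_dt * Vm[i, b] + Src[i, b] + sdr * ave1[i, b]
                    r2 = cx[i] * inv_dt * Vx[i, b] + sdr * ave2[i, b]
                    if i > 0:
                        b11 = -ga[i - 1]
                        b22 = -(ga[i - 1] + gp[i - 1])
                        det = D11[i - 1, b] * D22[i - 1, b] - D12[i - 1, b] * D21[i - 1, b]
                        i11 = D22[i - 1, b] / det
                        i12 = -D12[i - 1, b] / det
                        i21 = -D21[i - 1, b] / det
                        i22 = D11[i - 1, b] / det
                        # M = B_{i-1} @ inv(D'_{i-1}); B = [[b11, b11], [b11, b22]]
                        m11 = b11 * i11 + b11 * i21
                        m12 = b11 * i12 + b11 * i22
                        m21 = b11 * i11 + b22 * i21
                        m22 = b11 * i12 + b22 * i22
                        a11 -= m11 * b11 + m12 * b11
                        a12 -= m11 * b11 + m12 * b22
                        a21 -= m21 * b11 + m22 * b11
                        a22 -= m21 * b11 + m22 * b22
                        r1 -= m11 * R1[i - 1, b] + m12 * R2[i - 1, b]
                        r2 -= m21 * R1[i - 1, b] + m22 * R2[i - 1, b]
                    D11[i, b] = a11
                    D12[i, b] = a12
                    D21[i, b] = a21
                    D22[i, b] = a22
                    R1[i, b] = r1
                    R2[i, b] = r2

            # --- back substitution ---
            i = ncomp - 1
            for b in range(nb):
                det = D11[i, b] * D22[i, b] - D12[i, b] * D21[i, b]
                Vm[i, b] = (D22[i, b] * R1[i, b] - D12[i, b] * R2[i, b]) / det
                Vx[i, b] = (-D21[i, b] * R1[i, b] + D11[i, b] * R2[i, b]) / det
            for i in range(ncomp - 2, -1, -1):
                b11 = -ga[i]
                b22 = -(ga[i] + gp[i])
                for b in range(nb):
                    r1 = R1[i, b] - (b11 * Vm[i + 1, b] + b11 * Vx[i + 1, b])
                    r2 = R2[i, b] - (b11 * Vm[i + 1, b] + b22 * Vx[i + 1, b])
                    det = D11[i, b] * D22[i, b] - D12[i, b] * D21[i, b]
                    Vm[i, b] = (D22[i, b] * r1 - D12[i, b] * r2) / det
                    Vx[i, b] = (-D21[i, b] * r1 + D11[i, b] * r2) / det

            # --- spike detection at the recording node ---
            for b in range(nb):
                v = Vm[rec_idx, b]
                if vprev[b] < thr <= v and t_new - last_spike[b] >= lockout:
                    c = spike_counts[b]
                    if c < spike_times.shape[1]:
                        spike_times[b, c] = t_new
                        spike_counts[b] = c + 1
                    last_spike[b] = t_new
                vprev[b] = v

            if record_probes:
                for q in range(probe_idx.shape[0]):
                    probe_vm[step_counter, q] = Vm[probe_idx[q], 0]
                probe_t[step_counter] = t_new

            t = t_new
            step_counter += 1
    return t
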