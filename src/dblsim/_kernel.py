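"""Numba-compiled integration kernel for the reduced compartmental model.

The kernel advances a 3-compartment (soma, proximal, distal dendrite) cell:
gating variables by exponential Euler at the shifted voltage, compartment
voltages by a Crank-Nicolson implicit step (all membrane currents are linear
in v given the gates, so the update is a tridiagonal solve), and the internal
Ca2+ pool by exponential relaxation toward its influx-driven target.  The
depolarization-baseline mechanism (EMA of somatic depolarization -> Hill
drivers -> reversal/kinetic shifts) is evaluated once per step from the
somatic voltage at the start of the step and applied everywhere.

Everything here is plain arrays so that numba can compile it; the object
layer in ``dblsim.cell`` builds the arrays from the channel/config types.

Family codes (kept in sync with dblsim.channels):
  gate mode: 0 = (inf, tau), 1 = (alpha, beta) rate pair
  inf families:  0 sigmoid(vhalf, k)
  tau families:  0 constant(c), 1 sigmoid(base, amp, vhalf, k), 2 bell(base, amp, vhalf, w)
  rate families: 0 exp(a, vhalf, k), 1 sigmoid(a, vhalf, k), 2 linoid(a, vhalf, k)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NCOMP = 3
V_DIVERGE = 200.0  # mV; |v| beyond this signals numerical divergence


@njit(cache=False)
def _inf_eval(fam, p, v):
    # only family 0 (sigmoid) defined for inf curves
    return 1.0 / (1.0 + math.exp((p[0] - v) / p[1]))


@njit(cache=False)
def _tau_eval(fam, p, v):
    if fam == 0:
        return p[0]
    elif fam == 1:
        return p[0] + p[1] / (1.0 + math.exp((p[2] - v) / p[3]))
    else:
        x = (v - p[2]) / p[3]
        return p[0] + p[1] * math.exp(-x * x)


@njit(cache=False)
def _rate_eval(fam, p, v):
    if fam == 0:
        return p[0] * math.exp((v - p[1]) / p[2])
    elif fam == 1:
        return p[0] / (1.0 + math.exp((p[1] - v) / p[2]))
    else:
        x = (v - p[1]) / p[2]
        if abs(x) < 1e-7:
            return p[0] * p[2] * (1.0 + 0.5 * x)
        return p[0] * p[2] * x / -math.expm1(-x)


@njit(cache=False)
def _gate_inf_tau(mode, f1, p1, f2, p2, v):
    if mode == 0:
        return _inf_eval(f1, p1, v), _tau_eval(f2, p2, v)
    a = _rate_eval(f1, p1, v)
    b = _rate_eval(f2, p2, v)
    s = a + b
    return a / s, 1.0 / s


@njit(cache=False)
def simulate(
    # geometry / passive (totals per compartment)
    cm,            # (3,) nF
    gl,            # (3,) uS
    el,            # (3,) mV
    ax,            # (2,) uS: soma-prox, prox-dist coupling
    area,          # (3,) cm^2
    # channels
    gmax,          # (nchan, 3) uS
    rev_kind,      # (nchan,) 0 Na, 1 K, 2 Ca, 3 fixed
    e_fixed,       # (nchan,) mV
    ca_dep,        # (nchan,) 0/1
    ca_kd,         # (nchan,) mM
    # gates
    g_chan,        # (ng,) channel index
    g_mode,        # (ng,) 0 inf/tau, 1 rates
    g_f1, g_p1,    # (ng,), (ng,4)
    g_f2, g_p2,    # (ng,), (ng,4)
    g_exp,         # (ng,)
    g_shift,       # (ng,) -1 none, 0 Na, 1 K, 2 Ca
    # reversals & calcium pool
    e_na0, e_k0,   # scalars, mV
    ca_rest, ca_out, ca_tau, ca_depth,  # mM, mM, ms, um
    # mechanism: [on, F, t_step_eff, v_rest, aENa, BNa, CNa, aNa,
    #             aEK, BK, CK, aK, aCa, BCa, CCa, literal_signs]
    mech,
    static_sh,     # (3,) mV static kinetic shift per class (Na, K, Ca)
    # stimulation
    inj,           # (3,) nA constant amplitude per compartment
    t_on, t_off,   # ms injection window
    # synaptic event streams
    syn_comp,      # (ns,) target compartment
    syn_gpeak,     # (ns,) uS per unit event weight (peak-normalized)
    syn_tr, syn_td,  # (ns,) ms
    syn_e,         # (ns,) mV
    syn_nmda,      # (ns,) 0/1
    mg_par,        # (3,) [Mg]/K_mg ratio premultiplied? -> [mg_over_k, gamma, unused]
    ev_t, ev_w,    # concatenated event times/weights
    ev_start,      # (ns+1,) stream offsets into ev_t
    # initial state
    v0,            # (3,)
    gate0,         # (ng, 3)
    ca0,           # (3,)
    ema0, cnt0,    # EMA initial state
    # run control
    nsteps, dt, rec_every, record_gates,
):
    nchan = gmax.shape[0]
    ng = g_chan.shape[0]
    ns = syn_comp.shape[0]
    nrec = nsteps // rec_every + 1

    v = v0.copy()
    gates = gate0.copy()
    ca = ca0.copy()
    ema = ema0
    cnt = cnt0

    v_rec = np.empty((nrec, NCOMP))
    shift_rec = np.empty((nrec, 9))  # ema, fNa, fK, fCa, dENa, dEK, shNa, shK, shCa
    if record_gates:
        gate_rec = np.empty((nrec, ng))
    else:
        gate_rec = np.empty((1, ng))

    syn_a = np.zeros(ns)
    syn_b = np.zeros(ns)
    syn_norm = np.empty(ns)
    for s in range(ns):
        tr = syn_tr[s]
        td = syn_td[s]
        tp = tr * td / (td - tr) * math.log(td / tr)
        syn_norm[s] = 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))
    ev_ptr = np.zeros(ns, dtype=np.int64)
    for s in range(ns):
        ev_ptr[s] = ev_start[s]

    mech_on = mech[0] > 0.5
    F = mech[1]
    t_step = int(mech[2])
    v_rest = mech[3]

    # shift state
    f_na = 0.0
    f_k = 0.0
    f_ca = 0.0
    de_na = 0.0
    de_k = 0.0
    sh = np.zeros(3)

    kca = 1.0e4 / (2.0 * 96485.33212 * ca_depth)  # mM/ms per (mA/cm^2)
    rt2f = 13.277  # RT/2F at 308.15 K, mV

    # record initial sample
    v_rec[0, 0] = v[0]
    v_rec[0, 1] = v[1]
    v_rec[0, 2] = v[2]
    shift_rec[0, 0] = ema
    for j in range(1, 9):
        shift_rec[0, j] = 0.0
    if record_gates:
        for g in range(ng):
            gate_rec[0, g] = gates[g, 0]

    gtot = np.zeros(NCOMP)
    ge = np.zeros(NCOMP)
    ica = np.zeros(NCOMP)
    gca = np.zeros(NCOMP)

    err = 0
    t_err = -1.0

    for n in range(1, nsteps + 1):
        t = (n - 1) * dt

        # --- mechanism: EMA of somatic depolarization, Hill drivers, shifts
        if mech_on:
            if cnt < t_step:
                cnt += 1
            a = F / (cnt + 1.0)
            x = v[0] - v_rest
            ema = a * x + (1.0 - a) * ema
            if ema < 0.0:
                ema = 0.0
            f_na = mech[5] * mech[6] * ema / (mech[6] + ema)
            f_k = mech[9] * mech[10] * ema / (mech[10] + ema)
            f_ca = mech[13] * mech[14] * ema / (mech[14] + ema)
            de_na = -mech[4] * f_na
            if mech[15] > 0.5:
                de_k = -mech[8] * f_k
            else:
                de_k = mech[8] * f_k
            sh[0] = mech[7] * f_na
            sh[1] = mech[11] * f_k
            sh[2] = mech[12] * f_ca

        e_na = e_na0 + de_na
        e_k = e_k0 + de_k

        # --- gate update (exponential Euler at shifted voltage)
        for g in range(ng):
            cls = g_shift[g]
            if cls >= 0:
                shv = sh[cls] + static_sh[cls]
            else:
                shv = 0.0
            for k in range(NCOMP):
                veff = v[k] - shv
                inf, tau = _gate_inf_tau(g_mode[g], g_f1[g], g_p1[g], g_f2[g], g_p2[g], veff)
                gates[g, k] += (inf - gates[g, k]) * -math.expm1(-dt / tau)

        # --- membrane conductances
        for k in range(NCOMP):
            gtot[k] = gl[k]
            ge[k] = gl[k] * el[k]
            gca[k] = 0.0
        for c in range(nchan):
            if rev_kind[c] == 0:
                e_c = e_na
            elif rev_kind[c] == 1:
                e_c = e_k
            elif rev_kind[c] == 2:
                e_c = 0.0  # set per compartment below
            else:
                e_c = e_fixed[c]
            for k in range(NCOMP):
                g = gmax[c, k]
                if g == 0.0:
                    continue
                of = 1.0
                for gg in range(ng):
                    if g_chan[gg] == c:
                        x = gates[gg, k]
                        e = g_exp[gg]
                        y = x
                        for _ in range(e - 1):
                            y *= x
                        of *= y
                if ca_dep[c] == 1:
                    of *= ca[k] / (ca[k] + ca_kd[c])
                gc = g * of
                gtot[k] += gc
                if rev_kind[c] == 2:
                    e_ca_k = rt2f * math.log(ca_out / ca[k])
                    ge[k] += gc * e_ca_k
                    gca[k] += gc
                else:
                    ge[k] += gc * e_c

        # --- synaptic conductances
        for s in range(ns):
            syn_a[s] *= math.exp(-dt / syn_tr[s])
            syn_b[s] *= math.exp(-dt / syn_td[s])
            p = ev_ptr[s]
            while p < ev_start[s + 1] and ev_t[p] < t + dt:
                syn_a[s] += ev_w[p]
                syn_b[s] += ev_w[p]
                p += 1
            ev_ptr[s] = p
            gsyn = syn_gpeak[s] * syn_norm[s] * (syn_b[s] - syn_a[s])
            if gsyn != 0.0:
                k = syn_comp[s]
                if syn_nmda[s] == 1:
                    gsyn /= 1.0 + mg_par[0] * math.exp(-mg_par[1] * v[k])
                gtot[k] += gsyn
                ge[k] += gsyn * syn_e[s]

        # --- injected current
        b0 = ge[0]
        b1 = ge[1]
        b2 = ge[2]
        if t_on <= t < t_off:
            b0 += inj[0]
            b1 += inj[1]
            b2 += inj[2]

        # --- Crank-Nicolson tridiagonal solve (soma - prox - dist chain)
        d0 = cm[0] / dt + 0.5 * (gtot[0] + ax[0])
        d1 = cm[1] / dt + 0.5 * (gtot[1] + ax[0] + ax[1])
        d2 = cm[2] / dt + 0.5 * (gtot[2] + ax[1])
        o01 = -0.5 * ax[0]
        o12 = -0.5 * ax[1]
        r0 = (cm[0] / dt - 0.5 * (gtot[0] + ax[0])) * v[0] + 0.5 * ax[0] * v[1] + b0
        r1 = (cm[1] / dt - 0.5 * (gtot[1] + ax[0] + ax[1])) * v[1] \
            + 0.5 * (ax[0] * v[0] + ax[1] * v[2]) + b1
        r2 = (cm[2] / dt - 0.5 * (gtot[2] + ax[1])) * v[2] + 0.5 * ax[1] * v[1] + b2
        # Thomas elimination
        w = o01 / d0
        d1p = d1 - w * o01
        r1p = r1 - w * r0
        w2 = o12 / d1p
        d2p = d2 - w2 * o12
        r2p = r2 - w2 * r1p
        v2n = r2p / d2p
        v1n = (r1p - o12 * v2n) / d1p
        v0n = (r0 - o01 * v1n) / d0

        vm0 = 0.5 * (v[0] + v0n)
        vm1 = 0.5 * (v[1] + v1n)
        vm2 = 0.5 * (v[2] + v2n)
        v[0] = v0n
        v[1] = v1n
        v[2] = v2n

        # --- calcium pool (exponential relaxation toward influx-driven target)
        vm = (vm0, vm1, vm2)
        for k in range(NCOMP):
            if gca[k] > 0.0:
                e_ca_k = rt2f * math.log(ca_out / ca[k])
                ica[k] = gca[k] * (vm[k] - e_ca_k) / (area[k] * 1.0e6)  # mA/cm^2
            else:
                ica[k] = 0.0
            influx = -kca * ica[k]  # positive for inward Ca current
            target = ca_rest + influx * ca_tau
            ca[k] += (target - ca[k]) * -math.expm1(-dt / ca_tau)
            if ca[k] < 1.0e-9:
                ca[k] = 1.0e-9

        if abs(v[0]) > V_DIVERGE or abs(v[1]) > V_DIVERGE or abs(v[2]) > V_DIVERGE:
            err = 1
            t_err = t + dt
            break

        if n % rec_every == 0:
            i = n // rec_every
            v_rec[i, 0] = v[0]
            v_rec[i, 1] = v[1]
            v_rec[i, 2] = v[2]
            shift_rec[i, 0] = ema
            shift_rec[i, 1] = f_na
            shift_rec[i, 2] = f_k
            shift_rec[i, 3] = f_ca
            shift_rec[i, 4] = de_na
            shift_rec[i, 5] = de_k
            shift_rec[i, 6] = sh[0]
            shift_rec[i, 7] = sh[1]
            shift_rec[i, 8] = sh[2]
            if record_gates:
                for g in range(ng):
                    gate_rec[i, g] = gates[g, 0]

    return err, t_err, v_rec, shift_rec, gate_rec, v, gates, ca, ema, cnt
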