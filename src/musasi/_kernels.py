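"""Compiled Monte Carlo inner loop for the half-sarcomere ensemble.

The kernel advances every myosin head and every troponin/tropomyosin (T/T)
unit of a (possibly batched) half-sarcomere ensemble through ``n`` micro
steps of size ``dt`` with the filament sliding extrapolated from the stretch
rate at the interval start.  Hazards are evaluated synchronously from
start-of-step states, so the result is independent of iteration order.

Randomness is counter based: every draw is a splitmix64-style hash of
(seed, global micro-step, entity index, draw index), which makes runs
bitwise reproducible from one integer seed and gives each (filament,
molecule) pair its own logical stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# parameter-vector layout (float64); see pack_params below
P_KPOS, P_KNEG, P_KBT, P_XMIN, P_XMAX = 0, 1, 2, 3, 4
P_S1, P_S2, P_E0, P_E1, P_E2 = 5, 6, 7, 8, 9
P_PREF1, P_PREF2, P_RMAX, P_KIND = 10, 11, 12, 13
P_KNP0, P_KPN0, P_KA, P_KD, P_KOFF, P_KREC = 14, 15, 16, 17, 18, 19
P_GAMMA, P_PERM_BLOCKED = 20, 21
P_TT_KON, P_TT_KOFFCA, P_TT_KOPEN, P_TT_KCLOSE = 22, 23, 24, 25
P_HSL0 = 26
P_TT_HOLD, P_MPT, P_NM = 27, 28, 29
NPARAMS = 30

# myosin states (must match sarcomere_core)
_N_XB, _P_XB, _N_ATP, _PRER, _POSTR1, _POSTR2 = 0, 1, 2, 3, 4, 5
# T/T unit states
TT_OFF, TT_ONCA, TT_OPEN = 0, 1, 2

# transition-edge ids (myosin 0..10, T/T 11..14)
E_NP, E_PN, E_ATTACH, E_DETACH = 0, 1, 2, 3
E_PS1F, E_PS1B, E_PS2F, E_PS2B = 4, 5, 6, 7
E_R2_CYCLE, E_ATP_CYCLE, E_FORCED = 8, 9, 10
E_TT_ON, E_TT_OFFCA, E_TT_OPEN, E_TT_CLOSE = 11, 12, 13, 14
NEDGE = 15

#: (from, to) myosin states per myosin edge id
EDGE_STATES = (
    (_N_XB, _P_XB), (_P_XB, _N_XB), (_P_XB, _PRER), (_PRER, _P_XB),
    (_PRER, _POSTR1), (_POSTR1, _PRER), (_POSTR1, _POSTR2), (_POSTR2, _POSTR1),
    (_POSTR2, _N_XB), (_N_ATP, _N_XB), (-1, _N_ATP),
)

_U1 = np.uint64(0x9E3779B97F4A7C15)
_U2 = np.uint64(0xBF58476D1CE4E5B9)
_U3 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _u01(seed, g, ent, d):
    """Uniform in (0, 1] keyed by (seed, micro-step g, entity, draw index)."""
    z = _mix64(seed ^ (np.uint64(g) * _U1))
    z = _mix64(z ^ (np.uint64(ent) * _U2) ^ (np.uint64(d) * _U3))
    return ((z >> np.uint64(11)) + np.uint64(1)) * _INV53


@njit(cache=True, inline="always")
def _randn(seed, g, ent, d):
    u1 = _u01(seed, g, ent, d)
    u2 = _u01(seed, g, ent, d + np.uint64(1))
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True, inline="always")
def _W(x, kpos, kneg):
    if x >= 0.0:
        return 0.5 * kpos * x * x
    return 0.5 * kneg * x * x


@njit(cache=True, inline="always")
def _stroke_pair(kind, pref, Ehi, Elo, si, kpos, kneg, kBT, rmax, x):
    """Capped (h_f(x), h_b(x+s_i)) pair; Ehi/Elo are E_{i-1}/E_i."""
    Wx = _W(x, kpos, kneg)
    Wxs = _W(x + si, kpos, kneg)
    if kind == 0:  # destination strain energy
        hf = pref * np.exp(-(Wxs - (Ehi - Elo)) / kBT)
        hb = pref * np.exp(-Wx / kBT)
    else:          # barrier strain energy at mid stroke
        Wm = _W(x + 0.5 * si, kpos, kneg)
        hf = pref * np.exp((Ehi + Wx - Elo - Wm) / kBT)
        hb = pref * np.exp((Wxs - Wm) / kBT)
    hi = hf if hf > hb else hb
    if hi > rmax:
        sc = rmax / hi
        hf *= sc
        hb *= sc
    return hf, hb


@njit(cache=True, inline="always")
def _sample_attach(seed, g, m, kpos, kneg, kBT, xmin, xmax):
    """Boltzmann attachment strain, truncated two-half-Gaussian."""
    sig_p = np.sqrt(kBT / kpos)
    sig_n = np.sqrt(kBT / kneg)
    p_pos = sig_p / (sig_p + sig_n)  # truncation correction negligible here
    d = np.uint64(2)
    for _ in range(1000):
        u = _u01(seed, g, m, d)
        z = np.abs(_randn(seed, g, m, d + np.uint64(1)))
        d += np.uint64(3)
        if u < p_pos:
            x = z * sig_p
            if x <= xmax:
                return x
        else:
            x = -z * sig_n
            if x >= xmin:
                return x
    return 0.0  # unreachable for sane stiffness


@njit(cache=True)
def advance_interval(
    state, x_a, s_off, lam_a, k_a_step, tt,
    tt_of_mol, batch_of_mol, pos_of_mol, batch_of_unit,
    lam_T, lam_dot, ca_steps, n, dt_ms, pk, seed64, step0,
    rec_delta, rec_state, rec_xa, rec_soff, rec_lama, rec_ka,
    edge_counts, log_events, ev_k, ev_ent, ev_from, ev_to, ev_n,
    stats_out,
):
    """Advance the ensemble through n micro steps; fill the interval record.

    Mutates the state arrays in place.  ``edge_counts`` has shape
    (B, NEDGE); record arrays have shape (n, n_molecules).  ``stats_out[0]``
    returns the maximum total-exit-rate * dt encountered (scheme validity
    check) and ``ev_n[0]`` the number of events (logged up to capacity).
    """
    n_mol = state.shape[0]
    n_unit = tt.shape[0]
    nm_per_fil = 0
    for m in range(n_mol):
        if pos_of_mol[m] + 1 > nm_per_fil:
            nm_per_fil = pos_of_mol[m] + 1

    kpos = pk[P_KPOS]; kneg = pk[P_KNEG]; kBT = pk[P_KBT]
    xmin = pk[P_XMIN]; xmax = pk[P_XMAX]
    s1 = pk[P_S1]; s2 = pk[P_S2]
    E0 = pk[P_E0]; E1 = pk[P_E1]; E2 = pk[P_E2]
    pref1 = pk[P_PREF1]; pref2 = pk[P_PREF2]
    rmax = pk[P_RMAX]; kind = int(pk[P_KIND])
    knp0 = pk[P_KNP0]; kpn0 = pk[P_KPN0]
    ka = pk[P_KA]; kd = pk[P_KD]; koff = pk[P_KOFF]; krec = pk[P_KREC]
    gam = pk[P_GAMMA]; perm_blocked = pk[P_PERM_BLOCKED]
    tt_kon = pk[P_TT_KON]; tt_koffca = pk[P_TT_KOFFCA]
    tt_kopen = pk[P_TT_KOPEN]; tt_kclose = pk[P_TT_KCLOSE]
    hsl0 = pk[P_HSL0]
    tt_hold = pk[P_TT_HOLD]
    mpt = int(pk[P_MPT]); nm_mol = int(pk[P_NM])
    units_per_fil = (nm_mol + mpt - 1) // mpt
    dt_s = dt_ms * 1.0e-3
    gpow_f = np.empty(3)
    gpow_b = np.empty(3)
    for j in range(3):
        gpow_f[j] = gam ** j
        gpow_b[j] = gam ** (-j)

    old_state = np.empty(n_mol, dtype=np.int8)
    old_tt = np.empty(n_unit, dtype=np.int8)
    rates = np.empty(3)
    targets = np.empty(3, dtype=np.int8)
    edges = np.empty(3, dtype=np.int8)
    max_rdt = 0.0
    nev = 0
    cap = ev_k.shape[0]

    for k in range(1, n + 1):
        g = step0 + np.uint64(k)
        for m in range(n_mol):
            old_state[m] = state[m]
        for u in range(n_unit):
            old_tt[u] = tt[u]

        # ---- T/T units (Ca gating), synchronous hazards -------------------
        for u in range(n_unit):
            b = batch_of_unit[u]
            st = old_tt[u]
            ca = ca_steps[k - 1, b]
            ne = 0
            if st == TT_OFF:
                rates[0] = tt_kon * ca; targets[0] = TT_ONCA
                edges[0] = E_TT_ON; ne = 1
            elif st == TT_ONCA:
                rates[0] = tt_koffca; targets[0] = TT_OFF
                edges[0] = E_TT_OFFCA
                rates[1] = tt_kopen; targets[1] = TT_OPEN
                edges[1] = E_TT_OPEN; ne = 2
            else:
                # attached heads under this unit sterically hold the
                # tropomyosin open (feedback of the myosin-head states on
                # the T/T rate constants)
                kc = tt_kclose
                if tt_hold != 1.0:
                    fil = u // units_per_fil
                    pos0 = (u % units_per_fil) * mpt
                    m0 = fil * nm_mol + pos0
                    m1 = m0 + mpt
                    if m1 > (fil + 1) * nm_mol:
                        m1 = (fil + 1) * nm_mol
                    for mm in range(m0, m1):
                        sm = old_state[mm]
                        if sm == _P_XB or sm >= _PRER:
                            kc = tt_kclose * tt_hold
                            break
                rates[0] = kc; targets[0] = TT_ONCA
                edges[0] = E_TT_CLOSE; ne = 1
            rtot = 0.0
            for e in range(ne):
                rtot += rates[e]
            if rtot <= 0.0:
                continue
            rdt = rtot * dt_s
            if rdt > max_rdt:
                max_rdt = rdt
            p = -np.expm1(-rdt)
            uu = _u01(seed64, g, np.uint64(n_mol + u), np.uint64(0))
            if uu < p:
                pick = uu / p * rtot
                acc = 0.0
                for e in range(ne):
                    acc += rates[e]
                    if pick <= acc:
                        tt[u] = targets[e]
                        edge_counts[b, edges[e]] += 1
                        if log_events:
                            if nev < cap:
                                ev_k[nev] = k
                                ev_ent[nev] = n_mol + u
                                ev_from[nev] = st
                                ev_to[nev] = targets[e]
                            nev += 1
                        break

        # ---- myosin heads -------------------------------------------------
        for m in range(n_mol):
            b = batch_of_mol[m]
            st = old_state[m]
            lam_k = lam_T[b] + k * dt_ms * lam_dot[b]

            if st >= _PRER:
                x = x_a[m] + s_off[m] + hsl0 * (lam_k - lam_a[m])
                if x < xmin or x > xmax:
                    # extreme rod strain: forced detachment to N_ATP
                    state[m] = _N_ATP
                    x_a[m] = np.nan; lam_a[m] = np.nan
                    s_off[m] = 0.0; k_a_step[m] = -1
                    edge_counts[b, E_FORCED] += 1
                    if log_events:
                        if nev < cap:
                            ev_k[nev] = k; ev_ent[nev] = m
                            ev_from[nev] = st; ev_to[nev] = _N_ATP
                        nev += 1
                    continue
            else:
                x = 0.0

            # nearest-neighbour cooperativity exponent from start-of-step
            ng = 0
            pos = pos_of_mol[m]
            if pos > 0:
                sn = old_state[m - 1]
                if sn == _P_XB or sn >= _PRER:
                    ng += 1
            if pos < nm_per_fil - 1:
                sn = old_state[m + 1]
                if sn == _P_XB or sn >= _PRER:
                    ng += 1

            ne = 0
            if st == _N_XB:
                perm = 1.0 if old_tt[tt_of_mol[m]] == TT_OPEN else perm_blocked
                r = knp0 * gpow_f[ng] * perm
                if r > 0.0:
                    rates[0] = r; targets[0] = _P_XB; edges[0] = E_NP; ne = 1
            elif st == _P_XB:
                rates[0] = kpn0 * gpow_b[ng]; targets[0] = _N_XB
                edges[0] = E_PN
                rates[1] = ka; targets[1] = _PRER; edges[1] = E_ATTACH
                ne = 2
            elif st == _N_ATP:
                rates[0] = krec; targets[0] = _N_XB; edges[0] = E_ATP_CYCLE
                ne = 1
            elif st == _PRER:
                hf, _hb = _stroke_pair(kind, pref1, E0, E1, s1,
                                       kpos, kneg, kBT, rmax, x)
                rates[0] = hf; targets[0] = _POSTR1; edges[0] = E_PS1F
                rates[1] = kd; targets[1] = _P_XB; edges[1] = E_DETACH
                ne = 2
            elif st == _POSTR1:
                _hf, hb = _stroke_pair(kind, pref1, E0, E1, s1,
                                       kpos, kneg, kBT, rmax, x - s1)
                rates[0] = hb; targets[0] = _PRER; edges[0] = E_PS1B
                hf2, _hb2 = _stroke_pair(kind, pref2, E1, E2, s2,
                                         kpos, kneg, kBT, rmax, x)
                rates[1] = hf2; targets[1] = _POSTR2; edges[1] = E_PS2F
                ne = 2
            else:  # _POSTR2
                _hf2, hb2 = _stroke_pair(kind, pref2, E1, E2, s2,
                                         kpos, kneg, kBT, rmax, x - s2)
                rates[0] = hb2; targets[0] = _POSTR1; edges[0] = E_PS2B
                rates[1] = koff; targets[1] = _N_XB; edges[1] = E_R2_CYCLE
                ne = 2

            rtot = 0.0
            for e in range(ne):
                rtot += rates[e]
            if rtot <= 0.0:
                continue
            rdt = rtot * dt_s
            if rdt > max_rdt:
                max_rdt = rdt
            p = -np.expm1(-rdt)
            uu = _u01(seed64, g, np.uint64(m), np.uint64(0))
            if uu < p:
                pick = uu / p * rtot
                acc = 0.0
                for e in range(ne):
                    acc += rates[e]
                    if pick <= acc:
                        tgt = targets[e]
                        eid = edges[e]
                        if eid == E_ATTACH:
                            x_a[m] = _sample_attach(seed64, g, np.uint64(m),
                                                    kpos, kneg, kBT,
                                                    xmin, xmax)
                            lam_a[m] = lam_k
                            s_off[m] = 0.0
                            k_a_step[m] = k
                        elif eid == E_PS1F:
                            s_off[m] = s1
                        elif eid == E_PS1B:
                            s_off[m] = 0.0
                        elif eid == E_PS2F:
                            s_off[m] = s1 + s2
                        elif eid == E_PS2B:
                            s_off[m] = s1
                        elif tgt < _PRER:
                            # any detachment clears the attachment bookkeeping
                            x_a[m] = np.nan; lam_a[m] = np.nan
                            s_off[m] = 0.0; k_a_step[m] = -1
                        state[m] = tgt
                        edge_counts[b, eid] += 1
                        if log_events:
                            if nev < cap:
                                ev_k[nev] = k; ev_ent[nev] = m
                                ev_from[nev] = st; ev_to[nev] = tgt
                            nev += 1
                        break

        # ---- interval record at time T + k*dt (post-step states) ----------
        for m in range(n_mol):
            st = state[m]
            rec_state[k - 1, m] = st
            if st >= _PRER:
                rec_delta[k - 1, m] = 1
                rec_xa[k - 1, m] = x_a[m]
                rec_soff[k - 1, m] = s_off[m]
                rec_lama[k - 1, m] = lam_a[m]
                rec_ka[k - 1, m] = k_a_step[m]
            else:
                rec_delta[k - 1, m] = 0
                rec_xa[k - 1, m] = 0.0
                rec_soff[k - 1, m] = 0.0
                rec_lama[k - 1, m] = 0.0
                rec_ka[k - 1, m] = 0

    stats_out[0] = max_rdt
    ev_n[0] = nev
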