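"""Compiled fixed-step integrator for the VTA microcircuit.

The biophysical formulas live in :mod:`vtanic.neurons`; here they are
evaluated once on a fine voltage grid and the inner loop only interpolates
the resulting tables.  Gating variables, synaptic gates and receptor pools
use exponential-Euler updates (exact for frozen voltage / piecewise-constant
agonist); membrane voltages use explicit Euler.  Agonist concentrations are
advanced recursively (exact exponential decay between grid-aligned pulses),
so no per-step transcendental calls are needed except for the
nicotine-dependent desensitization time constant.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# voltage grid for lookup tables
V_MIN = -130.0
V_MAX = 70.0
DV = 0.05

# DA table rows
DA_MCA, DA_MNA3, DA_HINF, DA_HFAC, DA_NINF, DA_NFAC, DA_QINF, DA_QFAC, \
    DA_UINF, DA_UFAC, DA_MSNA, DA_MGB = range(12)

# GABA table rows
GB_MINF3, GB_HINF, GB_HFAC, GB_NINF, GB_NFAC = range(5)

# DA scalar parameter layout
DP_CM, DP_GCA, DP_ECA, DP_GSK, DP_KSK, DP_SKHILL, DP_KCA, DP_TAUCA, \
    DP_GKS, DP_GDR, DP_GNA, DP_ENA, DP_EK, DP_GSNA, DP_GL, DP_EL, \
    DP_GH, DP_EH, DP_GNMDA, DP_GAMPA, DP_EGLU, DP_GGABA, DP_EGABA, \
    DP_ICONST = range(24)

# GABA scalar parameter layout (leak conductance is per neuron)
GP_CM, GP_GNA, GP_ENA, GP_GK, GP_EK, GP_EL, GP_IBIAS = range(7)

# receptor pool parameter layout
RP_GMAX, RP_EC50, RP_IC50, RP_KTAU, RP_W, RP_NACT, RP_NDES, RP_ACTFAC, \
    RP_TDBASE, RP_TDAMP, RP_EREV = range(11)

# synaptic gate parameter layout
GT_NMDA_FAC, GT_NMDA_INC, GT_AMPA_FAC, GT_AMPA_INC, GT_GABA_FAC, \
    GT_GABA_INC = range(6)

SPIKE_THRESH = -20.0
SPIKE_LOCKOUT = 2.0

N_TRACE_CH = 12


def voltage_grid() -> np.ndarray:
    return np.arange(V_MIN, V_MAX + DV / 2, DV)


def build_da_tables(p, dt: float) -> np.ndarray:
    """Tabulate DA gating steady states / decay factors on the voltage grid."""
    v = voltage_grid()
    tab = np.empty((12, v.size))
    tab[DA_MCA] = p.mca_inf(v)
    tab[DA_MNA3] = p.mna_inf(v) ** 3
    tab[DA_HINF] = p.hna_inf(v)
    tab[DA_HFAC] = np.exp(-dt / p.hna_tau(v))
    tab[DA_NINF] = p.ndr_inf(v)
    tab[DA_NFAC] = np.full(v.size, np.exp(-dt / p.ndr_tau))
    tab[DA_QINF] = p.qh_inf(v)
    tab[DA_QFAC] = np.full(v.size, np.exp(-dt / p.qh_tau))
    tab[DA_UINF] = p.uks_inf(v)
    tab[DA_UFAC] = np.full(v.size, np.exp(-dt / p.uks_tau))
    tab[DA_MSNA] = p.msna_inf(v)
    tab[DA_MGB] = 1.0 / (1.0 + (p.mg / p.mg_k) * np.exp(-p.mg_gamma * v))
    return tab


def build_gaba_tables(p, dt: float) -> np.ndarray:
    v = voltage_grid()
    tab = np.empty((5, v.size))
    tab[GB_MINF3] = p.m_inf(v) ** 3
    tab[GB_HINF] = p.h_inf(v)
    tab[GB_HFAC] = np.exp(-dt / p.h_tau(v))
    tab[GB_NINF] = p.n_inf(v)
    tab[GB_NFAC] = np.exp(-dt / p.n_tau(v))
    return tab


def pack_da_params(p) -> np.ndarray:
    dp = np.zeros(24)
    dp[DP_CM] = p.cm
    dp[DP_GCA] = p.g_ca
    dp[DP_ECA] = p.e_ca
    dp[DP_GSK] = p.g_sk
    dp[DP_KSK] = p.k_sk
    dp[DP_SKHILL] = p.sk_hill
    dp[DP_KCA] = p.k_ca
    dp[DP_TAUCA] = p.tau_ca
    dp[DP_GKS] = p.g_ks
    dp[DP_GDR] = p.g_dr
    dp[DP_GNA] = p.g_na
    dp[DP_ENA] = p.e_na
    dp[DP_EK] = p.e_k
    dp[DP_GSNA] = p.g_sna
    dp[DP_GL] = p.g_leak
    dp[DP_EL] = p.e_leak
    dp[DP_GH] = p.g_h
    dp[DP_EH] = p.e_h
    dp[DP_GNMDA] = p.g_nmda
    dp[DP_GAMPA] = p.g_ampa
    dp[DP_EGLU] = p.e_glu
    dp[DP_GGABA] = p.g_gaba
    dp[DP_EGABA] = p.e_gaba
    dp[DP_ICONST] = p.i_const
    return dp


def pack_gaba_params(p) -> np.ndarray:
    gp = np.zeros(7)
    gp[GP_CM] = p.cm
    gp[GP_GNA] = p.g_na
    gp[GP_ENA] = p.e_na
    gp[GP_GK] = p.g_k
    gp[GP_EK] = p.e_k
    gp[GP_EL] = p.e_leak
    gp[GP_IBIAS] = p.i_bias
    return gp


def pack_receptor_params(p, g_max: float, dt: float) -> np.ndarray:
    rp = np.zeros(11)
    rp[RP_GMAX] = g_max
    rp[RP_EC50] = p.ec50
    rp[RP_IC50] = p.ic50
    rp[RP_KTAU] = p.k_tau
    rp[RP_W] = p.w
    rp[RP_NACT] = p.n_act
    rp[RP_NDES] = p.n_des
    rp[RP_ACTFAC] = np.exp(-dt / p.tau_act)
    rp[RP_TDBASE] = p.tau_des_base
    rp[RP_TDAMP] = p.tau_des_amp
    rp[RP_EREV] = p.e_rev
    return rp


@njit(cache=True, inline="always")
def _tab(tab, row, pos, frac):
    return tab[row, pos] + frac * (tab[row, pos + 1] - tab[row, pos])


@njit(cache=True, fastmath=True)
def run_circuit(
    n_steps, dt, record_stride, discard_steps,
    da_tab, gaba_tab,
    dp, gp, gl_arr, gatep, rp_da, rp_gaba,
    glu_counts, ach_counts, ach_amp_da, ach_amp_gaba, ach_fac_da, ach_fac_gb,
    nic_on, nic_off, nic_amp_norm, nic_fr, nic_fd,
    v_da0, ca0, h0, n0, q0, u0,
    v_g0, h_g0, n_g0,
    da_cap, gaba_cap,
):
    """Integrate the full circuit; returns spike times, accumulators, traces.

    Returns (status, t_fail, da_spk, n_da, g_spk_t, g_spk_id, n_gspk,
    mean_iach_da, mean_sgaba, traces).  status != 0 flags numeric blow-up
    at time t_fail.
    """
    n_gaba = gl_arr.size
    inv_dv = 1.0 / DV
    npts = da_tab.shape[1]

    # state
    v_da = v_da0
    ca = ca0
    h = h0
    n = n0
    q = q0
    u = u0
    v_g = v_g0.copy()
    h_g = h_g0.copy()
    n_g = n_g0.copy()
    s_gi = np.zeros(n_gaba)
    s_nmda = 0.0
    s_ampa = 0.0
    a_da = 0.0
    d_da = 0.0
    a_gb = 0.0
    d_gb = 0.0
    c_ach_da = 0.0
    c_ach_gb = 0.0
    er = 0.0
    ed = 0.0
    last_da = -1e9
    last_g = np.full(n_gaba, -1e9)

    da_spk = np.empty(da_cap)
    n_da = 0
    g_spk_t = np.empty(gaba_cap)
    g_spk_id = np.empty(gaba_cap, dtype=np.int32)
    n_gspk = 0

    n_rec = n_steps // record_stride + 1 if record_stride > 0 else 0
    traces = np.zeros((N_TRACE_CH, n_rec))
    i_rec = 0

    sum_iach = 0.0
    sum_sg = 0.0
    n_acc = 0

    status = 0
    t_fail = -1.0
    ca_fac = np.exp(-dt / dp[DP_TAUCA])

    for i in range(n_steps):
        t = i * dt

        # --- agonist concentrations ---
        c_ach_da *= ach_fac_da
        c_ach_gb *= ach_fac_gb
        k = ach_counts[i]
        if k > 0:
            c_ach_da += k * ach_amp_da
            c_ach_gb += k * ach_amp_gaba
        if nic_on <= i < nic_off:
            if i == nic_on:
                er = 1.0
                ed = 1.0
            er *= nic_fr
            ed *= nic_fd
            c_nic = nic_amp_norm * (ed - er)
            if c_nic < 0.0:
                c_nic = 0.0
        else:
            c_nic = 0.0

        # --- receptor pools ---
        for pool in range(2):
            rp = rp_da if pool == 0 else rp_gaba
            c_ach = c_ach_da if pool == 0 else c_ach_gb
            c_eff = c_ach + rp[RP_W] * c_nic
            if c_eff > 0.0:
                a_inf = 1.0 / (1.0 + (rp[RP_EC50] / c_eff) ** rp[RP_NACT])
            else:
                a_inf = 0.0
            if c_nic > 0.0:
                d_inf = 1.0 / (1.0 + (rp[RP_IC50] / c_nic) ** rp[RP_NDES])
                tau_d = rp[RP_TDBASE] + rp[RP_TDAMP] / (
                    1.0 + (c_nic / rp[RP_KTAU]) ** 3
                )
            else:
                d_inf = 0.0
                tau_d = rp[RP_TDBASE] + rp[RP_TDAMP]
            dfac = np.exp(-dt / tau_d)
            if pool == 0:
                a_da = a_inf + (a_da - a_inf) * rp[RP_ACTFAC]
                d_da = d_inf + (d_da - d_inf) * dfac
            else:
                a_gb = a_inf + (a_gb - a_inf) * rp[RP_ACTFAC]
                d_gb = d_inf + (d_gb - d_inf) * dfac

        g_ach_da = rp_da[RP_GMAX] * a_da * (1.0 - d_da)
        g_ach_gb = rp_gaba[RP_GMAX] * a_gb * (1.0 - d_gb)

        # --- glutamatergic gates ---
        s_nmda *= gatep[GT_NMDA_FAC]
        s_ampa *= gatep[GT_AMPA_FAC]
        kg = glu_counts[i]
        for _ in range(kg):
            s_nmda += gatep[GT_NMDA_INC] * (1.0 - s_nmda)
            s_ampa += gatep[GT_AMPA_INC] * (1.0 - s_ampa)

        # --- GABA population ---
        s_sum = 0.0
        for j in range(n_gaba):
            vj = v_g[j]
            pos_f = (vj - V_MIN) * inv_dv
            if pos_f < 0.0:
                pos_f = 0.0
            elif pos_f > npts - 2:
                pos_f = float(npts - 2)
            pos = int(pos_f)
            frac = pos_f - pos
            i_na = gp[GP_GNA] * _tab(gaba_tab, GB_MINF3, pos, frac) * h_g[j] * (
                gp[GP_ENA] - vj
            )
            nj = n_g[j]
            i_k = gp[GP_GK] * nj * nj * nj * nj * (gp[GP_EK] - vj)
            i_l = gl_arr[j] * (gp[GP_EL] - vj)
            i_ach = g_ach_gb * (rp_gaba[RP_EREV] - vj)
            v_new = vj + dt * (i_na + i_k + i_l + gp[GP_IBIAS] + i_ach) / gp[GP_CM]
            h_inf = _tab(gaba_tab, GB_HINF, pos, frac)
            h_g[j] = h_inf + (h_g[j] - h_inf) * _tab(gaba_tab, GB_HFAC, pos, frac)
            n_inf = _tab(gaba_tab, GB_NINF, pos, frac)
            n_g[j] = n_inf + (n_g[j] - n_inf) * _tab(gaba_tab, GB_NFAC, pos, frac)
            # spike detection + gate increment
            s_gi[j] *= gatep[GT_GABA_FAC]
            if (
                vj < SPIKE_THRESH <= v_new
                and t - last_g[j] > SPIKE_LOCKOUT
            ):
                last_g[j] = t
                if n_gspk < gaba_cap:
                    g_spk_t[n_gspk] = t
                    g_spk_id[n_gspk] = j
                    n_gspk += 1
                s_gi[j] += gatep[GT_GABA_INC] * (1.0 - s_gi[j])
            v_g[j] = v_new
            s_sum += s_gi[j]
        s_gaba = s_sum / n_gaba

        # --- DA neuron ---
        v = v_da
        pos_f = (v - V_MIN) * inv_dv
        if pos_f < 0.0:
            pos_f = 0.0
        elif pos_f > npts - 2:
            pos_f = float(npts - 2)
        pos = int(pos_f)
        frac = pos_f - pos
        i_ca = dp[DP_GCA] * _tab(da_tab, DA_MCA, pos, frac) * (dp[DP_ECA] - v)
        can = ca ** dp[DP_SKHILL]
        sk = can / (can + dp[DP_KSK] ** dp[DP_SKHILL])
        i_kca = dp[DP_GSK] * sk * (dp[DP_EK] - v)
        i_ks = dp[DP_GKS] * u * (dp[DP_EK] - v)
        i_dr = dp[DP_GDR] * n * n * n * (dp[DP_EK] - v)
        i_na = dp[DP_GNA] * _tab(da_tab, DA_MNA3, pos, frac) * h * (dp[DP_ENA] - v)
        i_sna = dp[DP_GSNA] * _tab(da_tab, DA_MSNA, pos, frac) * (dp[DP_ENA] - v)
        i_l = dp[DP_GL] * (dp[DP_EL] - v)
        i_h = dp[DP_GH] * q * (dp[DP_EH] - v)
        i_nmda = (
            dp[DP_GNMDA] * s_nmda * _tab(da_tab, DA_MGB, pos, frac)
            * (dp[DP_EGLU] - v)
        )
        i_ampa = dp[DP_GAMPA] * s_ampa * (dp[DP_EGLU] - v)
        i_gaba = dp[DP_GGABA] * s_gaba * (dp[DP_EGABA] - v)
        i_achda = g_ach_da * (rp_da[RP_EREV] - v)
        i_tot = (
            i_ca + i_kca + i_ks + i_dr + i_na + i_sna + i_l + i_h
            + i_nmda + i_ampa + i_gaba + i_achda + dp[DP_ICONST]
        )
        v_new = v + dt * i_tot / dp[DP_CM]
        # Ca: exponential-Euler toward influx/removal balance
        ca_inf = dp[DP_KCA] * i_ca * dp[DP_TAUCA]
        ca = ca_inf + (ca - ca_inf) * ca_fac
        if ca < 0.0:
            ca = 0.0
        h_inf = _tab(da_tab, DA_HINF, pos, frac)
        h = h_inf + (h - h_inf) * _tab(da_tab, DA_HFAC, pos, frac)
        n_inf = _tab(da_tab, DA_NINF, pos, frac)
        n = n_inf + (n - n_inf) * _tab(da_tab, DA_NFAC, pos, frac)
        q_inf = _tab(da_tab, DA_QINF, pos, frac)
        q = q_inf + (q - q_inf) * _tab(da_tab, DA_QFAC, pos, frac)
        u_inf = _tab(da_tab, DA_UINF, pos, frac)
        u = u_inf + (u - u_inf) * _tab(da_tab, DA_UFAC, pos, frac)
        if v < SPIKE_THRESH <= v_new and t - last_da > SPIKE_LOCKOUT:
            last_da = t
            if n_da < da_cap:
                da_spk[n_da] = t
                n_da += 1
        v_da = v_new

        if not (-200.0 < v_da < 200.0):
            status = 1
            t_fail = t
            break

        if i >= discard_steps:
            sum_iach += i_achda
            sum_sg += s_gaba
            n_acc += 1

        if record_stride > 0 and i % record_stride == 0:
            traces[0, i_rec] = t
            traces[1, i_rec] = v_da
            traces[2, i_rec] = ca
            traces[3, i_rec] = s_nmda
            traces[4, i_rec] = s_gaba
            traces[5, i_rec] = c_ach_da
            traces[6, i_rec] = c_nic
            traces[7, i_rec] = a_da
            traces[8, i_rec] = d_da
            traces[9, i_rec] = a_gb
            traces[10, i_rec] = d_gb
            traces[11, i_rec] = v_g[0]
            i_rec += 1

    mean_iach = sum_iach / n_acc if n_acc > 0 else 0.0
    mean_sg = sum_sg / n_acc if n_acc > 0 else 0.0
    return (
        status, t_fail,
        da_spk[:n_da].copy(), n_da,
        g_spk_t[:n_gspk].copy(), g_spk_id[:n_gspk].copy(), n_gspk,
        mean_iach, mean_sg,
        traces[:, :i_rec].copy(),
    )
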