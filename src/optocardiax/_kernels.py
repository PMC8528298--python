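"""Numba-compiled integration kernels.

The voltage-dependent gate kinetics and current factors of the CRN model are
tabulated on a fine V grid (0.05 mV) by evaluating the reference formulas in
:mod:`optocardiax.ionic_models`, so the fast path and the formula-level
reference share a single source of truth; the kernels interpolate linearly.
Gates use the Rush-Larsen exponential update, voltage / concentrations /
photocycle use forward Euler, all at a fixed dt.

State layout per node: 21 CRN states (see ionic_models.STATE_NAMES) plus 5
ChR2 states (O1, O2, C1, C2, p).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# fastmath without nnan/ninf: keeps NaN/Inf semantics so blow-up detection works
_FM = {"contract", "arcp", "nsz", "reassoc", "afn"}

from . import ionic_models as im
from .ionic_models import IonicParams
from .chr2 import ChR2Params

NA_O = im.NA_O
K_O = im.K_O
CA_O = im.CA_O

# voltage grid for the lookup tables
VMIN = -120.0
VMAX = 80.0
NV = 4001
DV = (VMAX - VMIN) / (NV - 1)

# gate ordering inside the tables = STATE_NAMES[1:12] + ("w",)
TAB_GATES = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")
N_TAB_GATES = len(TAB_GATES)

# rows of the current-factor table
# 0: I_K1 rectification, 1: g_Kur(V), 2: I_Kr rectification, 3: f_NaK,
# 4: exp(gamma V/RTF), 5: exp((gamma-1) V/RTF), 6: ChR2 G(V)*V numerator
N_CUR = 7


def build_tables(params: IonicParams, dt: float):
    """Tabulate gate inf / Rush-Larsen factors and V-dependent current factors."""
    V = np.linspace(VMIN, VMAX, NV)
    inf, tau = im.gate_inf_tau(V, params)
    # tables are stored voltage-major, (NV, n_cols), so one node's lookups
    # touch only a couple of contiguous cache lines
    inf_tab = np.empty((NV, N_TAB_GATES))
    rl_tab = np.empty((NV, N_TAB_GATES))
    for i, g in enumerate(TAB_GATES):
        inf_tab[:, i] = inf[g]
        rl_tab[:, i] = np.exp(-dt / tau[g])
    cur = np.empty((NV, N_CUR))
    cur[:, 0] = 1.0 / (1.0 + np.exp(0.07 * (V + 80.0)))
    cur[:, 1] = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    cur[:, 2] = 1.0 / (1.0 + np.exp((V + 15.0) / 22.4))
    sigma = (np.exp(im.NA_O / 67.3) - 1.0) / 7.0
    cur[:, 3] = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / im.RTF)
                       + 0.0365 * sigma * np.exp(-V / im.RTF))
    cur[:, 4] = np.exp(params.gamma_NaCa * V / im.RTF)
    cur[:, 5] = np.exp((params.gamma_NaCa - 1.0) * V / im.RTF)
    cur[:, 6] = 10.6408 - 14.6408 * np.exp(-V / 42.7671)
    return inf_tab, rl_tab, cur


def ionic_scalars(p: IonicParams) -> np.ndarray:
    return np.array([
        p.g_Na, p.g_K1_eff, p.g_to_eff, p.g_CaL_eff, p.g_Kr, p.g_Ks,
        p.g_bCa, p.g_bNa, p.i_NaK_max, p.i_NaCa_max, p.i_pCa_max,
        p.i_up_max, p.k_rel, p.K_up, p.Ca_up_max, p.K_mNai, p.K_mKo,
        p.K_mNa, p.K_mCa, p.k_sat, p.gamma_NaCa, p.C_m,
        # derived, hoisted out of the node loop:
        p.i_NaCa_max / ((p.K_mNa ** 3 + NA_O ** 3) * (p.K_mCa + CA_O)),
        p.i_NaK_max * K_O / (K_O + p.K_mKo),
    ])


def chr2_scalars(cp: ChR2Params) -> np.ndarray:
    return np.array([
        cp.g_ChR2, cp.gamma, cp.E_ChR2, cp.G_d1, cp.G_d2, cp.G_r,
        cp.eps1, cp.eps2, cp.tau_ChR2, cp.wavelength, cp.w_loss,
        cp.irradiance_unit_scale,
    ])


@njit(cache=True, fastmath=_FM, inline="always")
def _lk(tab, col, idx, frac):
    return tab[idx, col] * (1.0 - frac) + tab[idx + 1, col] * frac


@njit(cache=True, fastmath=_FM)
def _light_scalars(E_e, csc):
    """Per-step photo-transition scalars (F, e12, e21, S0) at irradiance E_e."""
    if E_e <= 0.0:
        S0 = 0.5 * (1.0 + np.tanh(-12.0))
        return 0.0, 0.0, 0.0, S0
    F = 6e-5 * (csc[11] * E_e) * csc[9] / csc[10]
    e12 = 0.011 + 0.005 * np.log(E_e / 0.024)
    e21 = 0.008 + 0.004 * np.log(E_e / 0.024)
    if e12 < 0.0:
        e12 = 0.0
    if e21 < 0.0:
        e21 = 0.0
    S0 = 0.5 * (1.0 + np.tanh(120.0 * (E_e - 0.1)))
    return F, e12, e21, S0


@njit(cache=True, fastmath=_FM, inline="always")
def _node_step(s, ch, ern, i, lap_i, istim, dt, inf_tab, rl_tab, cur_tab, sc,
               csc, F, e12, e21, S0, rl_fca, rl_u, gna_i):
    """Advance one node by dt; returns the updated membrane voltage."""
    V = s[i, 0]
    if V < VMIN:
        V = VMIN
    elif V > VMAX - DV:
        V = VMAX - DV
    x = (V - VMIN) / DV
    idx = int(x)
    frac = x - idx

    m = s[i, 1]; h = s[i, 2]; j = s[i, 3]
    oa = s[i, 4]; oi = s[i, 5]; ua = s[i, 6]; ui = s[i, 7]
    xr = s[i, 8]; xs = s[i, 9]
    d = s[i, 10]; f = s[i, 11]; fca = s[i, 12]
    u = s[i, 13]; v = s[i, 14]; w = s[i, 15]
    Nai = s[i, 16]; Ki = s[i, 17]; Cai = s[i, 18]
    Caup = s[i, 19]; Carel = s[i, 20]
    Vm = s[i, 0]

    E_Na = ern[i, 0]
    E_K = ern[i, 1]
    E_Ca = ern[i, 2]

    I_Na = gna_i * sc[0] * m * m * m * h * j * (Vm - E_Na)
    I_K1 = sc[1] * (Vm - E_K) * _lk(cur_tab, 0, idx, frac)
    I_to = sc[2] * oa * oa * oa * oi * (Vm - E_K)
    I_Kur = _lk(cur_tab, 1, idx, frac) * ua * ua * ua * ui * (Vm - E_K)
    I_Kr = sc[4] * xr * (Vm - E_K) * _lk(cur_tab, 2, idx, frac)
    I_Ks = sc[5] * xs * xs * (Vm - E_K)
    I_CaL = sc[3] * d * f * fca * (Vm - 65.0)
    rat = sc[15] / Nai
    nak_na = 1.0 + rat * np.sqrt(rat)
    I_NaK = sc[23] * _lk(cur_tab, 3, idx, frac) / nak_na
    eg = _lk(cur_tab, 4, idx, frac)
    egm = _lk(cur_tab, 5, idx, frac)
    I_NaCa = sc[22] * (eg * Nai * Nai * Nai * CA_O
                       - egm * (NA_O * NA_O * NA_O) * Cai) / (1.0 + sc[19] * egm)
    I_pCa = sc[10] * Cai / (0.0005 + Cai)
    I_bNa = sc[7] * (Vm - E_Na)
    I_bCa = sc[6] * (Vm - E_Ca)

    I_rel = sc[12] * u * u * v * w * (Carel - Cai)
    I_up = sc[11] / (1.0 + sc[13] / Cai)
    I_upleak = sc[11] * Caup / sc[14]
    I_tr = (Caup - Carel) / 180.0

    I_ion = (I_Na + I_K1 + I_to + I_Kur + I_Kr + I_Ks + I_CaL + I_pCa
             + I_NaK + I_NaCa + I_bNa + I_bCa)

    # ChR2 photocurrent (density pA/pF); E_ChR2 = 0 uses the exact
    # singularity-free product G(V)*V
    O1 = ch[i, 0]; O2 = ch[i, 1]; C1 = ch[i, 2]; C2 = ch[i, 3]; pch = ch[i, 4]
    I_chr2 = 0.0
    if csc[0] > 0.0:
        drive = _lk(cur_tab, 6, idx, frac)
        if csc[2] != 0.0:
            Vsafe = Vm if abs(Vm) > 1e-9 else 1e-9
            drive = drive * (Vm - csc[2]) / Vsafe
        I_chr2 = csc[0] * (O1 + csc[1] * O2) * drive

    # voltage and concentration (forward Euler)
    Vnew = Vm + dt * (lap_i - I_ion - I_chr2 + istim)
    s[i, 0] = Vnew

    cm_vf = sc[21] / (im.V_I * im.FARADAY)
    s[i, 16] = Nai + dt * (-3.0 * I_NaK - (3.0 * I_NaCa + I_bNa + I_Na)) * cm_vf
    s[i, 17] = Ki + dt * (2.0 * I_NaK - (I_K1 + I_to + I_Kur + I_Kr + I_Ks)) * cm_vf
    B1 = (2.0 * I_NaCa - (I_pCa + I_CaL + I_bCa)) * sc[21] / (
        2.0 * im.V_I * im.FARADAY
    ) + (im.V_UP * (I_upleak - I_up) + I_rel * im.V_REL) / im.V_I
    B2 = (1.0 + im.TRPN_MAX * im.KM_TRPN / (Cai + im.KM_TRPN) ** 2
          + im.CMDN_MAX * im.KM_CMDN / (Cai + im.KM_CMDN) ** 2)
    s[i, 18] = Cai + dt * B1 / B2
    s[i, 19] = Caup + dt * (I_up - (I_upleak + I_tr * im.V_REL / im.V_UP))
    s[i, 20] = Carel + dt * (I_tr - I_rel) / (
        1.0 + im.CSQN_MAX * im.KM_CSQN / (Carel + im.KM_CSQN) ** 2)

    # Rush-Larsen gate updates (tables evaluated at the pre-step V)
    for g in range(12):
        gi = 1 + g if g < 11 else 15  # table row 11 is the w gate (state 15)
        ginf = _lk(inf_tab, g, idx, frac)
        grl = _lk(rl_tab, g, idx, frac)
        s[i, gi] = ginf + (s[i, gi] - ginf) * grl

    fca_inf = 1.0 / (1.0 + Cai / 0.00035)
    s[i, 12] = fca_inf + (fca - fca_inf) * rl_fca

    Fn = 1e-12 * im.V_REL * I_rel - (5e-13 / im.FARADAY) * (
        0.5 * I_CaL * sc[21] - 0.2 * I_NaCa * sc[21])
    a1 = -(Fn - 3.4175e-13) / 1.367e-15
    if a1 > 500.0:
        a1 = 500.0
    a2 = -(Fn - 6.835e-14) / 1.367e-15
    if a2 > 500.0:
        a2 = 500.0
    efn = np.exp(a1)
    u_inf = 1.0 / (1.0 + efn)
    tau_v = 1.91 + 2.09 / (1.0 + efn)
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(a2))
    s[i, 13] = u_inf + (u - u_inf) * rl_u
    # dt/tau_v <= 0.011: second-order expansion of exp(-dt/tau_v)
    xv = dt / tau_v
    s[i, 14] = v_inf + (v - v_inf) * (1.0 - xv + 0.5 * xv * xv)

    # ChR2 photocycle (forward Euler, conservative)
    k1 = csc[6] * F * pch
    k2 = csc[7] * F * pch
    dO1 = k1 * C1 - (csc[3] + e12) * O1 + e21 * O2
    dO2 = k2 * C2 - (csc[4] + e21) * O2 + e12 * O1
    dC1 = csc[5] * C2 + csc[3] * O1 - k1 * C1
    dC2 = csc[4] * O2 - (k2 + csc[5]) * C2
    O1 += dt * dO1; O2 += dt * dO2; C1 += dt * dC1; C2 += dt * dC2
    if O1 < 0.0: O1 = 0.0
    if O2 < 0.0: O2 = 0.0
    if C1 < 0.0: C1 = 0.0
    if C2 < 0.0: C2 = 0.0
    tot = O1 + O2 + C1 + C2
    ch[i, 0] = O1 / tot; ch[i, 1] = O2 / tot
    ch[i, 2] = C1 / tot; ch[i, 3] = C2 / tot
    ch[i, 4] = pch + dt * (S0 - pch) / csc[8]
    return Vnew


@njit(cache=True, fastmath=_FM)
def _run_coupled(s, ch, nbr, lapfac, dt, stim_series, stim_mask, ee_series,
                 ee_mask, inf_tab, rl_tab, cur_tab, sc, csc, gna_scale,
                 trace_idx, trace_every, traces, frame_every, frames,
                 step0):
    """Advance the coupled reaction-diffusion system over len(stim_series) steps.

    Returns (status, node): status 0 = ok, 1 = voltage out of range / NaN at
    `node`.  ``lapfac`` = D*dt/dx^2 premultiplied into the stencil; set to 0
    for uncoupled (0D-per-node) runs.  Recording: V at trace_idx nodes every
    trace_every steps; full V field every frame_every steps (0 disables).
    """
    n = s.shape[0]
    n_steps = stim_series.shape[0]
    lap = np.empty(n)
    ern = np.empty((n, 3))
    rl_fca = np.exp(-dt / 2.0)
    rl_u = np.exp(-dt / 8.0)
    dfac = lapfac / dt if dt > 0.0 else 0.0  # = D/dx^2
    nernst_every = 25  # refresh reversal potentials every 0.5 ms at dt = 0.02
    for step in range(n_steps):
        if step % nernst_every == 0:
            for i in range(n):
                ern[i, 0] = im.RTF * np.log(NA_O / s[i, 16])
                ern[i, 1] = im.RTF * np.log(K_O / s[i, 17])
                ern[i, 2] = 0.5 * im.RTF * np.log(CA_O / s[i, 18])
        if lapfac > 0.0:
            for i in range(n):
                vi = s[i, 0]
                lap[i] = (s[nbr[i, 0], 0] + s[nbr[i, 1], 0]
                          + s[nbr[i, 2], 0] + s[nbr[i, 3], 0] - 4.0 * vi)
        else:
            for i in range(n):
                lap[i] = 0.0
        amp = stim_series[step]
        Ee = ee_series[step]
        F_on, e12_on, e21_on, S0_on = _light_scalars(Ee, csc)
        F_off, e12_off, e21_off, S0_off = _light_scalars(0.0, csc)
        bad = -1
        for i in range(n):
            if Ee > 0.0 and ee_mask[i] != 0.0:
                F = F_on; e12 = e12_on; e21 = e21_on; S0 = S0_on
            else:
                F = F_off; e12 = e12_off; e21 = e21_off; S0 = S0_off
            vnew = _node_step(s, ch, ern, i, dfac * lap[i], amp * stim_mask[i],
                              dt, inf_tab, rl_tab, cur_tab, sc, csc,
                              F, e12, e21, S0, rl_fca, rl_u, gna_scale[i])
            if not (-150.0 < vnew < 150.0):
                bad = i
        if bad >= 0:
            return 1, bad
        gstep = step0 + step + 1
        if trace_every > 0 and gstep % trace_every == 0:
            r = (gstep // trace_every) - 1
            if 0 <= r < traces.shape[1]:
                for k in range(trace_idx.shape[0]):
                    traces[k, r] = s[trace_idx[k], 0]
        if frame_every > 0 and gstep % frame_every == 0:
            r = (gstep // frame_every) - 1
            if 0 <= r < frames.shape[0]:
                for i in range(n):
                    frames[r, i] = s[i, 0]
    return 0, -1


def run_zero_d(cell: np.ndarray, ch: np.ndarray, params: IonicParams,
               chr2_params: ChR2Params, dt: float,
               stim_series: np.ndarray, ee_series: np.ndarray,
               record_every: int = 0):
    """Integrate a single cell in place; optionally return a V trace.

    ``stim_series`` / ``ee_series`` give the injected current (pA/pF) and
    irradiance (mW/mm^2) at every step.
    """
    inf_tab, rl_tab, cur_tab = build_tables(params, dt)
    sc = ionic_scalars(params)
    csc = chr2_scalars(chr2_params)
    n_steps = len(stim_series)
    s = cell.reshape(1, -1)
    c = ch.reshape(1, -1)
    nbr = np.zeros((1, 4), dtype=np.int64)
    tidx = np.zeros(1, dtype=np.int64)
    if record_every > 0:
        n_rec = n_steps // record_every
        traces = np.empty((1, n_rec))
    else:
        traces = np.empty((1, 0))
    frames = np.empty((0, 1), dtype=np.float32)
    status, node = _run_coupled(
        s, c, nbr, 0.0, dt, np.asarray(stim_series, float),
        np.ones(1), np.asarray(ee_series, float), np.ones(1),
        inf_tab, rl_tab, cur_tab, sc, csc, np.ones(1), tidx,
        record_every, traces, 0, frames, 0)
    if status != 0:
        raise FloatingPointError("0D integration blew up")
    if record_every > 0:
        t = (np.arange(1, traces.shape[1] + 1)) * record_every * dt
        return t, traces[0]
    return None
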