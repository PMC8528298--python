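"""Courtemanche–Ramirez–Nattel (CRN) human atrial membrane kinetics.

The CRN model describes the action potential of a human atrial myocyte as the
sum of 12 sarcolemmal currents (I_Na, I_K1, I_to, I_Kur, I_Kr, I_Ks, I_CaL,
I_pCa, I_NaK, I_NaCa, I_bNa, I_bCa) together with intracellular Na+/K+/Ca2+
handling (SR uptake, release and transfer).  Two parameter sets are provided:

* ``make_healthy_params`` — the published 1998 parameterisation with the
  inward-rectifier conductance raised from 0.09 to 0.117 nS/pF, which tunes the
  1 Hz APD90 of the working atrial myocardium to ~284 ms;
* ``make_caf_params`` — a chronic-atrial-fibrillation (cAF) remodelling recipe
  layered on top of the healthy set: I_to and I_CaL maximal conductances
  reduced by 85% and 74%, G_K1 increased by 250%, the I_CaL activation time
  constant slowed by 62%, the I_to and I_CaL activation curves shifted by
  +16 mV and −5.4 mV, and the I_Na inactivation curve shifted by +1.6 mV.

All modifiers are explicit fields of :class:`IonicParams` so that alternative
remodelling recipes are one-line changes.  Voltage shifts act on the
steady-state (in)activation curves only; time constants are untouched except
for the explicit I_CaL tau scaling.

This module is the formula-level source of truth: the fast tissue kernels in
:mod:`optocardiax._kernels` tabulate the functions defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Union

import numpy as np

__all__ = [
    "CellState",
    "IonicParams",
    "make_healthy_params",
    "make_caf_params",
    "ionic_derivatives",
    "compute_currents",
    "gate_inf_tau",
    "initial_state",
    "equilibrate_rest",
    "STATE_NAMES",
    "N_STATE",
]

# physical constants
R_GAS = 8.3143          # J/(mol K)
TEMP = 310.0            # K
FARADAY = 96.4867       # C/mmol
RTF = R_GAS * TEMP / FARADAY

# cell geometry / capacitance
CM_PF = 100.0           # membrane capacitance, pF
V_CELL = 20100.0        # cell volume, um^3
V_I = 13668.0           # intracellular (myoplasmic) volume
V_UP = 1109.52          # SR uptake compartment volume
V_REL = 96.48           # SR release compartment volume

# fixed external concentrations (mM)
K_O = 5.4
NA_O = 140.0
CA_O = 1.8

# buffering
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8

K_Q10 = 3.0
TAU_TR = 180.0
TAU_U = 8.0
TAU_F_CA = 2.0

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "f_Ca", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel",
)
N_STATE = len(STATE_NAMES)

# CRN published initial conditions (quiescent cell)
_INIT = np.array([
    -81.18,        # V (mV)
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # f_Ca
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    11.17,         # Na_i (mM)
    139.0,         # K_i
    1.013e-4,      # Ca_i
    1.488,         # Ca_up
    1.488,         # Ca_rel
])


@dataclass
class CellState:
    """State of one CRN node: voltage, 15 gates, 5 concentrations."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-1] != N_STATE:
            raise ValueError(f"CellState needs {N_STATE} entries, got {self.values.shape}")

    def __getattr__(self, name):
        try:
            idx = STATE_NAMES.index(name)
        except ValueError:
            raise AttributeError(name) from None
        return self.values[..., idx]

    def copy(self) -> "CellState":
        return CellState(self.values.copy())

    def as_array(self) -> np.ndarray:
        return self.values


@dataclass
class IonicParams:
    """CRN maximal conductances (nS/pF) plus remodelling modifiers.

    ``g_K1`` is the *baseline* inward-rectifier conductance; the effective
    value used in the equations is ``g_K1 * gk1_scale``.
    """

    name: str = "healthy"
    g_Na: float = 7.8
    g_K1: float = 0.117
    g_to: float = 0.1652
    g_Kr: float = 0.029411765
    g_Ks: float = 0.12941176
    g_CaL: float = 0.12375
    g_bCa: float = 0.001131
    g_bNa: float = 0.0006744375
    i_NaK_max: float = 0.59933874
    i_NaCa_max: float = 1600.0
    i_pCa_max: float = 0.275
    i_up_max: float = 0.005
    k_rel: float = 30.0
    K_up: float = 0.00092
    Ca_up_max: float = 15.0
    K_mNai: float = 10.0
    K_mKo: float = 1.5
    K_mNa: float = 87.5
    K_mCa: float = 1.38
    k_sat: float = 0.1
    gamma_NaCa: float = 0.35
    C_m: float = CM_PF
    # remodelling modifiers (identity for the healthy cell)
    gto_scale: float = 1.0
    gcal_scale: float = 1.0
    gk1_scale: float = 1.0
    tau_d_scale: float = 1.0
    shift_oa_act: float = 0.0      # mV shift of the I_to activation curve
    shift_d_act: float = 0.0       # mV shift of the I_CaL activation curve
    shift_na_inact: float = 0.0    # mV shift of the I_Na inactivation curve

    def __post_init__(self):
        for nm in ("g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL", "g_bCa", "g_bNa"):
            if getattr(self, nm) < 0:
                raise ValueError(f"conductance {nm} must be >= 0")
        for nm in ("gto_scale", "gcal_scale", "gk1_scale", "tau_d_scale"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"scale factor {nm} must be > 0")

    # effective conductances with modifiers applied
    @property
    def g_to_eff(self) -> float:
        return self.g_to * self.gto_scale

    @property
    def g_CaL_eff(self) -> float:
        return self.g_CaL * self.gcal_scale

    @property
    def g_K1_eff(self) -> float:
        return self.g_K1 * self.gk1_scale

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IonicParams":
        return cls(**d)


def make_healthy_params(**overrides) -> IonicParams:
    """Healthy human atrial parameter set (G_K1 = 0.117 nS/pF, no modifiers)."""
    return IonicParams(name="healthy", **overrides)


def make_caf_params(**overrides) -> IonicParams:
    """Chronic-AF remodelled parameter set.

    G_to x0.15, G_CaL x0.26, G_K1 x3.5 (a 250% increase over the healthy
    baseline), I_CaL activation tau x1.62, I_to activation shifted +16 mV,
    I_CaL activation shifted -5.4 mV, I_Na inactivation shifted +1.6 mV.
    """
    base = dict(
        name="caf",
        gto_scale=0.15,
        gcal_scale=0.26,
        gk1_scale=3.5,
        tau_d_scale=1.62,
        shift_oa_act=16.0,
        shift_d_act=-5.4,
        shift_na_inact=1.6,
    )
    base.update(overrides)
    return IonicParams(**base)


def initial_state(n: int | None = None) -> CellState:
    """CRN published initial conditions; stacked ``n`` times if requested."""
    if n is None:
        return CellState(_INIT.copy())
    return CellState(np.tile(_INIT, (n, 1)))


# ---------------------------------------------------------------------------
# gate kinetics
# ---------------------------------------------------------------------------

def _safe_div(num, den, limit):
    """num/den with a supplied removable-singularity limit where den == 0."""
    den = np.asarray(den, dtype=float)
    num = np.asarray(num, dtype=float)
    tiny = np.abs(den) < 1e-12
    out = np.where(tiny, limit, num / np.where(tiny, 1.0, den))
    return out


def _na_alpha_beta(V):
    V = np.asarray(V, dtype=float)
    a_m = _safe_div(0.32 * (V + 47.13), 1.0 - np.exp(-0.1 * (V + 47.13)), 3.2)
    b_m = 0.08 * np.exp(-V / 11.0)
    low = V < -40.0
    a_h = np.where(low, 0.135 * np.exp(-(V + 80.0) / 6.8), 0.0)
    b_h = np.where(
        low,
        3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
        1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))),
    )
    a_j = np.where(
        low,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    b_j = np.where(
        low,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    return a_m, b_m, a_h, b_h, a_j, b_j


def gate_inf_tau(V, p: IonicParams):
    """Steady states and time constants of the 12 voltage-dependent gates.

    Returns ``(inf, tau)`` dicts keyed by gate name.  Remodelling shifts enter
    the steady-state curves only (V replaced by V − shift); time constants are
    evaluated at the unshifted V, with the I_CaL activation tau additionally
    scaled by ``tau_d_scale``.
    """
    V = np.asarray(V, dtype=float)
    inf, tau = {}, {}

    a_m, b_m, a_h, b_h, a_j, b_j = _na_alpha_beta(V)
    inf["m"] = a_m / (a_m + b_m)
    tau["m"] = 1.0 / (a_m + b_m)
    tau["h"] = 1.0 / (a_h + b_h)
    tau["j"] = 1.0 / (a_j + b_j)
    # inactivation steady state from shifted V, tau from unshifted V
    Vs = V - p.shift_na_inact
    _, _, a_hs, b_hs, a_js, b_js = _na_alpha_beta(Vs)
    inf["h"] = a_hs / (a_hs + b_hs)
    inf["j"] = a_js / (a_js + b_js)

    # I_to gates
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    tau["oa"] = 1.0 / ((a_oa + b_oa) * K_Q10)
    inf["oa"] = 1.0 / (1.0 + np.exp(-((V - p.shift_oa_act) + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    tau["oi"] = 1.0 / ((a_oi + b_oi) * K_Q10)
    inf["oi"] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))

    # I_Kur gates
    a_ua = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    tau["ua"] = 1.0 / ((a_ua + b_ua) * K_Q10)
    inf["ua"] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    tau["ui"] = 1.0 / ((a_ui + b_ui) * K_Q10)
    inf["ui"] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))

    # delayed rectifiers
    a_xr = _safe_div(0.0003 * (V + 14.1), 1.0 - np.exp(-(V + 14.1) / 5.0), 0.0015)
    b_xr = _safe_div(
        7.3898e-5 * (V - 3.3328), np.exp((V - 3.3328) / 5.1237) - 1.0, 3.7836118e-4
    )
    tau["xr"] = 1.0 / (a_xr + b_xr)
    inf["xr"] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    a_xs = _safe_div(4e-5 * (V - 19.9), 1.0 - np.exp(-(V - 19.9) / 17.0), 0.00068)
    b_xs = _safe_div(3.5e-5 * (V - 19.9), np.exp((V - 19.9) / 9.0) - 1.0, 0.000315)
    tau["xs"] = 0.5 / (a_xs + b_xs)
    inf["xs"] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))

    # I_CaL gates
    Vd = V - p.shift_d_act
    inf["d"] = 1.0 / (1.0 + np.exp(-(Vd + 10.0) / 8.0))
    e_d = np.exp(-(V + 10.0) / 6.24)
    tau["d"] = p.tau_d_scale * _safe_div(
        1.0 - e_d, 0.035 * (V + 10.0) * (1.0 + e_d), 4.579 / (1.0 + 1.0)
    )
    inf["f"] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau["f"] = 9.0 / (0.0197 * np.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)

    # SR release voltage gate
    e_w = np.exp(-(V - 7.9) / 5.0)
    tau["w"] = _safe_div(
        6.0 * (1.0 - e_w), (1.0 + 0.3 * e_w) * (V - 7.9), 6.0 * 0.2 / 1.3
    )
    inf["w"] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    return inf, tau


# ---------------------------------------------------------------------------
# currents and derivatives
# ---------------------------------------------------------------------------

def compute_currents(state: Union[CellState, np.ndarray], p: IonicParams) -> dict:
    """All 12 CRN currents (pA/pF) plus SR fluxes (mM/ms) for a state."""
    s = state.as_array() if isinstance(state, CellState) else np.asarray(state, float)
    V = s[..., 0]
    m, h, j = s[..., 1], s[..., 2], s[..., 3]
    oa, oi, ua, ui = s[..., 4], s[..., 5], s[..., 6], s[..., 7]
    xr, xs = s[..., 8], s[..., 9]
    d, f, f_Ca = s[..., 10], s[..., 11], s[..., 12]
    u, v, w = s[..., 13], s[..., 14], s[..., 15]
    Na_i, K_i, Ca_i = s[..., 16], s[..., 17], s[..., 18]
    Ca_up, Ca_rel = s[..., 19], s[..., 20]

    E_Na = RTF * np.log(NA_O / Na_i)
    E_K = RTF * np.log(K_O / K_i)
    E_Ca = 0.5 * RTF * np.log(CA_O / Ca_i)

    out = {}
    out["I_Na"] = p.g_Na * m ** 3 * h * j * (V - E_Na)
    out["I_K1"] = p.g_K1_eff * (V - E_K) / (1.0 + np.exp(0.07 * (V + 80.0)))
    out["I_to"] = p.g_to_eff * oa ** 3 * oi * (V - E_K)
    g_Kur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    out["I_Kur"] = g_Kur * ua ** 3 * ui * (V - E_K)
    out["I_Kr"] = p.g_Kr * xr * (V - E_K) / (1.0 + np.exp((V + 15.0) / 22.4))
    out["I_Ks"] = p.g_Ks * xs ** 2 * (V - E_K)
    out["I_CaL"] = p.g_CaL_eff * d * f * f_Ca * (V - 65.0)

    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    f_NaK = 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * V / RTF) + 0.0365 * sigma * np.exp(-V / RTF)
    )
    out["I_NaK"] = (
        p.i_NaK_max * f_NaK * (1.0 / (1.0 + (p.K_mNai / Na_i) ** 1.5))
        * K_O / (K_O + p.K_mKo)
    )
    eg = np.exp(p.gamma_NaCa * V / RTF)
    egm = np.exp((p.gamma_NaCa - 1.0) * V / RTF)
    out["I_NaCa"] = (
        p.i_NaCa_max
        * (eg * Na_i ** 3 * CA_O - egm * NA_O ** 3 * Ca_i)
        / ((p.K_mNa ** 3 + NA_O ** 3) * (p.K_mCa + CA_O) * (1.0 + p.k_sat * egm))
    )
    out["I_pCa"] = p.i_pCa_max * Ca_i / (0.0005 + Ca_i)
    out["I_bNa"] = p.g_bNa * (V - E_Na)
    out["I_bCa"] = p.g_bCa * (V - E_Ca)

    out["I_rel"] = p.k_rel * u ** 2 * v * w * (Ca_rel - Ca_i)
    out["I_up"] = p.i_up_max / (1.0 + p.K_up / Ca_i)
    out["I_up_leak"] = p.i_up_max * Ca_up / p.Ca_up_max
    out["I_tr"] = (Ca_up - Ca_rel) / TAU_TR

    out["I_ion"] = (
        out["I_Na"] + out["I_K1"] + out["I_to"] + out["I_Kur"] + out["I_Kr"]
        + out["I_Ks"] + out["I_CaL"] + out["I_pCa"] + out["I_NaK"]
        + out["I_NaCa"] + out["I_bNa"] + out["I_bCa"]
    )
    return out


def ionic_derivatives(
    state: Union[CellState, np.ndarray], p: IonicParams, I_inject: float = 0.0
) -> np.ndarray:
    """Time derivatives of the full CRN state vector.

    ``I_inject`` (pA/pF, positive = depolarising) adds to the voltage equation
    only.  Raises on non-finite input, which signals numerical blow-up.
    """
    s = state.as_array() if isinstance(state, CellState) else np.asarray(state, float)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite cell state (numerical blow-up?)")
    V = s[..., 0]
    cur = compute_currents(s, p)
    inf, tau = gate_inf_tau(V, p)

    ds = np.empty_like(s)
    ds[..., 0] = -cur["I_ion"] + I_inject

    for k, name in enumerate(STATE_NAMES[1:12], start=1):  # m..f (V gates)
        ds[..., k] = (inf[name] - s[..., k]) / tau[name]

    Ca_i = s[..., 18]
    f_Ca_inf = 1.0 / (1.0 + Ca_i / 0.00035)
    ds[..., 12] = (f_Ca_inf - s[..., 12]) / TAU_F_CA

    # SR release gating driven by Fn (whole-cell currents in pA)
    Fn = 1e-12 * V_REL * cur["I_rel"] - (5e-13 / FARADAY) * (
        0.5 * cur["I_CaL"] * p.C_m - 0.2 * cur["I_NaCa"] * p.C_m
    )
    u_inf = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 1.367e-15))
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 1.367e-15))
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 1.367e-15))
    ds[..., 13] = (u_inf - s[..., 13]) / TAU_U
    ds[..., 14] = (v_inf - s[..., 14]) / tau_v
    ds[..., 15] = (inf["w"] - s[..., 15]) / tau["w"]

    cm_vf = p.C_m / (V_I * FARADAY)
    ds[..., 16] = (-3.0 * cur["I_NaK"] - (3.0 * cur["I_NaCa"] + cur["I_bNa"] + cur["I_Na"])) * cm_vf
    ds[..., 17] = (2.0 * cur["I_NaK"] - (cur["I_K1"] + cur["I_to"] + cur["I_Kur"]
                                         + cur["I_Kr"] + cur["I_Ks"])) * cm_vf
    B1 = (2.0 * cur["I_NaCa"] - (cur["I_pCa"] + cur["I_CaL"] + cur["I_bCa"])) * p.C_m / (
        2.0 * V_I * FARADAY
    ) + (V_UP * (cur["I_up_leak"] - cur["I_up"]) + cur["I_rel"] * V_REL) / V_I
    B2 = (
        1.0
        + TRPN_MAX * KM_TRPN / (Ca_i + KM_TRPN) ** 2
        + CMDN_MAX * KM_CMDN / (Ca_i + KM_CMDN) ** 2
    )
    ds[..., 18] = B1 / B2
    Ca_up, Ca_rel = s[..., 19], s[..., 20]
    ds[..., 19] = cur["I_up"] - (cur["I_up_leak"] + cur["I_tr"] * V_REL / V_UP)
    ds[..., 20] = (cur["I_tr"] - cur["I_rel"]) / (
        1.0 + CSQN_MAX * KM_CSQN / (Ca_rel + KM_CSQN) ** 2
    )
    return ds


def equilibrate_rest(params: IonicParams, duration: float = 10_000.0,
                     dt: float = 0.02, tol: float = 1e-3) -> CellState:
    """Quiescent 0D integration from the published initial conditions.

    Returns the settled state; raises if |dV/dt| has not fallen below ``tol``
    (mV/ms) by the end of ``duration`` (ms).
    """
    if duration < 1000.0:
        raise ValueError("equilibration needs at least 1000 ms")
    from ._kernels import run_zero_d

    n_steps = int(round(duration / dt))
    zeros = np.zeros(n_steps)
    s = initial_state().as_array().copy()
    ch = np.array([0.0, 0.0, 1.0, 0.0, 0.0])  # dark-adapted ChR2, unused here
    from .chr2 import ChR2Params

    run_zero_d(s, ch, params, ChR2Params(g_ChR2=0.0), dt, zeros, zeros)
    dv = ionic_derivatives(s, params)[0]
    if abs(dv) > tol:
        raise RuntimeError(f"cell failed to settle: |dV/dt| = {abs(dv):.3g} mV/ms")
    return CellState(s)
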