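"""Hybrid four-state channelrhodopsin-2 (ChR2) photocycle model.

ChR2 is modelled as two closed states (C1 dark-adapted, C2 light-adapted) and
two open states (O1, O2) with light-driven openings C1->O1 (rate k1) and
C2->O2 (k2), open-state interconversion e12/e21, closures G_d1/G_d2 and slow
thermal recovery C2->C1 (G_r).  A light-adaptation variable p relaxes toward a
steeply irradiance-dependent target S0(E_e), which makes the sub/supra
threshold boundary of the channel sharp near E_e ~ 0.1 mW/mm^2.  Voltage
sensitivity is confined to the empirical inward rectification G(V) of the
conductance; the kinetic rates are voltage independent.

Units: irradiance E_e in mW/mm^2, rates in 1/ms, conductance in mS/cm^2.
With a specific membrane capacitance of 1 uF/cm^2 the photocurrent density
(mS/cm^2 x mV = uA/cm^2) is numerically equal to pA/pF, the unit of the host
ionic model.

Note on the photon flux: the flux entering k1 and k2 is
``F = 6e-5 * (unit_scale * E_e) * lambda / w_loss`` per ms.  The constant
6e-5 originates from the retinal photon-capture cross-section divided by the
photon energy at wavelength lambda, which fixes the irradiance unit inside
this formula; ``irradiance_unit_scale`` (default 100, i.e. E_e quoted in
mW/mm^2 converted to mW/cm^2) is exposed because this choice, not the printed
constant, sets the absolute current scale.  The default is the only reading
consistent with a stimulation threshold near 0.095 mW/mm^2 together with
sub-threshold APD/CV modulation at 0.085-0.092 mW/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ChR2State",
    "ChR2Params",
    "rectification_times_driving",
    "photo_rates",
    "chr2_derivatives",
    "chr2_current",
    "step_chr2",
    "dark_state",
    "CHR2_STATE_NAMES",
]

CHR2_STATE_NAMES = ("O1", "O2", "C1", "C2", "p")

# irradiance floor used only to evaluate the logarithmic e12/e21 expressions
# in the dark (the rates are irrelevant when the channel is closed)
_EE_FLOOR = 1e-10


@dataclass
class ChR2State:
    """Photocycle occupancies (O1+O2+C1+C2 = 1) and light adaptation p."""

    O1: float = 0.0
    O2: float = 0.0
    C1: float = 1.0
    C2: float = 0.0
    p: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.O1, self.O2, self.C1, self.C2, self.p])

    @classmethod
    def from_array(cls, a) -> "ChR2State":
        return cls(*np.asarray(a, dtype=float))


def dark_state() -> ChR2State:
    """Dark-adapted initial condition: all channels in C1, p = 0."""
    return ChR2State()


@dataclass
class ChR2Params:
    g_ChR2: float = 0.17        # mS/cm^2
    gamma: float = 0.1          # O2/O1 conductance ratio
    E_ChR2: float = 0.0         # mV
    G_d1: float = 0.1           # 1/ms
    G_d2: float = 0.05          # 1/ms
    G_r: float = 0.004          # 1/ms
    eps1: float = 0.8535        # quantum efficiency factor of k1
    eps2: float = 0.14          # quantum efficiency factor of k2
    tau_ChR2: float = 1.3       # ms, relaxation of p
    wavelength: float = 470.0   # nm
    w_loss: float = 1.3         # photon-loss scaling
    irradiance_unit_scale: float = 100.0  # mW/mm^2 -> unit used in the flux formula
    S_cell: float = np.pi * 16e-4 * 100e-4  # lateral surface of a 100x16 um cylinder, cm^2
    C_m: float = 1.0            # uF/cm^2

    def __post_init__(self):
        for nm in ("G_d1", "G_d2", "G_r", "tau_ChR2", "S_cell", "C_m", "w_loss"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.g_ChR2 < 0:
            raise ValueError("g_ChR2 must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChR2Params":
        return cls(**d)


def rectification_times_driving(V, E_ChR2: float = 0.0):
    """The product G(V) * (V - E_ChR2) of the empirical rectifier.

    G(V) = (10.6408 - 14.6408 exp(-V/42.7671)) / V has a removable pole at
    V = 0; with the default E_ChR2 = 0 the product reduces exactly to the
    numerator and is finite everywhere.
    """
    V = np.asarray(V, dtype=float)
    num = 10.6408 - 14.6408 * np.exp(-V / 42.7671)
    if E_ChR2 == 0.0:
        out = num
    else:
        Vsafe = np.where(np.abs(V) < 1e-9, 1e-9, V)
        out = num * (V - E_ChR2) / Vsafe
    return out if out.ndim else float(out)


def photo_rates(E_e, p, params: ChR2Params) -> dict:
    """Light-dependent transition rates {k1, k2, e12, e21, S0, F} at E_e, p."""
    E_e = np.asarray(E_e, dtype=float)
    if np.any(E_e < 0):
        raise ValueError("irradiance must be >= 0")
    F = 6e-5 * (params.irradiance_unit_scale * E_e) * params.wavelength / params.w_loss
    k1 = params.eps1 * F * np.asarray(p, dtype=float)
    k2 = params.eps2 * F * np.asarray(p, dtype=float)
    S0 = 0.5 * (1.0 + np.tanh(120.0 * (E_e - 0.1)))
    Ee_log = np.maximum(E_e, _EE_FLOOR)
    e12 = np.maximum(0.0, 0.011 + 0.005 * np.log(Ee_log / 0.024))
    e21 = np.maximum(0.0, 0.008 + 0.004 * np.log(Ee_log / 0.024))
    dark = E_e == 0.0
    e12 = np.where(dark, 0.0, e12)
    e21 = np.where(dark, 0.0, e21)
    return {"k1": k1, "k2": k2, "e12": e12, "e21": e21, "S0": S0, "F": F}


def rate_matrix(E_e: float, p: float, params: ChR2Params) -> np.ndarray:
    """4x4 generator of the occupancy ODEs in (O1, O2, C1, C2) order."""
    r = photo_rates(E_e, p, params)
    k1, k2, e12, e21 = (float(r[k]) for k in ("k1", "k2", "e12", "e21"))
    Gd1, Gd2, Gr = params.G_d1, params.G_d2, params.G_r
    return np.array([
        [-(Gd1 + e12), e21, k1, 0.0],
        [e12, -(Gd2 + e21), 0.0, k2],
        [Gd1, 0.0, -k1, Gr],
        [0.0, Gd2, 0.0, -(k2 + Gr)],
    ])


def chr2_derivatives(s: ChR2State, V: float, E_e: float, params: ChR2Params) -> np.ndarray:
    """d/dt of (O1, O2, C1, C2, p).  The occupancy part sums to zero exactly."""
    A = rate_matrix(E_e, s.p, params)
    occ = np.array([s.O1, s.O2, s.C1, s.C2])
    d_occ = A @ occ
    S0 = float(photo_rates(E_e, s.p, params)["S0"])
    dp = (S0 - s.p) / params.tau_ChR2
    return np.append(d_occ, dp)


def chr2_current(s: ChR2State, V, params: ChR2Params):
    """Photocurrent density I_ChR2 in pA/pF (outward positive).

    I = g_ChR2 * G(V) * (O1 + gamma*O2) * (V - E_ChR2); with C_m = 1 uF/cm^2
    the uA/cm^2 value is numerically the pA/pF current density seen by the
    host ionic model.  Negative at rest (depolarising).
    """
    drive = rectification_times_driving(V, params.E_ChR2)
    return params.g_ChR2 * (s.O1 + params.gamma * s.O2) * drive


def whole_cell_current(s: ChR2State, V, params: ChR2Params):
    """Whole-cell photocurrent in nA (current density x cell surface)."""
    dens = chr2_current(s, V, params)  # uA/cm^2
    return dens * params.S_cell * 1e3  # uA/cm^2 * cm^2 = uA -> nA


def step_chr2(s: ChR2State, V: float, E_e: float, dt: float,
              params: ChR2Params) -> ChR2State:
    """One forward-Euler update of the photocycle.

    Renormalises the occupancy sum if numerical drift exceeds 1e-12 and raises
    if any occupancy leaves [0, 1] by more than 1e-6.
    """
    d = chr2_derivatives(s, V, E_e, params)
    occ = np.array([s.O1, s.O2, s.C1, s.C2]) + dt * d[:4]
    p = s.p + dt * d[4]
    if np.any(occ < -1e-6) or np.any(occ > 1.0 + 1e-6):
        raise RuntimeError(f"ChR2 occupancy left [0,1]: {occ}")
    occ = np.clip(occ, 0.0, 1.0)
    tot = occ.sum()
    if abs(tot - 1.0) > 1e-12:
        occ /= tot
    return ChR2State(occ[0], occ[1], occ[2], occ[3], p)
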