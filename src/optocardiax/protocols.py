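"""Declarative stimulus and illumination schedules plus experiment drivers.

Schedules are pure, deterministic functions of time and node position:
:class:`LightProtocol` yields the irradiance E_e(t) (mW/mm^2) applied over a
rectangular node region, :class:`StimProtocol` the injected current density
(pA/pF).  ``series()`` samples a schedule at the solver step times, which is
what the integration kernels consume.

The experiment drivers at the bottom reproduce the single-cell protocols of
the study: optical threshold search, S1-S2 restitution under constant
illumination, and the phase-dependent light-pulse scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ionic_models import IonicParams, initial_state, equilibrate_rest
from .chr2 import ChR2Params

__all__ = [
    "Region",
    "LightProtocol",
    "StimProtocol",
    "constant_light",
    "pulsed_light",
    "no_light",
    "paced_stim",
    "global_subthreshold_electrical",
    "find_optical_threshold",
    "find_electrical_threshold",
    "s1s2_restitution",
    "phase_scan",
]


@dataclass(frozen=True)
class Region:
    """Half-open rectangular node region [x0, x1) x [y0, y1); None = unbounded."""

    x0: Optional[int] = None
    x1: Optional[int] = None
    y0: Optional[int] = None
    y1: Optional[int] = None

    def contains(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        m = np.ones_like(X, dtype=bool)
        if self.x0 is not None:
            m &= X >= self.x0
        if self.x1 is not None:
            m &= X < self.x1
        if self.y0 is not None:
            m &= Y >= self.y0
        if self.y1 is not None:
            m &= Y < self.y1
        return m


WHOLE_DOMAIN = Region()


@dataclass(frozen=True)
class LightProtocol:
    """Piecewise-constant irradiance field E_e(t, node).

    mode 'constant': E_e on [t_on, t_off).  mode 'pulsed': square pulses of
    ``pulse_width`` ms at ``frequency`` Hz starting at ``t_on``.
    """

    mode: str = "constant"
    E_e: float = 0.0
    t_on: float = 0.0
    t_off: float = math.inf
    frequency: float = 1.0           # Hz, pulsed mode
    pulse_width: float = 500.0       # ms, pulsed mode
    region: Region = WHOLE_DOMAIN

    def __post_init__(self):
        if self.E_e < 0:
            raise ValueError("irradiance must be >= 0")
        if self.mode not in ("constant", "pulsed"):
            raise ValueError(f"unknown light mode {self.mode!r}")
        if self.mode == "pulsed":
            period = 1000.0 / self.frequency
            if self.pulse_width > period + 1e-9:
                raise ValueError("pulse width exceeds the pulse period")

    def irradiance(self, t) -> np.ndarray:
        """Scalar irradiance at time(s) t (ms), before region masking."""
        t = np.asarray(t, dtype=float)
        active = (t >= self.t_on) & (t < self.t_off)
        if self.mode == "pulsed":
            period = 1000.0 / self.frequency
            active &= ((t - self.t_on) % period) < self.pulse_width
        out = np.where(active, self.E_e, 0.0)
        return out if out.ndim else float(out)

    def series(self, t0: float, n_steps: int, dt: float) -> np.ndarray:
        return np.asarray(self.irradiance(t0 + np.arange(n_steps) * dt), float)


@dataclass(frozen=True)
class StimProtocol:
    """Injected-current schedule: pulses of ``duration`` ms at given onsets.

    Either a regular train (``period`` ms starting at ``t_on``, optionally
    limited to ``n_pulses``) or explicit ``times``.  Amplitude in pA/pF,
    positive = depolarising.
    """

    amplitude: float = 20.0
    duration: float = 2.0
    period: Optional[float] = None
    t_on: float = 0.0
    n_pulses: Optional[int] = None
    times: Optional[Tuple[float, ...]] = None
    region: Region = WHOLE_DOMAIN

    def __post_init__(self):
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.duration <= 0:
            raise ValueError("pulse duration must be > 0")

    def current(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.times is not None:
            active = np.zeros_like(t, dtype=bool)
            for on in self.times:
                active |= (t >= on) & (t < on + self.duration)
        elif self.period is not None:
            rel = t - self.t_on
            active = (rel >= 0) & ((rel % self.period) < self.duration)
            if self.n_pulses is not None:
                active &= rel < self.n_pulses * self.period
        else:
            active = (t >= self.t_on) & (t < self.t_on + self.duration)
        out = np.where(active, self.amplitude, 0.0)
        return out if out.ndim else float(out)

    def series(self, t0: float, n_steps: int, dt: float) -> np.ndarray:
        return np.asarray(self.current(t0 + np.arange(n_steps) * dt), float)


def no_light() -> LightProtocol:
    return LightProtocol(mode="constant", E_e=0.0)


def constant_light(E_e: float, region: Region = WHOLE_DOMAIN,
                   t_on: float = 0.0, t_off: float = math.inf) -> LightProtocol:
    """Uniform constant illumination at E_e on [t_on, t_off) over ``region``."""
    if not t_off > t_on:
        raise ValueError("t_off must exceed t_on")
    return LightProtocol(mode="constant", E_e=E_e, t_on=t_on, t_off=t_off,
                         region=region)


def pulsed_light(E_e: float, frequency: float, pulse_width: float,
                 region: Region = WHOLE_DOMAIN, t_on: float = 0.0,
                 t_off: float = math.inf) -> LightProtocol:
    """Square-wave illumination: ``pulse_width`` ms on per 1000/frequency ms."""
    return LightProtocol(mode="pulsed", E_e=E_e, frequency=frequency,
                         pulse_width=pulse_width, t_on=t_on, t_off=t_off,
                         region=region)


def paced_stim(amplitude: float, cycle_length: float, duration: float = 2.0,
               region: Region = WHOLE_DOMAIN, t_on: float = 0.0,
               n_pulses: Optional[int] = None) -> StimProtocol:
    """Regular pacing train (edge pacing uses ``region`` = x < 4 by default)."""
    return StimProtocol(amplitude=amplitude, duration=duration,
                        period=cycle_length, t_on=t_on, n_pulses=n_pulses,
                        region=region)


def global_subthreshold_electrical(amplitude: float, pulse_width: float,
                                   frequency: float,
                                   capture_threshold: Optional[float] = None,
                                   ) -> StimProtocol:
    """Uniform whole-domain current pulses (the electrical analogue of the
    pulsed-light protocol).  Warns if the amplitude exceeds the supplied
    single-cell capture threshold, i.e. the protocol is supra-threshold."""
    if capture_threshold is not None and amplitude > capture_threshold:
        import warnings

        warnings.warn("amplitude exceeds capture threshold: protocol is "
                      "supra-threshold", stacklevel=2)
    return StimProtocol(amplitude=amplitude, duration=pulse_width,
                        period=1000.0 / frequency, region=WHOLE_DOMAIN)


# ---------------------------------------------------------------------------
# single-cell experiment drivers
# ---------------------------------------------------------------------------

def _pace_cell(params, chr2_params, stim_series, ee_series, dt,
               cell=None, ch=None, record_every=1):
    from ._kernels import run_zero_d

    if cell is None:
        cell = initial_state().as_array().copy()
    if ch is None:
        ch = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    t, V = run_zero_d(cell, ch, params, chr2_params, dt, stim_series,
                      ee_series, record_every=record_every)
    return t, V, cell, ch


def _triggers_ap(params, chr2_params, E_e, rest_cell, dt, window):
    """Does sustained illumination at E_e elicit an AP (V crossing 0 mV)?"""
    n = int(round(window / dt))
    _, V, _, _ = _pace_cell(params, chr2_params, np.zeros(n),
                            np.full(n, E_e), dt,
                            cell=rest_cell.copy(),
                            record_every=5)
    return bool(np.any(V > 0.0))


def find_optical_threshold(params: IonicParams,
                           chr2_params: Optional[ChR2Params] = None,
                           resolution: float = 0.001,
                           lo: float = 0.0, hi: float = 1.0,
                           dt: float = 0.02, window: float = 500.0,
                           rest_state=None) -> float:
    """Smallest constant irradiance (to ``resolution``) that fires a resting cell.

    Bisection on a ``resolution``-spaced grid between ``lo`` (must not
    trigger) and ``hi`` (must trigger); an AP is a 0 mV crossing within
    ``window`` ms of light onset from the dark-adapted resting state.
    """
    if resolution > 0.001 + 1e-12:
        raise ValueError("resolution must be <= 0.001 mW/mm^2")
    chr2_params = chr2_params or ChR2Params()
    if rest_state is None:
        rest_state = equilibrate_rest(params).as_array()
    rest_state = np.asarray(rest_state, float)
    n_grid = int(round((hi - lo) / resolution))
    a, b = 0, n_grid  # grid indices; lo + i*resolution
    if not _triggers_ap(params, chr2_params, lo + b * resolution, rest_state,
                        dt, window):
        raise RuntimeError(f"no optical threshold found in [{lo}, {hi}] mW/mm^2")
    if _triggers_ap(params, chr2_params, lo + a * resolution, rest_state,
                    dt, window):
        raise RuntimeError("lower bracket already triggers an AP")
    while b - a > 1:
        m = (a + b) // 2
        if _triggers_ap(params, chr2_params, lo + m * resolution, rest_state,
                        dt, window):
            b = m
        else:
            a = m
    return lo + b * resolution


def find_electrical_threshold(params: IonicParams, duration: float = 2.0,
                              dt: float = 0.02, window: float = 50.0,
                              resolution: float = 0.25,
                              rest_state=None) -> float:
    """Diastolic capture threshold (pA/pF) of a ``duration``-ms current pulse."""
    from .chr2 import ChR2Params as _CP

    cp = _CP(g_ChR2=0.0)
    if rest_state is None:
        rest_state = equilibrate_rest(params).as_array()
    rest_state = np.asarray(rest_state, float)
    n = int(round(window / dt))
    ee = np.zeros(n)
    t = np.arange(n) * dt

    def fires(amp):
        stim = np.where(t < duration, amp, 0.0)
        _, V, _, _ = _pace_cell(params, cp, stim, ee, dt,
                                cell=rest_state.copy(), record_every=5)
        return bool(np.any(V > 0.0))

    lo_amp, hi_amp = 0.0, 64.0
    if not fires(hi_amp):
        raise RuntimeError("no electrical capture up to 64 pA/pF")
    while hi_amp - lo_amp > resolution:
        mid = 0.5 * (lo_amp + hi_amp)
        if fires(mid):
            hi_amp = mid
        else:
            lo_amp = mid
    return hi_amp


def default_pacing_amplitude(params: IonicParams, rest_state=None) -> float:
    """Twice the diastolic 2-ms capture threshold, the package's default
    pacing stimulus."""
    return 2.0 * find_electrical_threshold(params, rest_state=rest_state)


def s1s2_restitution(params: IonicParams,
                     chr2_params: Optional[ChR2Params] = None,
                     E_e_constant: float = 0.0,
                     s1_cycle_length: float = 1000.0, s1_count: int = 10,
                     s2_intervals: Optional[Sequence[float]] = None,
                     stim_amplitude: Optional[float] = None,
                     stim_duration: float = 2.0,
                     dt: float = 0.02) -> pd.DataFrame:
    """Single-cell S1-S2 APD restitution under sustained uniform illumination.

    Runs ``s1_count`` S1 beats at ``s1_cycle_length``, snapshots the state at
    the last S1 onset + one full beat, then launches one S2 per coupling
    interval.  Returns a DataFrame with columns CI (S2 coupling interval, ms),
    DI (diastolic interval = CI - APD90 of the last S1), APD90 (of the S2
    beat) and captured.  Failed S2 captures are flagged and excluded from
    slope estimates downstream.
    """
    from .analysis import apd

    chr2_params = chr2_params or ChR2Params()
    if stim_amplitude is None:
        stim_amplitude = default_pacing_amplitude(params)

    from ._kernels import run_zero_d

    # S1 train up to (but not including) the last S1 beat
    n1 = int(round((s1_count - 1) * s1_cycle_length / dt))
    t1 = np.arange(n1) * dt
    stim1 = np.where((t1 % s1_cycle_length) < stim_duration, stim_amplitude, 0.0)
    ee1 = np.full(n1, E_e_constant)
    _, _, cell, ch = _pace_cell(params, chr2_params, stim1, ee1, dt)

    if s2_intervals is None:
        # target the standard diastolic-interval span 50-1000 ms: probe the
        # last-S1 APD90 once, then place S2 at CI = APD90(S1) + DI
        probe_n = int(round(s1_cycle_length / dt))
        cp, chp = cell.copy(), ch.copy()
        tpr = np.arange(probe_n) * dt
        stim_pr = np.where(tpr < stim_duration, stim_amplitude, 0.0)
        tt, VV = run_zero_d(cp, chp, params, chr2_params, dt, stim_pr,
                            np.full(probe_n, E_e_constant), record_every=1)
        probe = apd(tt, VV, X=90.0)
        if not probe:
            raise RuntimeError("S1 beat failed to capture during DI probing")
        di_grid = [50, 75, 100, 125, 150, 200, 250, 300, 400, 500,
                   600, 700, 850, 1000]
        s2_intervals = [probe[0]["apd"] + di for di in di_grid]

    # each branch re-runs the last S1 (at relative t = 0) plus one S2 at t = CI
    rows = []
    apd_s1 = None
    for ci in sorted(s2_intervals):
        c2, ch2 = cell.copy(), ch.copy()
        horizon = ci + 800.0
        n2 = int(round(horizon / dt))
        t2 = np.arange(n2) * dt
        stim2 = np.where((t2 < stim_duration)
                         | ((t2 >= ci) & (t2 < ci + stim_duration)),
                         stim_amplitude, 0.0)
        ee2 = np.full(n2, E_e_constant)
        tr_t, tr_V = run_zero_d(c2, ch2, params, chr2_params, dt, stim2, ee2,
                                record_every=1)
        beats = apd(tr_t, tr_V, X=90.0)
        if not beats:
            raise RuntimeError("last S1 beat failed to capture")
        apd_s1 = beats[0]["apd"]
        captured = len(beats) >= 2 and beats[1]["v_max"] > 0.0
        rows.append({
            "CI": float(ci),
            "DI": float(ci - apd_s1),
            "APD90": float(beats[1]["apd"]) if captured else np.nan,
            "captured": captured,
        })
    df = pd.DataFrame(rows)
    df.attrs["apd_s1"] = float(apd_s1)
    return df


def phase_scan(params: IonicParams,
               chr2_params: Optional[ChR2Params] = None,
               E_e: float = 0.092, pulse_width: float = 100.0,
               repolarisation_levels: Optional[Sequence[float]] = None,
               cycle_length: float = 1000.0, n_pre: int = 8,
               stim_amplitude: Optional[float] = None,
               stim_duration: float = 2.0, dt: float = 0.02) -> pd.DataFrame:
    """Phase-dependent response of the APD to a sub-threshold light pulse.

    Paces the cell to steady state in the dark, records the unperturbed AP
    (APD90 = A0) of the following beat, and for each repolarisation level L
    (percent, per the APD threshold convention) re-runs that beat with a
    light pulse triggered when the unperturbed AP first repolarises to L%.
    Returns a DataFrame with columns level, t_pulse (ms after the upstroke
    threshold crossing), A1, ratio (= A1/A0) and valid.
    """
    from .analysis import apd
    from ._kernels import run_zero_d

    chr2_params = chr2_params or ChR2Params()
    if stim_amplitude is None:
        stim_amplitude = default_pacing_amplitude(params)
    if repolarisation_levels is None:
        repolarisation_levels = np.arange(2.0, 99.0, 2.0)

    # steady-state pre-pacing (dark)
    n0 = int(round(n_pre * cycle_length / dt))
    t0 = np.arange(n0) * dt
    stim0 = np.where((t0 % cycle_length) < stim_duration, stim_amplitude, 0.0)
    _, _, cell, ch = _pace_cell(params, chr2_params, stim0, np.zeros(n0), dt)

    # unperturbed reference beat (twin run)
    n1 = int(round(cycle_length / dt))
    t1 = np.arange(n1) * dt
    stim1 = np.where(t1 < stim_duration, stim_amplitude, 0.0)
    c_ref, ch_ref = cell.copy(), ch.copy()
    tr_t, tr_V = run_zero_d(c_ref, ch_ref, params, chr2_params, dt, stim1,
                            np.zeros(n1), record_every=1)
    ref = apd(tr_t, tr_V, X=90.0)
    if len(ref) != 1:
        raise RuntimeError("reference beat did not contain exactly one AP")
    a0 = ref[0]["apd"]
    vmax, vmin = ref[0]["v_max"], ref[0]["v_min"]
    i_up = np.argmax(tr_V)  # peak; repolarisation trajectory follows it

    rows = []
    for level in repolarisation_levels:
        v_level = vmax - level / 100.0 * (vmax - vmin)
        after_peak = tr_V[i_up:]
        below = np.where(after_peak <= v_level)[0]
        if len(below) == 0:
            rows.append({"level": float(level), "t_pulse": np.nan,
                         "A1": np.nan, "ratio": np.nan, "valid": False})
            continue
        t_pulse = tr_t[i_up + below[0]]
        c1, chx = cell.copy(), ch.copy()
        ee = np.where((t1 >= t_pulse) & (t1 < t_pulse + pulse_width), E_e, 0.0)
        tp_t, tp_V = run_zero_d(c1, chx, params, chr2_params, dt, stim1, ee,
                                record_every=1)
        pert = apd(tp_t, tp_V, X=90.0)
        if len(pert) == 0:
            rows.append({"level": float(level), "t_pulse": float(t_pulse),
                         "A1": np.nan, "ratio": np.nan, "valid": False})
            continue
        a1 = pert[0]["apd"]
        rows.append({"level": float(level), "t_pulse": float(t_pulse),
                     "A1": float(a1), "ratio": float(a1 / a0), "valid": True})
    df = pd.DataFrame(rows)
    df.attrs["A0"] = float(a0)
    return df
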