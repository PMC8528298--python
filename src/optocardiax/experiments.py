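"""Composed in-silico experiments: cable propagation and spiral-wave setups.

These drivers wire together domains, protocols and measurements for the
standard characterisation runs: plane-wave conduction velocity, wavelength
(CV x APD90) at steady pacing, and S1-S2 cross-field spiral initiation in a
2D sheet.  They are what the command-line tools and the reproduction script
call; each returns plain dicts/objects so results are easy to tabulate.
"""

from __future__ import annotations

import copy
from typing import Optional, Sequence, Tuple

import numpy as np

from . import analysis as an
from . import solver
from .chr2 import ChR2Params
from .ionic_models import IonicParams, equilibrate_rest
from .protocols import LightProtocol, Region, StimProtocol, paced_stim

__all__ = [
    "cable_cv",
    "cable_wavelength",
    "make_spiral",
    "spiral_ps_counts",
]


def cable_cv(params: IonicParams,
             chr2_params: Optional[ChR2Params] = None,
             nx: int = 512, ny: int = 10,
             dx: float = solver.DEFAULT_DX, D: float = solver.DEFAULT_D,
             dt: float = solver.DEFAULT_DT,
             light: Optional[LightProtocol] = None,
             stim_amplitude: float = 30.0,
             sites: Tuple[int, int] = (150, 350),
             duration: Optional[float] = None,
             rest_state: Optional[np.ndarray] = None) -> dict:
    """Plane-wave CV on a pseudo-1D cable paced once from the left edge (x < 4).

    CV is measured mid-cable between ``sites`` from the -40 mV upstroke
    crossing times.  Returns {'cv', 'activation_times'} with cv = NaN on block.
    """
    if rest_state is None:
        rest_state = equilibrate_rest(params).as_array()
    dom = solver.TissueDomain.create(nx, ny, params, chr2_params, dx=dx, D=D,
                                     cell_state=rest_state)
    stim = paced_stim(amplitude=stim_amplitude, cycle_length=1e9,
                      duration=2.0, region=Region(x1=4), n_pulses=1)
    if duration is None:
        duration = nx * dx / 0.03 + 60.0  # generous for CV >= 30 cm/s
    a, b = sites
    y_mid = ny // 2
    rec = solver.run(dom, duration, stim=stim, light=light, dt=dt,
                     trace_sites=[(a, y_mid), (b, y_mid)], trace_every=0.0)
    tA, VA = rec.trace((a, y_mid))
    tB, VB = rec.trace((b, y_mid))
    cv = an.conduction_velocity(tA, VA, tB, VB, (b - a) * dx)
    return {"cv": cv,
            "activation_times": (an.activation_time(tA, VA),
                                 an.activation_time(tB, VB))}


def cable_wavelength(params: IonicParams,
                     chr2_params: Optional[ChR2Params] = None,
                     nx: int = 1200, ny: int = 3,
                     dx: float = solver.DEFAULT_DX, D: float = solver.DEFAULT_D,
                     dt: float = solver.DEFAULT_DT,
                     cycle_length: float = 1000.0, beats: int = 3,
                     stim_amplitude: Optional[float] = None,
                     light: Optional[LightProtocol] = None,
                     rest_state: Optional[np.ndarray] = None) -> dict:
    """Wavelength = CV x APD90 of the last of ``beats`` paced plane waves.

    The cable is paced at ``cycle_length`` from the left edge; CV and APD90
    are measured between/at interior sites on the final beat, approximating
    the 1 Hz steady state.
    """
    from .protocols import default_pacing_amplitude

    if rest_state is None:
        rest_state = equilibrate_rest(params).as_array()
    if stim_amplitude is None:
        stim_amplitude = default_pacing_amplitude(params, rest_state=rest_state)
    dom = solver.TissueDomain.create(nx, ny, params, chr2_params, dx=dx, D=D,
                                     cell_state=rest_state)
    stim = paced_stim(amplitude=stim_amplitude, cycle_length=cycle_length,
                      duration=2.0, region=Region(x1=4), n_pulses=beats)
    a, b = int(nx * 0.33), int(nx * 0.67)
    y_mid = ny // 2
    rec = solver.run(dom, beats * cycle_length, stim=stim, light=light, dt=dt,
                     trace_sites=[(a, y_mid), (b, y_mid)], trace_every=0.1)
    tA, VA = rec.trace((a, y_mid))
    tB, VB = rec.trace((b, y_mid))
    t_last = (beats - 1) * cycle_length
    cv = an.conduction_velocity(tA, VA, tB, VB, (b - a) * dx, t_after=t_last)
    sel = tB > t_last
    beats_b = an.apd(tB[sel], VB[sel], X=90.0)
    if not beats_b or np.isnan(cv):
        raise RuntimeError("wave blocked before the measurement window")
    apd90 = beats_b[0]["apd"]
    return {"cv": cv, "apd90": apd90,
            "wavelength": an.wavelength(cv, apd90)}


def make_spiral(params: IonicParams,
                chr2_params: Optional[ChR2Params] = None,
                nx: int = 160, ny: int = 160,
                dx: float = solver.DEFAULT_DX, D: float = solver.DEFAULT_D,
                dt: float = solver.DEFAULT_DT,
                stim_amplitude: float = 30.0,
                s2_offsets: Sequence[float] = (10.0, 25.0, 40.0, -5.0, 55.0),
                settle: float = 400.0,
                rest_state: Optional[np.ndarray] = None,
                verbose: bool = False) -> Tuple[solver.TissueDomain, dict]:
    """S1-S2 cross-field spiral initiation in a square sheet.

    S1: plane wave from the left edge.  S2: stimulus over the lower half
    (y < ny/2) when the S1 waveback has just cleared the domain centre,
    plus a deterministic offset searched over ``s2_offsets`` until exactly
    one sustained phase singularity remains ``settle`` ms after S2.
    Returns the domain (time reset to 0) holding the rotating spiral, and an
    info dict with the chosen timing and the final tip count.
    """
    if rest_state is None:
        rest_state = equilibrate_rest(params).as_array()

    # probe run: when does the S1 waveback clear the domain centre?
    dom = solver.TissueDomain.create(nx, ny, params, chr2_params, dx=dx, D=D,
                                     cell_state=rest_state)
    s1 = paced_stim(amplitude=stim_amplitude, cycle_length=1e9, duration=2.0,
                    region=Region(x1=4), n_pulses=1)
    probe_T = nx * dx / 0.03 + 400.0
    rec = solver.run(dom, probe_T, stim=s1, dt=dt,
                     trace_sites=[(nx // 2, ny // 2)], trace_every=0.2)
    tc, Vc = rec.trace((nx // 2, ny // 2))
    up = an.activation_time(tc, Vc)
    if np.isnan(up):
        raise RuntimeError("S1 wave failed to reach the domain centre")
    after = tc > up
    down = np.where((Vc[:-1] >= -60.0) & (Vc[1:] < -60.0) & after[:-1])[0]
    if len(down) == 0:
        raise RuntimeError("S1 waveback never cleared the domain centre")
    t_back = tc[down[0]]

    info = {"t_waveback_centre": float(t_back)}
    for off in s2_offsets:
        t2 = t_back + off
        dom = solver.TissueDomain.create(nx, ny, params, chr2_params, dx=dx,
                                         D=D, cell_state=rest_state)
        solver.run(dom, t2, stim=s1, dt=dt)
        s2 = StimProtocol(amplitude=stim_amplitude, duration=2.0, t_on=dom.t,
                          region=Region(y1=ny // 2))
        rec2 = solver.run(dom, settle, stim=s2, dt=dt, frame_every=10.0)
        tail = rec2.frames[-8:]
        traj = an.tip_trajectory(np.nan_to_num(tail, nan=-85.0),
                                 rec2.frame_t[-8:], dx)
        counts = traj.count_per_frame()
        if verbose:
            print(f"  S2 offset {off}: tip counts {counts}")
        if len(counts) and counts.min() >= 1 and np.median(counts) <= 2:
            info.update({"s2_offset": float(off), "t_s2": float(t2),
                         "tip_counts": counts.tolist()})
            dom.t = 0.0
            return dom, info
    raise RuntimeError("no S2 offset produced a single sustained spiral; "
                       f"probe info: {info}")


def spiral_ps_counts(domain: solver.TissueDomain, duration: float,
                     light: Optional[LightProtocol],
                     dt: float = solver.DEFAULT_DT,
                     frame_every: float = 10.0,
                     trace_site: Optional[Tuple[int, int]] = None):
    """Run a spiral domain (copy; the input is untouched) under a light
    protocol and return (tip counts per frame, Recording)."""
    dom = copy.deepcopy(domain)
    sites = [trace_site] if trace_site else []
    rec = solver.run(dom, duration, light=light, dt=dt,
                     trace_sites=sites, trace_every=1.0,
                     frame_every=frame_every)
    traj = an.tip_trajectory(np.nan_to_num(rec.frames, nan=-85.0),
                             rec.frame_t, domain.dx)
    return traj.count_per_frame(), rec
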