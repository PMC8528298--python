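"""Explicit monodomain integrator over 0D, cable, 2D and hybrid geometries.

The transmembrane potential obeys dV/dt = D lap(V) - (I_ion + I_ChR2)/C_m
(+ injected current), discretised with a 5-point Laplacian, no-flux (mirror)
boundaries at domain edges and mask boundaries, forward-Euler voltage /
concentration updates and Rush-Larsen gate updates at a fixed dt.

Default numerics: dt = 0.02 ms, dx = dy = 0.022 cm, D = 0.0023 cm^2/ms
(stability requires D dt/dx^2 <= 1/4 in 2D; the defaults give 0.095).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import ionic_models as im
from .chr2 import ChR2Params
from .ionic_models import IonicParams
from .protocols import LightProtocol, StimProtocol, no_light

__all__ = [
    "TissueDomain",
    "Recording",
    "laplacian",
    "step_tissue",
    "run",
    "run_cell",
    "build_hybrid_domain",
    "DEFAULT_DT",
    "DEFAULT_DX",
    "DEFAULT_D",
    "FIG2G_SITES",
]

DEFAULT_DT = 0.02    # ms
DEFAULT_DX = 0.022   # cm
DEFAULT_D = 0.0023   # cm^2/ms

# the five representative recording sites of the 512 x 512 sheet, (x, y)
FIG2G_SITES = ((128, 128), (128, 384), (384, 384), (384, 128), (256, 256))


def laplacian(V_field: np.ndarray, mask: Optional[np.ndarray] = None,
              dx: float = DEFAULT_DX) -> np.ndarray:
    """5-point Laplacian with no-flux boundaries at edges and mask borders.

    Out-of-domain neighbours are mirrored (replaced by the centre value), so
    the discrete integral of the result over the domain vanishes exactly.
    """
    V = np.asarray(V_field, float)
    if mask is None:
        mask = np.ones_like(V, bool)
    out = np.zeros_like(V)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb = np.roll(V, shift, axis=axis)
        nb_ok = np.roll(mask, shift, axis=axis).copy()
        # roll wraps around; sever the wrap to make the edge reflective
        if axis == 0:
            (nb_ok[0] if shift == 1 else nb_ok[-1])[:] = False
        else:
            (nb_ok[:, 0] if shift == 1 else nb_ok[:, -1])[:] = False
        out += np.where(nb_ok, nb, V) - V
    out /= dx * dx
    return np.where(mask, out, 0.0)


@dataclass
class TissueDomain:
    """Masked rectangular grid of coupled CRN + ChR2 nodes.

    ``cell`` and ``chr2`` hold the states of the active (masked-in) nodes in
    row-major order of the (x, y) grid; ``index`` maps grid -> flat node id
    (-1 outside the mask); ``nbr`` holds the four neighbour ids with the node
    itself substituted across no-flux borders.
    """

    nx: int
    ny: int
    dx: float
    D: float
    mask: np.ndarray
    index: np.ndarray
    nbr: np.ndarray
    cell: np.ndarray
    chr2: np.ndarray
    ionic_params: IonicParams
    chr2_params: ChR2Params
    t: float = 0.0
    # per-node I_Na scaling (1 = normal); lets tests/users carve inexcitable
    # patches without a second parameter set
    gna_scale: Optional[np.ndarray] = None

    @property
    def n_nodes(self) -> int:
        return self.cell.shape[0]

    @classmethod
    def create(cls, nx: int, ny: int, ionic_params: IonicParams,
               chr2_params: Optional[ChR2Params] = None,
               dx: float = DEFAULT_DX, D: float = DEFAULT_D,
               mask: Optional[np.ndarray] = None,
               cell_state: Optional[np.ndarray] = None) -> "TissueDomain":
        if dx <= 0:
            raise ValueError("dx must be > 0")
        if D < 0:
            raise ValueError("D must be >= 0")
        if mask is None:
            mask = np.ones((nx, ny), bool)
        mask = np.asarray(mask, bool)
        if mask.shape != (nx, ny):
            raise ValueError("mask shape does not match the grid")
        index = -np.ones((nx, ny), np.int64)
        xs, ys = np.nonzero(mask)
        n = len(xs)
        index[xs, ys] = np.arange(n)
        nbr = np.empty((n, 4), np.int64)
        for k, (di, dj) in enumerate(((1, 0), (-1, 0), (0, 1), (0, -1))):
            xi, yj = xs + di, ys + dj
            ok = (xi >= 0) & (xi < nx) & (yj >= 0) & (yj < ny)
            flat = np.arange(n)
            tgt = flat.copy()
            ii = index[xi[ok], yj[ok]]
            sel = np.where(ok)[0]
            good = ii >= 0
            tgt[sel[good]] = ii[good]
            nbr[:, k] = tgt
        if cell_state is None:
            cell = im.initial_state(n).as_array()
        else:
            cell_state = np.asarray(cell_state, float)
            cell = np.tile(cell_state, (n, 1)) if cell_state.ndim == 1 \
                else cell_state.copy()
        chr2 = np.tile(np.array([0.0, 0.0, 1.0, 0.0, 0.0]), (n, 1))
        return cls(nx=nx, ny=ny, dx=dx, D=D, mask=mask, index=index, nbr=nbr,
                   cell=cell, chr2=chr2, ionic_params=ionic_params,
                   chr2_params=chr2_params or ChR2Params())

    def check_stability(self, dt: float) -> None:
        cfl = self.D * dt / self.dx ** 2
        if cfl > 0.25 + 1e-12:
            raise ValueError(
                f"D*dt/dx^2 = {cfl:.3f} violates the explicit stability "
                "bound 1/4")

    def site_index(self, x: int, y: int) -> int:
        i = int(self.index[x, y])
        if i < 0:
            raise ValueError(f"site ({x}, {y}) is outside the tissue mask")
        return i

    def voltage_grid(self) -> np.ndarray:
        V = np.full((self.nx, self.ny), np.nan)
        V[self.mask] = self.cell[:, 0]
        return V

    def grid_coords(self) -> Tuple[np.ndarray, np.ndarray]:
        xs, ys = np.nonzero(self.mask)
        return xs, ys

    def region_mask(self, region) -> np.ndarray:
        """Float 0/1 mask over active nodes for a protocol Region."""
        if region is None:
            return np.ones(self.n_nodes)
        xs, ys = self.grid_coords()
        return region.contains(xs, ys).astype(float)


@dataclass
class Recording:
    """Traces, frames and protocol log of one run."""

    trace_t: np.ndarray
    traces: Dict[Tuple[int, int], np.ndarray]
    frame_t: np.ndarray
    frames: np.ndarray              # (n_frames, nx, ny), NaN outside mask
    meta: dict = field(default_factory=dict)

    def trace(self, site: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
        return self.trace_t, self.traces[site]


def _series_and_masks(domain, stim, light, n_steps, dt):
    if stim is None:
        stim_series = np.zeros(n_steps)
        stim_mask = np.zeros(domain.n_nodes)
    else:
        stim_series = stim.series(domain.t, n_steps, dt)
        stim_mask = domain.region_mask(stim.region)
    light = light or no_light()
    ee_series = light.series(domain.t, n_steps, dt)
    ee_mask = domain.region_mask(light.region)
    return stim_series, stim_mask, ee_series, ee_mask


def run(domain: TissueDomain, duration: float,
        stim: Optional[StimProtocol] = None,
        light: Optional[LightProtocol] = None,
        dt: float = DEFAULT_DT,
        trace_sites: Sequence[Tuple[int, int]] = (),
        trace_every: float = 0.0,
        frame_every: float = 0.0) -> Recording:
    """Integrate the domain in place for ``duration`` ms and record.

    ``trace_every`` / ``frame_every`` are sampling intervals in ms (0 =
    record every step for traces, disable for frames).  Raises
    FloatingPointError with the blow-up location if V leaves [-150, 150] mV.
    """
    from ._kernels import (_run_coupled, build_tables, chr2_scalars,
                           ionic_scalars)

    domain.check_stability(dt)
    n_steps = int(round(duration / dt))
    stim_series, stim_mask, ee_series, ee_mask = _series_and_masks(
        domain, stim, light, n_steps, dt)

    tr_every = max(1, int(round(trace_every / dt))) if trace_every > 0 else 1
    fr_every = int(round(frame_every / dt)) if frame_every > 0 else 0
    tidx = np.array([domain.site_index(x, y) for (x, y) in trace_sites],
                    np.int64)
    n_tr = n_steps // tr_every if len(tidx) else 0
    traces = np.empty((len(tidx), n_steps // tr_every))
    n_fr = n_steps // fr_every if fr_every else 0
    frames_flat = np.empty((n_fr, domain.n_nodes), np.float32)

    inf_tab, rl_tab, cur_tab = build_tables(domain.ionic_params, dt)
    lapfac = domain.D * dt / domain.dx ** 2
    status, bad = _run_coupled(
        domain.cell, domain.chr2, domain.nbr, lapfac, dt,
        stim_series, stim_mask, ee_series, ee_mask,
        inf_tab, rl_tab, cur_tab,
        ionic_scalars(domain.ionic_params), chr2_scalars(domain.chr2_params),
        domain.gna_scale if domain.gna_scale is not None
        else np.ones(domain.n_nodes),
        tidx, tr_every if len(tidx) else 0, traces,
        fr_every, frames_flat, 0)
    if status != 0:
        xs, ys = domain.grid_coords()
        raise FloatingPointError(
            f"voltage blow-up at node ({xs[bad]}, {ys[bad]}), t ~ "
            f"{domain.t:.1f}+ ms")
    if not np.all(np.isfinite(domain.cell[:, 0])):
        raise FloatingPointError("non-finite voltage after integration")

    t0 = domain.t
    domain.t += n_steps * dt
    trace_t = t0 + np.arange(1, traces.shape[1] + 1) * tr_every * dt
    frame_t = t0 + np.arange(1, n_fr + 1) * fr_every * dt if fr_every \
        else np.empty(0)
    frames = np.full((n_fr, domain.nx, domain.ny), np.nan, np.float32)
    if n_fr:
        frames[:, domain.mask] = frames_flat
    rec = Recording(
        trace_t=trace_t,
        traces={site: traces[k] for k, site in enumerate(trace_sites)},
        frame_t=frame_t,
        frames=frames,
        meta={
            "dt": dt, "dx": domain.dx, "D": domain.D,
            "nx": domain.nx, "ny": domain.ny,
            "duration": duration, "t0": t0,
            "ionic_params": domain.ionic_params.to_dict(),
            "chr2_params": domain.chr2_params.to_dict(),
            "stim": repr(stim), "light": repr(light),
        },
    )
    return rec


def step_tissue(domain: TissueDomain, dt: float = DEFAULT_DT,
                stim: Optional[StimProtocol] = None,
                light: Optional[LightProtocol] = None) -> TissueDomain:
    """Advance the domain by a single dt (thin wrapper over :func:`run`)."""
    run(domain, dt, stim=stim, light=light, dt=dt)
    return domain


def run_cell(ionic_params: IonicParams,
             chr2_params: Optional[ChR2Params] = None,
             duration: float = 1000.0,
             stim: Optional[StimProtocol] = None,
             light: Optional[LightProtocol] = None,
             dt: float = DEFAULT_DT, record_every: float = 0.0,
             cell_state: Optional[np.ndarray] = None,
             chr2_state: Optional[np.ndarray] = None):
    """0D convenience wrapper: returns (t, V, final_cell, final_chr2)."""
    from ._kernels import run_zero_d

    chr2_params = chr2_params or ChR2Params()
    n = int(round(duration / dt))
    t_axis = np.arange(n) * dt
    stim_series = stim.series(0.0, n, dt) if stim is not None else np.zeros(n)
    light = light or no_light()
    ee_series = light.series(0.0, n, dt)
    cell = (np.asarray(cell_state, float).copy() if cell_state is not None
            else im.initial_state().as_array().copy())
    ch = (np.asarray(chr2_state, float).copy() if chr2_state is not None
          else np.array([0.0, 0.0, 1.0, 0.0, 0.0]))
    rec = max(1, int(round(record_every / dt))) if record_every > 0 else 1
    t, V = run_zero_d(cell, ch, ionic_params, chr2_params, dt, stim_series,
                      ee_series, record_every=rec)
    return t, V, cell, ch


def build_hybrid_domain(ionic_params: IonicParams,
                        chr2_params: Optional[ChR2Params] = None,
                        main_shape: Tuple[int, int] = (512, 512),
                        strip_shape: Tuple[int, int] = (1536, 30),
                        dx: float = DEFAULT_DX, D: float = DEFAULT_D,
                        attach_y: Optional[int] = None,
                        cell_state: Optional[np.ndarray] = None
                        ) -> TissueDomain:
    """2D sheet with a pseudo-1D strip attached to its right edge.

    The strip (length x width, along x) couples diffusively to the main sheet
    across the junction; by construction there are no sources inside it, so
    its activity is driven by waves entering from the 2D part.  ``attach_y``
    positions the strip's lower edge (default: centred).
    """
    mx, my = main_shape
    sx, sy = strip_shape
    if sy > my:
        raise ValueError("strip wider than the main domain edge")
    if attach_y is None:
        attach_y = (my - sy) // 2
    if attach_y < 0 or attach_y + sy > my:
        raise ValueError("strip attachment leaves the main domain edge")
    nx, ny = mx + sx, my
    mask = np.zeros((nx, ny), bool)
    mask[:mx, :] = True
    mask[mx:, attach_y:attach_y + sy] = True
    dom = TissueDomain.create(nx, ny, ionic_params, chr2_params, dx=dx, D=D,
                              mask=mask, cell_state=cell_state)
    return dom
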