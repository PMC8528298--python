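"""Deterministic synthetic objects with closed-form ground truth.

Used by the analysis-module tests (and available from the CLI) to validate
the measurement operators independently of the PDE solver: ideal square and
triangle action potentials, a rigidly rotating Archimedean spiral phase
field, plane-wave frame stacks, and a cable with an inexcitable patch.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_fixtures", "square_ap", "triangle_ap", "rotating_spiral",
           "plane_wave_frames", "waveback_collapse_profiles"]


def square_ap(width: float = 100.0, dt: float = 0.1, rest: float = -80.0,
              peak: float = 20.0, total: float = 400.0, onset: float = 50.0):
    """Ideal square AP of the given width: APD_X = width for all X in (0,100)."""
    t = np.arange(0.0, total, dt)
    V = np.where((t >= onset) & (t < onset + width), peak, rest)
    return t, V


def triangle_ap(duration: float = 300.0, dt: float = 0.1, v0: float = 20.0,
                v1: float = -80.0):
    """Linear ramp from (0, v0) to (duration, v1); APD_X = X/100 * duration."""
    t = np.arange(0.0, duration + dt / 2, dt)
    V = v0 + (v1 - v0) * t / duration
    return t, V


def rotating_spiral(n: int = 128, period: float = 87.0, frame_every: float = 5.0,
                    n_frames: int = 40, dx: float = 0.022,
                    pitch_nodes: float = 30.0, centre=None):
    """Rigidly rotating Archimedean spiral phase field.

    V(r, theta, t) = -60 + 45*cos(theta - 2*pi*t/period - 2*pi*r/pitch), a
    single phase singularity fixed at ``centre`` rotating with the given
    period (dominant frequency 1000/period Hz).
    Returns (frames, times, centre_xy_cm).
    """
    if centre is None:
        centre = ((n - 1) / 2.0, (n - 1) / 2.0)
    X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r = np.hypot(X - centre[0], Y - centre[1])
    th = np.arctan2(Y - centre[1], X - centre[0])
    times = np.arange(n_frames) * frame_every
    frames = np.empty((n_frames, n, n))
    for k, t in enumerate(times):
        phase = th - 2 * np.pi * t / period - 2 * np.pi * r / pitch_nodes
        frames[k] = -60.0 + 45.0 * np.cos(phase)
    return frames, times, (centre[0] * dx, centre[1] * dx)


def plane_wave_frames(nx: int = 100, ny: int = 20, cv_nodes_per_ms: float = 1.5,
                      apd: float = 100.0, frame_every: float = 5.0,
                      n_frames: int = 40, rest: float = -80.0,
                      peak: float = 15.0):
    """Rightward-travelling rectangular wave: V = peak inside the excited band."""
    times = np.arange(n_frames) * frame_every
    X = np.arange(nx)[:, None] * np.ones((1, ny))
    frames = np.empty((n_frames, nx, ny))
    for k, t in enumerate(times):
        front = cv_nodes_per_ms * t
        back = cv_nodes_per_ms * max(0.0, t - apd)
        frames[k] = np.where((X <= front) & (X >= back), peak, rest)
    return frames, times


def waveback_collapse_profiles(nx: int = 200, dt_frame: float = 10.0,
                               n_frames: int = 30, split_at: int = 10,
                               heal_at: int = 20, gap=(90, 110),
                               rest: float = -80.0, peak: float = 15.0):
    """1D profile stack in which one excited band splits, exposing a
    recovered gap over frames [split_at, heal_at), after which the gap is
    re-excited (propagation direction reversal).

    Ground truth: the vulnerable window spans times
    (split_at * dt_frame, heal_at * dt_frame) and x-range ``gap`` (nodes).
    """
    times = np.arange(n_frames) * dt_frame
    x = np.arange(nx)
    band = (x >= 40) & (x < 160)
    profiles = np.full((n_frames, nx), rest)
    for k in range(n_frames):
        exc = band.copy()
        if split_at <= k < heal_at:
            exc &= ~((x >= gap[0]) & (x < gap[1]))
        profiles[k, exc] = peak
    return profiles, times, (times[split_at], times[heal_at])


def make_fixtures(kind: str):
    """Factory keyed by fixture name (see module docstring)."""
    factories = {
        "square-AP trace": square_ap,
        "triangle-AP trace": triangle_ap,
        "rotating-spiral phase field": rotating_spiral,
        "plane-wave frames": plane_wave_frames,
        "blocked-cable frames": waveback_collapse_profiles,
    }
    if kind not in factories:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {sorted(factories)}")
    return factories[kind]()
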