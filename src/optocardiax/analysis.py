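"""Measurements on voltage traces and frame stacks.

Conventions shared by all detectors:

* APD_X uses the relative-threshold rule V_th = V_max - X/100 (V_max - V_min),
  with V_max/V_min taken per beat window and sub-sample linear interpolation
  of the threshold crossings (APD is therefore invariant to affine rescaling
  of V).
* Activation time is the upstroke crossing of -40 mV (interpolated).
* Spiral tips (phase singularities) are located as intersections of the
  V = V_iso isoline with the dV/dt = 0 isoline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

__all__ = [
    "apd",
    "activation_time",
    "conduction_velocity",
    "wavelength",
    "dominant_frequencies",
    "tip_trajectory",
    "TipTrajectory",
    "core_diameter",
    "min_enclosing_circle",
    "restitution_slope",
    "detect_conduction_block",
    "vulnerable_window",
]

ACTIVATION_THRESHOLD = -40.0  # mV


def _cross_time(t, V, v_th, i, rising):
    """Linear-interpolated time of the threshold crossing between i and i+1."""
    v0, v1 = V[i], V[i + 1]
    if v1 == v0:
        return t[i]
    return t[i] + (v_th - v0) / (v1 - v0) * (t[i + 1] - t[i])


def apd(t, V, X: float = 90.0) -> List[dict]:
    """Per-AP action potential durations at X% repolarisation.

    Returns one dict per detected AP with keys ``t_start``, ``t_end``,
    ``apd``, ``v_max``, ``v_min``.  Traces whose voltage range is below
    40 mV contain no AP and yield an empty list.
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    if len(t) != len(V):
        raise ValueError("time and voltage vectors differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time vector must be strictly increasing")
    vrange = V.max() - V.min()
    if vrange < 40.0:
        return []

    # beat segmentation: upward crossings of a detection level
    v_det = V.min() + 0.4 * vrange
    up = np.where((V[:-1] < v_det) & (V[1:] >= v_det))[0]
    # debounce: merge crossings closer than 5 ms
    if len(up) > 1:
        keep = [up[0]]
        for i in up[1:]:
            if t[i] - t[keep[-1]] > 5.0:
                keep.append(i)
        up = np.array(keep)
    if len(up) == 0:
        # trace starts depolarised (e.g. an ideal triangle AP): one beat
        windows = [(0, len(V))]
    else:
        # windows run from just before each upstroke to the diastolic
        # minimum preceding the next upstroke (so the next AP's foot is
        # never counted as a late threshold crossing of this beat)
        bounds = [max(0, up[0] - 1)]
        for a, b in zip(up, up[1:]):
            seg = V[a:b]
            # last occurrence of the diastolic minimum, i.e. just before the
            # next upstroke's foot
            bounds.append(a + int(len(seg) - 1 - np.argmin(seg[::-1])))
        bounds.append(len(V))
        windows = list(zip(bounds, bounds[1:]))

    out = []
    for s, e in windows:
        Vw, tw = V[s:e], t[s:e]
        v_max, v_min = Vw.max(), Vw.min()
        if v_max - v_min < 40.0:
            continue
        v_th = v_max - X / 100.0 * (v_max - v_min)
        above = Vw >= v_th
        idx = np.where(above)[0]
        if len(idx) == 0:
            continue
        i0, i1 = idx[0], idx[-1]
        t0 = _cross_time(tw, Vw, v_th, i0 - 1, True) if i0 > 0 else tw[0]
        t1 = _cross_time(tw, Vw, v_th, i1, False) if i1 < len(Vw) - 1 else tw[-1]
        out.append({"t_start": float(t0), "t_end": float(t1),
                    "apd": float(t1 - t0), "v_max": float(v_max),
                    "v_min": float(v_min)})
    return out


def activation_time(t, V, threshold: float = ACTIVATION_THRESHOLD,
                    t_after: float = -np.inf) -> float:
    """First upstroke crossing of ``threshold`` after ``t_after``; NaN if none."""
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    ok = t[:-1] >= t_after
    cross = ok & (V[:-1] < threshold) & (V[1:] >= threshold)
    idx = np.where(cross)[0]
    if len(idx) == 0:
        return math.nan
    return float(_cross_time(t, V, threshold, idx[0], True))


def conduction_velocity(t_a, V_a, t_b, V_b, separation: float,
                        threshold: float = ACTIVATION_THRESHOLD,
                        t_after: float = -np.inf) -> float:
    """CV (cm/s) between two sites a known ``separation`` (cm) apart.

    Activation = upstroke crossing of ``threshold``.  Returns NaN (block
    indicator) if either site never activates.
    """
    ta = activation_time(t_a, V_a, threshold, t_after)
    tb = activation_time(t_b, V_b, threshold, t_after)
    if math.isnan(ta) or math.isnan(tb) or tb == ta:
        return math.nan
    return separation / abs(tb - ta) * 1000.0


def wavelength(cv_cm_s: float, apd90_ms: float) -> float:
    """Wavelength (cm) = CV x APD90, the primary definition used throughout."""
    return cv_cm_s * apd90_ms / 1000.0


def excited_extent(V_line: np.ndarray, dx: float, v_th: float) -> float:
    """Spatial extent (cm) of the largest contiguous region with V > v_th.

    Cross-check estimator of the wavelength: the instantaneous excited
    length behind a propagating front.
    """
    excited = np.asarray(V_line) > v_th
    best = run = 0
    for e in excited:
        run = run + 1 if e else 0
        best = max(best, run)
    return best * dx


def dominant_frequencies(t, V, n_peaks: int = 2) -> List[float]:
    """Frequencies (Hz) of the ``n_peaks`` strongest periodogram peaks.

    The trace is linearly detrended; peaks are returned strongest first
    (fundamental first for a harmonic signal).  A flat trace yields [].
    """
    t = np.asarray(t, float)
    V = np.asarray(V, float)
    if V.std() < 1e-9:
        return []
    dt_s = (t[1] - t[0]) / 1000.0
    freqs, power = signal.periodogram(signal.detrend(V), fs=1.0 / dt_s)
    pk, _ = signal.find_peaks(power)
    if len(pk) == 0:
        pk = np.array([np.argmax(power)])
    order = pk[np.argsort(power[pk])[::-1]]
    return [float(freqs[i]) for i in order[:n_peaks]]


# ---------------------------------------------------------------------------
# spiral-tip tracking
# ---------------------------------------------------------------------------

@dataclass
class TipTrajectory:
    """Phase-singularity points per frame with chirality, plus linked tracks."""

    times: List[float] = field(default_factory=list)
    points: List[np.ndarray] = field(default_factory=list)  # (k, 3): x, y, chirality
    tracks: List[List[Tuple[float, float, float]]] = field(default_factory=list)

    def count_per_frame(self) -> np.ndarray:
        return np.array([len(p) for p in self.points])

    def all_points(self) -> np.ndarray:
        pts = [p[:, :2] for p in self.points if len(p)]
        return np.vstack(pts) if pts else np.empty((0, 2))


def _isoline_intersections(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Intersection points (in array index coordinates) of the zero isolines
    of two scalar fields on the same grid."""
    from skimage import measure
    from shapely.geometry import LineString, MultiLineString

    ca = measure.find_contours(A, 0.0)
    cb = measure.find_contours(B, 0.0)
    if not ca or not cb:
        return np.empty((0, 2))
    la = MultiLineString([LineString(c[:, ::-1]) for c in ca if len(c) > 1])
    pts = []
    for c in cb:
        if len(c) < 2:
            continue
        inter = LineString(c[:, ::-1]).intersection(la)
        if inter.is_empty:
            continue
        for g in getattr(inter, "geoms", [inter]):
            if g.geom_type == "Point":
                pts.append((g.x, g.y))
            elif g.geom_type in ("MultiPoint",):
                pts.extend((q.x, q.y) for q in g.geoms)
            elif g.geom_type == "LineString":
                pts.append((g.centroid.x, g.centroid.y))
    return np.array(pts) if pts else np.empty((0, 2))


def tip_trajectory(frames: np.ndarray, times: Sequence[float], dx: float,
                   v_iso: float = -40.0, link_radius: float = 0.5,
                   merge_radius_nodes: float = 3.0) -> TipTrajectory:
    """Locate and link spiral tips in a stack of voltage frames.

    A tip is an intersection of the V = ``v_iso`` isoline with the dV/dt = 0
    isoline, computed between consecutive frames.  Chirality is the sign of
    the cross product grad(V) x grad(dV/dt) at the tip.  Tips closer than
    ``merge_radius_nodes`` grid points are merged; tips are linked across
    frames by nearest neighbour within ``link_radius`` cm.
    """
    frames = np.asarray(frames, float)
    nt = frames.shape[0]
    traj = TipTrajectory()
    for k in range(nt - 1):
        Vk = frames[k]
        dvdt = frames[k + 1] - Vk
        pts_idx = _isoline_intersections(Vk - v_iso, dvdt)
        rows = []
        for x_idx, y_idx in pts_idx:
            # x_idx along axis 0 is contour row; we emitted (col, row) => (y, x)
            xi, yi = y_idx, x_idx
            i = int(round(np.clip(xi, 1, Vk.shape[0] - 2)))
            jj = int(round(np.clip(yi, 1, Vk.shape[1] - 2)))
            gV = np.array([Vk[i + 1, jj] - Vk[i - 1, jj],
                           Vk[i, jj + 1] - Vk[i, jj - 1]])
            gD = np.array([dvdt[i + 1, jj] - dvdt[i - 1, jj],
                           dvdt[i, jj + 1] - dvdt[i, jj - 1]])
            chir = float(np.sign(gV[0] * gD[1] - gV[1] * gD[0]))
            rows.append((xi * dx, yi * dx, chir))
        # merge near-duplicates (contour discretisation artefacts)
        merged: List[Tuple[float, float, float]] = []
        for x, y, c in rows:
            for m in merged:
                if (x - m[0]) ** 2 + (y - m[1]) ** 2 < (merge_radius_nodes * dx) ** 2:
                    break
            else:
                merged.append((x, y, c))
        traj.times.append(float(times[k]))
        traj.points.append(np.array(merged) if merged else np.empty((0, 3)))

    # nearest-neighbour linking
    open_tracks: List[List[Tuple[float, float, float]]] = []
    for pts in traj.points:
        used = set()
        next_open = []
        for tr in open_tracks:
            x0, y0, _ = tr[-1]
            best, bd = None, link_radius ** 2
            for idx in range(len(pts)):
                if idx in used:
                    continue
                d = (pts[idx, 0] - x0) ** 2 + (pts[idx, 1] - y0) ** 2
                if d < bd:
                    best, bd = idx, d
            if best is not None:
                used.add(best)
                tr.append(tuple(pts[best]))
                next_open.append(tr)
            else:
                traj.tracks.append(tr)
        for idx in range(len(pts)):
            if idx not in used:
                next_open.append([tuple(pts[idx])])
        open_tracks = next_open
    traj.tracks.extend(open_tracks)
    return traj


# ---------------------------------------------------------------------------
# minimum enclosing circle (Welzl) and core diameter
# ---------------------------------------------------------------------------

def _circle_two(a, b):
    c = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
    r = math.dist(a, b) / 2.0
    return c, r


def _circumcircle(a, b, c):
    ax, ay = a; bx, by = b; cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-30:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    centre = (ux, uy)
    return centre, math.dist(centre, a)


def _in_circle(c, r, p, eps=1e-9):
    return math.dist(c, p) <= r + eps


def min_enclosing_circle(points) -> Tuple[Tuple[float, float], float]:
    """Smallest circle enclosing the points (Welzl's algorithm, iterative
    move-to-front).  Returns (centre, radius)."""
    pts = [tuple(map(float, p)) for p in np.atleast_2d(np.asarray(points, float))]
    if len(pts) == 0:
        return (0.0, 0.0), 0.0
    rng = np.random.default_rng(0)  # deterministic shuffle
    pts = [pts[i] for i in rng.permutation(len(pts))]
    c, r = pts[0], 0.0
    for i, p in enumerate(pts):
        if _in_circle(c, r, p):
            continue
        c, r = p, 0.0
        for j in range(i):
            q = pts[j]
            if _in_circle(c, r, q):
                continue
            c, r = _circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if _in_circle(c, r, s):
                    continue
                cc = _circumcircle(p, q, s)
                if cc is not None:
                    c, r = cc
    return c, r


def core_diameter(traj) -> float:
    """Diameter (cm) of the minimum circle enclosing a tip trajectory.

    Accepts a :class:`TipTrajectory` or an (n, 2) array of points.
    """
    pts = traj.all_points() if isinstance(traj, TipTrajectory) else np.atleast_2d(traj)
    if len(pts) == 0:
        return 0.0
    _, r = min_enclosing_circle(pts[:, :2])
    return 2.0 * r


def restitution_slope(curve) -> float:
    """Maximum adjacent-point finite-difference slope of APD90 vs DI.

    ``curve`` is a DataFrame with DI/APD90 columns (captured rows only) or a
    sequence of (DI, APD90) pairs; needs at least 4 points.
    """
    if hasattr(curve, "columns"):
        df = curve
        if "captured" in df.columns:
            df = df[df["captured"]]
        pairs = df[["DI", "APD90"]].to_numpy(float)
    else:
        pairs = np.asarray(list(curve), float)
    pairs = pairs[np.argsort(pairs[:, 0])]
    if len(pairs) < 4:
        raise ValueError("restitution slope needs at least 4 points")
    d = np.diff(pairs, axis=0)
    d = d[np.abs(d[:, 0]) > 1e-9]  # ignore duplicated DIs
    slopes = d[:, 1] / d[:, 0]
    return float(np.max(slopes))


# ---------------------------------------------------------------------------
# conduction block and vulnerable window
# ---------------------------------------------------------------------------

def detect_conduction_block(frames: np.ndarray, times: Sequence[float],
                            period: float,
                            threshold: float = ACTIVATION_THRESHOLD,
                            dt_block: float = 50.0,
                            mask: Optional[np.ndarray] = None) -> List[dict]:
    """Lines of conduction block in a frame stack.

    Beats are segmented into windows of ``period`` ms.  Within a beat, a node
    is blocked if it never crosses ``threshold`` while at least two of its
    4-neighbours activated within ``dt_block`` ms of each other.  Contiguous
    blocked nodes form one event.  Returns a list of dicts with keys
    ``t_window``, ``nodes`` (array of (x, y) indices) and ``time``.
    """
    frames = np.asarray(frames, float)
    times = np.asarray(times, float)
    nx, ny = frames.shape[1], frames.shape[2]
    if mask is None:
        mask = np.ones((nx, ny), bool)
    events = []
    t0 = times[0]
    while t0 < times[-1] - 1e-9:
        t1 = min(t0 + period, times[-1])
        sel = (times >= t0) & (times <= t1)
        if sel.sum() < 2:
            break
        F = frames[sel]
        tt = times[sel]
        act = np.full((nx, ny), np.nan)
        crossed = (F[:-1] < threshold) & (F[1:] >= threshold)
        for i in range(nx):
            for j in range(ny):
                k = np.argmax(crossed[:, i, j])
                if crossed[k, i, j]:
                    act[i, j] = tt[k]
        activated = np.isfinite(act)
        blocked = np.zeros((nx, ny), bool)
        for i in range(nx):
            for j in range(ny):
                if activated[i, j] or not mask[i, j]:
                    continue
                nb_t = []
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and activated[a, b]:
                        nb_t.append(act[a, b])
                if len(nb_t) >= 2 and (max(nb_t) - min(nb_t)) <= dt_block:
                    blocked[i, j] = True
        if blocked.any():
            from scipy import ndimage

            lab, n_lab = ndimage.label(blocked)
            for L in range(1, n_lab + 1):
                nodes = np.argwhere(lab == L)
                nb_times = [act[a, b] for (i0, j0) in nodes
                            for (a, b) in ((i0 + 1, j0), (i0 - 1, j0),
                                           (i0, j0 + 1), (i0, j0 - 1))
                            if 0 <= a < nx and 0 <= b < ny
                            and np.isfinite(act[a, b])]
                events.append({"t_window": (float(t0), float(t1)),
                               "nodes": nodes,
                               "time": float(np.median(nb_times))
                               if nb_times else float(t0)})
        t0 = t0 + period
    return events


def _segments(excited_row: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    segs = []
    in_run, s = False, 0
    for i, e in enumerate(excited_row):
        if e and not in_run:
            in_run, s = True, i
        elif not e and in_run:
            in_run = False
            segs.append((s, i))
    if in_run:
        segs.append((s, len(excited_row)))
    return segs


def vulnerable_window(profiles: np.ndarray, times: Sequence[float],
                      dx: float = 1.0,
                      v_th: Optional[float] = None) -> Optional[dict]:
    """Re-excitable gap opening behind a pinched waveback in 1D profiles.

    A vulnerable window opens when one excited segment (V > v_th) splits into
    two, leaving a recovered gap bounded by excitation on both sides; it
    closes when the gap disappears or loses a bounding segment.  Returns
    ``None`` if no window occurs, else a dict with ``t_start``, ``t_end``,
    ``x_range`` (cm) and ``reentry`` (True if the gap is re-excited from its
    leading edge afterwards, i.e. the propagation direction reverses).
    ``v_th`` defaults to the 90%-repolarisation threshold of the stack.
    """
    profiles = np.asarray(profiles, float)
    times = np.asarray(times, float)
    if v_th is None:
        v_max, v_min = profiles.max(), profiles.min()
        v_th = v_max - 0.9 * (v_max - v_min)
    exc = profiles > v_th

    window = None
    for k in range(len(times) - 1):
        segs0 = _segments(exc[k])
        segs1 = _segments(exc[k + 1])
        if window is None:
            # did a single segment split into >= 2 overlapping children?
            for s0 in segs0:
                children = [s1 for s1 in segs1
                            if s1[0] < s0[1] and s1[1] > s0[0]]
                if len(children) >= 2:
                    children.sort()
                    gap = (children[0][1], children[-1][0])
                    window = {"t_start": float(times[k + 1]),
                              "t_end": float(times[k + 1]),
                              "gap": gap}
                    break
        else:
            g0, g1 = window["gap"]
            # gap persists if a recovered interior region still overlaps it
            rec = ~exc[k + 1]
            inner = rec[g0:g1] if g1 > g0 else np.array([])
            segs = segs1
            bounded = any(s[1] <= g0 for s in segs) and any(s[0] >= g1 for s in segs)
            if inner.size and inner.any() and bounded:
                window["t_end"] = float(times[k + 1])
                # track the (possibly shrinking) recovered gap
                sub = _segments(rec)
                keep = [s for s in sub if s[0] < g1 and s[1] > g0]
                if keep:
                    window["gap"] = (keep[0][0], keep[0][1])
            else:
                # closed: decide whether closure came from re-excitation
                reentry = bool(exc[k + 1, g0:g1].any())
                return {"t_start": window["t_start"],
                        "t_end": float(times[k + 1]),
                        "x_range": (window["gap"][0] * dx,
                                    window["gap"][1] * dx),
                        "reentry": reentry}
    if window is not None:
        return {"t_start": window["t_start"], "t_end": window["t_end"],
                "x_range": (window["gap"][0] * dx, window["gap"][1] * dx),
                "reentry": False}
    return None
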