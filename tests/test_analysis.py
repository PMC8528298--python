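"""Measurement-operator tests against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optocardiax import analysis as an
from optocardiax import fixtures as fx


class TestAPD:
    def test_square_ap_all_levels(self):
        t, V = fx.square_ap(width=100.0)
        for X in (10, 30, 50, 70, 90):
            beats = an.apd(t, V, X=X)
            assert len(beats) == 1
            assert beats[0]["apd"] == pytest.approx(100.0, abs=0.2)

    def test_triangle_closed_form(self):
        # ramp (0, +20) -> (300, -80): V_th(90) = -70, crossing at t = 270
        t, V = fx.triangle_ap()
        beats = an.apd(t, V, X=90.0)
        assert len(beats) == 1
        assert beats[0]["apd"] == pytest.approx(270.0, abs=0.2)

    def test_small_range_means_no_ap(self):
        t = np.arange(0.0, 100.0, 0.1)
        assert an.apd(t, np.full_like(t, -80.0)) == []
        assert an.apd(t, -80.0 + 10.0 * np.sin(t / 10)) == []

    def test_multi_beat_segmentation(self):
        t1, V1 = fx.square_ap(width=80.0, total=400.0)
        V = np.concatenate([V1, V1, V1])
        t = np.arange(len(V)) * 0.1
        beats = an.apd(t, V, X=50.0)
        assert len(beats) == 3
        assert all(b["apd"] == pytest.approx(80.0, abs=0.2) for b in beats)

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(0.5, 10.0), offset=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, scale, offset):
        t, V = fx.triangle_ap()
        a = an.apd(t, V, X=90.0)[0]["apd"]
        b = an.apd(t, scale * V + offset, X=90.0)[0]["apd"]
        assert b == pytest.approx(a, abs=1e-9)

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(ValueError):
            an.apd([0.0, 1.0, 1.0], [-80.0, 0.0, -80.0])


class TestConductionVelocity:
    def test_arithmetic(self):
        t = np.arange(0.0, 50.0, 0.1)
        mk = lambda t0: np.where(t >= t0, 20.0, -80.0)
        cv = an.conduction_velocity(t, mk(10.0), t, mk(20.0), 0.69)
        assert cv == pytest.approx(69.0, rel=1e-3)

    def test_block_indicator(self):
        t = np.arange(0.0, 50.0, 0.1)
        active = np.where(t >= 10.0, 20.0, -80.0)
        silent = np.full_like(t, -80.0)
        assert math.isnan(an.conduction_velocity(t, active, t, silent, 0.69))

    def test_wavelength_product(self):
        assert an.wavelength(50.0, 100.0) == pytest.approx(5.0)

    def test_excited_extent_cross_check(self):
        # spatial wavelength estimator: largest contiguous excited run
        row = np.full(200, -80.0)
        row[40:160] = 10.0
        assert an.excited_extent(row, dx=0.022, v_th=-60.0) == \
            pytest.approx(120 * 0.022)


class TestSpectra:
    def test_pure_tone(self):
        t = np.arange(0.0, 2000.0, 1.0)  # 1 kHz sampling, 2 s
        V = np.sin(2 * np.pi * 11.5 * t / 1000.0)
        f = an.dominant_frequencies(t, V, n_peaks=1)
        assert f[0] == pytest.approx(11.5, abs=0.5)

    def test_two_tone_power_ordering(self):
        t = np.arange(0.0, 4000.0, 1.0)
        V = 2.0 * np.sin(2 * np.pi * 3 * t / 1000) \
            + 1.0 * np.sin(2 * np.pi * 7 * t / 1000)
        f = an.dominant_frequencies(t, V, n_peaks=2)
        assert f[0] == pytest.approx(3.0, abs=0.3)
        assert f[1] == pytest.approx(7.0, abs=0.3)

    def test_flat_trace(self):
        t = np.arange(0.0, 1000.0, 1.0)
        assert an.dominant_frequencies(t, np.zeros_like(t)) == []


class TestTipTracking:
    def test_rotating_spiral_single_fixed_tip(self):
        frames, times, centre = fx.rotating_spiral(n=96, n_frames=30)
        traj = an.tip_trajectory(frames, times, dx=0.022)
        counts = traj.count_per_frame()
        assert np.median(counts) == 1
        pts = traj.all_points()
        # tip stays near the rotation centre: enclosing circle is small
        d = an.core_diameter(traj)
        assert d < 0.5  # cm; centre drift only
        assert np.hypot(*(pts.mean(0) - np.array(centre))) < 0.2

    def test_plane_wave_has_no_singularity(self):
        frames, times = fx.plane_wave_frames()
        traj = an.tip_trajectory(frames, times, dx=0.022)
        assert traj.count_per_frame().max(initial=0) == 0

    def test_vortex_pair_parity_and_charge(self):
        """A smooth vortex-antivortex phase field has exactly two
        singularities (pair creation parity) of opposite chirality."""
        n = 96
        X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        c1, c2 = (30.0, 48.0), (66.0, 48.0)
        th = (np.arctan2(Y - c1[1], X - c1[0])
              - np.arctan2(Y - c2[1], X - c2[0]))
        times = np.arange(10) * 5.0
        frames = np.array([-60.0 + 45.0 * np.cos(th - 2 * np.pi * t / 87.0)
                           for t in times])
        traj = an.tip_trajectory(frames, times, dx=0.022,
                                 merge_radius_nodes=5.0)
        counts = traj.count_per_frame()
        assert np.median(counts) == 2
        chir = [p[:, 2].sum() for p in traj.points if len(p) == 2]
        assert chir and np.allclose(chir, 0.0)  # net topological charge 0


class TestEnclosingCircle:
    def brute_force(self, pts):
        """Smallest circle through all pairs/triples containing every point."""
        pts = [tuple(p) for p in pts]
        best = None
        cands = []
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                cands.append(an._circle_two(pts[i], pts[j]))
                for k in range(j + 1, len(pts)):
                    cc = an._circumcircle(pts[i], pts[j], pts[k])
                    if cc:
                        cands.append(cc)
        if len(pts) == 1:
            return pts[0], 0.0
        for c, r in cands:
            if all(math.dist(c, p) <= r + 1e-9 for p in pts):
                if best is None or r < best[1]:
                    best = (c, r)
        return best

    def test_single_point(self):
        assert an.core_diameter(np.array([[1.0, 2.0]])) == 0.0

    def test_right_triangle_hypotenuse(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]])
        assert an.core_diameter(pts) == pytest.approx(5.0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
                    min_size=2, max_size=25))
    def test_matches_brute_force(self, pts):
        pts = np.array(pts)
        (_, r_w) = an.min_enclosing_circle(pts)
        (_, r_b) = self.brute_force(pts)
        assert r_w == pytest.approx(r_b, abs=1e-9)


class TestRestitutionSlope:
    def test_linear_curve(self):
        di = np.array([50.0, 120.0, 300.0, 600.0, 900.0])
        pairs = np.c_[di, 200.0 + 0.05 * di]
        assert an.restitution_slope(pairs) == pytest.approx(0.05)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        di = np.array([60.0, 100.0, 200.0, 400.0, 800.0])
        apd = 180.0 + 30.0 * (1 - np.exp(-di / 150.0))
        pairs = np.c_[di, apd]
        s1 = an.restitution_slope(pairs)
        s2 = an.restitution_slope(pairs[rng.permutation(5)])
        assert s1 == s2

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            an.restitution_slope([(100.0, 200.0), (200.0, 210.0)])


class TestConductionBlock:
    def test_plane_wave_clean(self):
        frames, times = fx.plane_wave_frames()
        events = an.detect_conduction_block(frames, times, period=times[-1] + 1)
        assert events == []

    def test_inexcitable_patch_positive_control(self, healthy, healthy_rest):
        """A wave forced around a gNa = 0 patch leaves a block line at the
        patch; the detector must find it there and nowhere else."""
        from optocardiax import solver
        from optocardiax.protocols import Region, paced_stim

        # the patch must be larger than the electrotonic space constant
        # (~6 nodes) so its interior is not depolarised passively
        dom = solver.TissueDomain.create(100, 60, healthy,
                                         cell_state=healthy_rest)
        gna = np.ones(dom.n_nodes)
        xs, ys = dom.grid_coords()
        patch = (xs >= 30) & (xs < 70) & (ys >= 10) & (ys < 50)
        gna[patch] = 0.0
        dom.gna_scale = gna
        stim = paced_stim(amplitude=30.0, cycle_length=1e9, duration=2.0,
                          region=Region(x1=4), n_pulses=1)
        rec = solver.run(dom, 80.0, stim=stim, frame_every=2.0)
        events = an.detect_conduction_block(
            np.nan_to_num(rec.frames, nan=-85.0), rec.frame_t, period=90.0)
        assert events
        nodes = np.vstack([e["nodes"] for e in events])
        assert np.all((nodes[:, 0] >= 30) & (nodes[:, 0] < 70))
        assert np.all((nodes[:, 1] >= 10) & (nodes[:, 1] < 50))


class TestVulnerableWindow:
    def test_constructed_gap_bounds(self):
        profiles, times, (t0, t1) = fx.waveback_collapse_profiles()
        w = an.vulnerable_window(profiles, times, dx=0.022)
        assert w is not None
        assert w["t_start"] == pytest.approx(t0, abs=10.0)
        assert w["t_end"] == pytest.approx(t1, abs=10.0)
        assert w["reentry"]

    def test_plane_wave_train_has_no_window(self):
        # two rightward bands entering from the left edge: gaps between
        # waves travel but never open by waveback collapse
        nx, nf = 200, 40
        x = np.arange(nx)
        profiles = np.full((nf, nx), -80.0)
        for k in range(nf):
            f1 = 5 * k
            for front in (f1, f1 - 100):
                exc = (x <= front) & (x >= front - 60)
                profiles[k, exc] = 15.0
        assert an.vulnerable_window(profiles, np.arange(nf) * 10.0) is None
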