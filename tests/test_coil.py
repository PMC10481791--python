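"""Filament coils: builders, Biot-Savart fields, Neumann inductances."""

import numpy as np
import pytest

import coilcore as cc
from coilcore.coil import SingularityError, _disc_fill
from coilcore.materials import MU0


class TestBuilders:
    def test_loop_segment_lengths(self):
        R = 0.01
        loop = cc.circular_loop(R, 0.001, n_segments=256, n_filaments=1)
        assert loop.n_segments == 256
        assert loop.lengths == pytest.approx(
            np.full(256, 2 * np.pi * R / 256), rel=1e-3)

    def test_loop_closure_and_weights(self):
        loop = cc.circular_loop(0.01, 0.002, n_segments=64, n_filaments=7)
        # each parallel filament forms a closed path: segment vectors sum to 0
        for k in range(7):
            seg = loop.segments[k * 64:(k + 1) * 64]
            assert np.linalg.norm(seg.sum(axis=0)) < 1e-12
        # net current through a cross-section equals I0 (weights sum to 1)
        assert loop.weight[:64].size * loop.weight[0] * 7 == pytest.approx(64)
        assert np.allclose(loop.weight, 1 / 7)

    def test_disc_fill_inside_radius(self):
        pts = _disc_fill(50, 1e-3)
        assert np.all(np.linalg.norm(pts, axis=1) <= 1e-3)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            cc.circular_loop(-0.01, 0.001)
        with pytest.raises(ValueError):
            cc.helical_spiral(0.009, 20, [5e-3] * 10)  # short pitch profile

    def test_rat_template_extent(self):
        # 20 turns, radius 9 mm, linearly tapered pitch totalling 110 mm
        pitch = np.linspace(7.5e-3, 3.5e-3, 20)
        sp = cc.helical_spiral(9e-3, 20, pitch, skew_angle=np.deg2rad(15))
        z = np.concatenate([sp.start[:, 2], sp.end[:, 2]])
        assert z.max() - z.min() <= 0.110 + 1e-9
        assert z.max() - z.min() == pytest.approx(0.110, rel=1e-6)

    def test_twist_lengthens_wire(self):
        kw = dict(radius=9e-3, n_turns=5, pitch=5e-3, bundle_radius=2e-3,
                  n_bundle_filaments=7, segments_per_turn=48)
        straight = cc.helical_spiral(**kw)
        twisted = cc.helical_spiral(**kw, twist_pitch=30e-3)
        assert twisted.total_wire_length > straight.total_wire_length

    def test_make_coil_dispatch(self):
        coil = cc.make_coil({"type": "circular_loop", "radius": 0.01,
                             "n_segments": 32})
        assert coil.n_segments == 32
        with pytest.raises(ValueError):
            cc.make_coil({"type": "toroid", "radius": 0.01})


class TestLitzBundle:
    def test_hundred_strand_bundle(self):
        assert cc.litz_bundle_radius(0.15e-3, 100) == pytest.approx(1.663e-3,
                                                                    rel=1e-3)

    def test_single_wire(self):
        assert cc.litz_bundle_radius(2e-3, 1) == 2e-3

    def test_linear_in_wire_radius(self):
        assert cc.litz_bundle_radius(0.30e-3, 100) == pytest.approx(
            2 * cc.litz_bundle_radius(0.15e-3, 100))

    def test_untabulated_count(self):
        with pytest.raises(ValueError, match="packing"):
            cc.litz_bundle_radius(0.15e-3, 101)


class TestPrimaryFields:
    def test_loop_center_field(self):
        R, I = 0.01, 2.0
        loop = cc.circular_loop(R, n_segments=512, I0=I)
        B = cc.primary_B(loop, [[0, 0, 0]])[0]
        assert np.linalg.norm(B) == pytest.approx(MU0 * I / (2 * R), rel=1e-3)
        assert abs(B[0]) < 1e-12 and abs(B[1]) < 1e-12

    def test_on_axis_closed_form(self):
        R, I, z = 0.01, 1.0, 0.007
        loop = cc.circular_loop(R, n_segments=512, I0=I)
        B = cc.primary_B(loop, [[0, 0, z]])[0]
        expect = MU0 * I * R**2 / (2 * (R**2 + z**2) ** 1.5)
        assert B[2] == pytest.approx(expect, rel=1e-3)

    def test_H_is_B_over_mu0_and_linearity(self):
        loop = cc.circular_loop(0.01, n_segments=64, I0=3.0)
        pts = np.array([[0.005, 0.002, 0.004], [0, 0, 0.02]])
        f = cc.primary_fields(loop, pts)
        assert np.allclose(f["H"], f["B"] / MU0)
        loop10 = cc.circular_loop(0.01, n_segments=64, I0=30.0)
        f10 = cc.primary_fields(loop10, pts)
        for k in ("A", "B", "H"):
            assert np.allclose(f10[k], 10 * f[k], rtol=1e-13)

    def test_reversal_negates_fields(self):
        loop = cc.circular_loop(0.01, n_segments=64, I0=2.0)
        pts = np.array([[0.004, -0.001, 0.003]])
        f = cc.primary_fields(loop, pts)
        r = cc.primary_fields(loop.reversed(), pts)
        for k in ("A", "B", "H"):
            assert np.allclose(r[k], -f[k], rtol=1e-13)

    def test_point_on_filament_rejected(self):
        loop = cc.circular_loop(0.01, n_segments=64)
        with pytest.raises(SingularityError):
            cc.primary_B(loop, loop.midpoints[3][None])

    def test_divergence_free(self):
        loop = cc.circular_loop(0.01, n_segments=128, I0=1.0)
        h = 1e-4
        base = np.array([0.004, 0.003, 0.005])
        div = 0.0
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            Bp = cc.primary_B(loop, (base + e)[None])[0][ax]
            Bm = cc.primary_B(loop, (base - e)[None])[0][ax]
            div += (Bp - Bm) / (2 * h)
        Bmax = np.linalg.norm(cc.primary_B(loop, base[None])[0])
        assert abs(div) <= 1e-6 * Bmax / h


class TestPrimaryE:
    def test_zero_rate(self):
        loop = cc.circular_loop(0.01, n_segments=64)
        pts = np.array([[0.004, 0.0, 0.002]])
        assert np.allclose(cc.primary_E(loop, pts, 0.0), 0.0)

    def test_linear_in_rate(self):
        loop = cc.circular_loop(0.01, n_segments=64, I0=5.0)
        pts = np.array([[0.004, 0.0, 0.002]])
        e1 = cc.primary_E(loop, pts, 1e6)
        e2 = cc.primary_E(loop, pts, 2e6)
        assert np.allclose(e2, 2 * e1, rtol=1e-13)

    def test_against_dense_quadrature_oracle(self):
        # E = -(dI/dt) * (mu0/4pi) * contour integral dl'/|r - r'|,
        # evaluated here by independent dense trapezoid quadrature
        R, dIdt = 0.01, 1e6
        p = np.array([0.004, 0.0, 0.006])
        th = np.linspace(0, 2 * np.pi, 200001)[:-1]
        src = np.column_stack([R * np.cos(th), R * np.sin(th), 0 * th])
        dl = np.column_stack([-R * np.sin(th), R * np.cos(th), 0 * th]) * (
            2 * np.pi / 200000)
        oracle = -dIdt * MU0 / (4 * np.pi) * (
            dl / np.linalg.norm(p - src, axis=1)[:, None]).sum(axis=0)
        loop = cc.circular_loop(R, n_segments=512, I0=3.0)
        got = cc.primary_E(loop, p[None], dIdt)[0]
        assert np.allclose(got, oracle, rtol=2e-4, atol=1e-12)


class TestInductance:
    def test_perpendicular_segments_no_coupling(self):
        a = cc.FilamentCoil([[0, 0, 0]], [[1e-2, 0, 0]], [1.0])
        b = cc.FilamentCoil([[0, 1e-2, 1e-2]], [[0, 2e-2, 1e-2]], [1.0])
        assert cc.mutual_inductance(a, b) == pytest.approx(0.0, abs=1e-18)

    def test_loop_self_inductance_thick_wire_formula(self, small_loop):
        # uniform-current loop: L = mu0 R (ln(8R/a) - 1.75)
        R, a = 0.01, 0.001
        expect = MU0 * R * (np.log(8 * R / a) - 1.75)
        got = cc.self_inductance(small_loop)
        assert got == pytest.approx(expect, rel=0.03)

    def test_thin_loop_warns(self):
        loop = cc.circular_loop(0.01, n_segments=512, n_filaments=1)
        with pytest.warns(UserWarning, match="mesh-dependent"):
            cc.self_inductance(loop)

    def test_self_inductance_independent_of_current(self, small_loop):
        big = cc.FilamentCoil(small_loop.start, small_loop.end,
                              small_loop.weight, I0=1e4,
                              n_parallel=small_loop.n_parallel)
        assert cc.self_inductance(big) == pytest.approx(
            cc.self_inductance(small_loop), rel=1e-13)

    def test_coaxial_loops_dipole_limit(self):
        # mutual inductance of distant coaxial loops: mu0 pi R^4 / (2 d^3)
        R, d = 0.01, 0.1
        a = cc.circular_loop(R, n_segments=256)
        b = cc.circular_loop(R, n_segments=256, center=(0, 0, d))
        expect = MU0 * np.pi * R**4 / (2 * d**3)
        assert cc.mutual_inductance(a, b) == pytest.approx(expect, rel=0.02)

    def test_mutual_symmetry(self):
        a = cc.circular_loop(0.01, n_segments=128)
        b = cc.circular_loop(0.015, n_segments=96, center=(0.004, 0, 0.03))
        assert cc.mutual_inductance(a, b) == pytest.approx(
            cc.mutual_inductance(b, a), rel=1e-14)

    def test_perpendicular_centered_loops_decouple(self):
        a = cc.circular_loop(0.01, n_segments=128)
        b = cc.circular_loop(0.012, n_segments=128, normal=(1, 0, 0))
        Lm = cc.mutual_inductance(a, b)
        La = cc.self_inductance(cc.circular_loop(0.01, 0.001, 128, 9))
        assert abs(Lm) < 1e-6 * La

    def test_intersecting_coils_rejected(self):
        a = cc.circular_loop(0.01, n_segments=64)
        with pytest.raises(SingularityError):
            cc.mutual_inductance(a, a)
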