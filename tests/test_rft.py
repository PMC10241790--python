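"""Resistive-force-theory twin: coefficients, drag integrals, trends."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nutbolt.params import ComplexParams
from nutbolt.geometry import Centreline, fibre_centreline
from nutbolt.motions import Rest, RotationZ, TranslationZ
from nutbolt.rft import (fibre_friction_coefficients,
                         tail_friction_coefficients,
                         groove_sliding_coefficient, friction_for,
                         element_drag_integrals, assemble_rft_coefficients,
                         rft_translocation_speed)
from nutbolt.mobility import limiting_translocation_speed

MU = 1.0e-3


def straight_rod(direction, L=10.0, n=41):
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    s = np.linspace(0.0, L, n)
    pts = s[:, None] * direction[None, :]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    nvec = np.cross(direction, ref)
    nvec /= np.linalg.norm(nvec)
    b = np.cross(direction, nvec)
    frames = np.broadcast_to(np.stack([direction, nvec, b]), (n, 3, 3)).copy()
    return Centreline(points=pts, arclength=s, frames=frames)


class TestFrictionCoefficients:
    def test_near_wall_value_at_baseline(self):
        zp, zpar = fibre_friction_coefficients(MU, d=2.0, r_fib=1.0)
        assert zp == pytest.approx(0.00906, abs=5e-6)
        assert zpar == pytest.approx(zp / 2.0, rel=1e-15)

    def test_log_argument_e_gives_4_pi_mu(self):
        zp, _ = fibre_friction_coefficients(MU, d=math.e / 2.0, r_fib=1.0)
        assert zp == pytest.approx(4.0 * math.pi * MU, rel=1e-12)

    @given(st.floats(min_value=0.6, max_value=50.0),
           st.floats(min_value=0.05, max_value=1.0))
    def test_parallel_is_half_perpendicular(self, d, r):
        if 2.0 * d / r <= 1.05:
            return
        zp, zpar = fibre_friction_coefficients(MU, d, r)
        assert zpar == pytest.approx(0.5 * zp, rel=1e-15)
        assert zp > 0

    def test_invalid_log_argument(self):
        with pytest.raises(ValueError):
            fibre_friction_coefficients(MU, d=0.4, r_fib=1.0)

    def test_groove_coefficient_baseline(self):
        zg = groove_sliding_coefficient(MU, r_fib=1.0, h_gap=0.5, f_cov=0.5)
        assert zg == pytest.approx(MU * 2.0 * math.pi, rel=1e-12)

    def test_groove_couette_scaling(self):
        z1 = groove_sliding_coefficient(MU, 1.0, 0.5, 0.5)
        z2 = groove_sliding_coefficient(MU, 1.0, 1.0, 0.5)
        assert z2 == pytest.approx(z1 / 2.0, rel=1e-12)
        assert groove_sliding_coefficient(MU, 1.0, 0.5, 0.0) == 0.0
        with pytest.raises(ValueError):
            groove_sliding_coefficient(MU, 1.0, 0.0, 0.5)

    def test_tail_coefficients_ordering(self):
        zp, zpar = tail_friction_coefficients(MU, 220.0, 7.0)
        assert 0 < zpar < zp

    def test_head_coefficients(self):
        fc = friction_for(ComplexParams())
        assert fc.head_translation == pytest.approx(6 * math.pi * MU * 30.0)
        assert fc.head_rotation == pytest.approx(8 * math.pi * MU * 30.0 ** 3)


class TestDragIntegrals:
    def test_straight_rod_axial_translation(self):
        rod = straight_rod([0, 0, 1.0], L=10.0)
        F_z, M_z = element_drag_integrals(rod, TranslationZ(2.0), 1.0, 0.5)
        assert F_z == pytest.approx(-0.5 * 10.0 * 2.0, rel=1e-12)
        assert M_z == pytest.approx(0.0, abs=1e-12)

    def test_straight_rod_perpendicular_translation(self):
        rod = straight_rod([1.0, 0, 0], L=10.0)
        F_z, _ = element_drag_integrals(rod, TranslationZ(2.0), 1.0, 0.5)
        assert F_z == pytest.approx(-1.0 * 10.0 * 2.0, rel=1e-12)

    def test_rotating_helix_generates_thrust_with_chirality_sign(self):
        # a rotating helix produces nonzero axial thrust; mirrored helices
        # thrust oppositely while the rotation torque is mirror-invariant
        results = {}
        for h in (1, -1):
            p = ComplexParams(model=2, h=h)
            cl = fibre_centreline(p, 801)
            results[h] = element_drag_integrals(cl, RotationZ(1.0), 1.0, 0.5)
        assert results[1][0] != 0.0
        assert results[-1][0] == pytest.approx(-results[1][0], rel=1e-12)
        assert results[-1][1] == pytest.approx(results[1][1], rel=1e-12)

    def test_quadrature_step_independence(self):
        p = ComplexParams(model=2)
        coarse = fibre_centreline(p, 801)
        fine = fibre_centreline(p, 6401)
        Fc, Mc = element_drag_integrals(coarse, RotationZ(1.0), 1.0, 0.5)
        Ff, Mf = element_drag_integrals(fine, RotationZ(1.0), 1.0, 0.5)
        assert Fc == pytest.approx(Ff, rel=1e-4)
        assert Mc == pytest.approx(Mf, rel=1e-4)

    def test_locality_additivity(self):
        # RFT is strictly local: halves of the fibre contribute additively
        p = ComplexParams(model=1)
        full = fibre_centreline(p, 1601)
        half = len(full.arclength) // 2
        lo = Centreline(full.points[:half + 1], full.arclength[:half + 1],
                        full.frames[:half + 1])
        hi = Centreline(full.points[half:], full.arclength[half:],
                        full.frames[half:])
        m = RotationZ(3.0)
        F = element_drag_integrals(full, m, 1.0, 0.5)
        Fl = element_drag_integrals(lo, m, 1.0, 0.5)
        Fh = element_drag_integrals(hi, m, 1.0, 0.5)
        assert F[0] == pytest.approx(Fl[0] + Fh[0], rel=1e-12)
        assert F[1] == pytest.approx(Fl[1] + Fh[1], rel=1e-12)

    def test_missing_frames_rejected(self):
        cl = Centreline(points=np.zeros((3, 3)),
                        arclength=np.array([0.0, 1.0, 2.0]), frames=None)
        with pytest.raises(ValueError):
            element_drag_integrals(cl, Rest(), 1.0, 0.5)


class TestRftCoefficients:
    def test_model1_c3_closed_form(self):
        # phage translating axially: fibre tangent makes angle alpha with z,
        # tail tilted 45 deg, head Stokes drag -- all projections constant
        p = ComplexParams(model=1)
        fc = friction_for(p)
        C = assemble_rft_coefficients(p, fc)
        ca, sa = math.cos(p.alpha_rad), math.sin(p.alpha_rad)
        fib = -p.L_fib * (fc.zeta_par_fib * ca ** 2 + fc.zeta_perp_fib * sa ** 2)
        ct = math.cos(math.radians(p.tail_tilt))
        st_ = math.sin(math.radians(p.tail_tilt))
        tail = -p.L_t * (fc.zeta_par_tail * ct ** 2 + fc.zeta_perp_tail * st_ ** 2)
        head = -fc.head_translation
        assert C.C3 == pytest.approx(fib + tail + head, rel=1e-10)

    def test_flagellum_rotation_drives_fibre_only(self):
        # with the phage at rest, only the fibre (whose drag is relative to
        # the moving wall) carries load in the local theory
        p = ComplexParams(model=1)
        C = assemble_rft_coefficients(p)
        cl = fibre_centreline(p, 801)
        fc = friction_for(p)
        from nutbolt.rft import nearest_wall_points
        F_fib, M_fib = element_drag_integrals(
            cl, Rest(), fc.zeta_perp_fib, fc.zeta_par_fib,
            wall_motion=RotationZ(1.0), R_fl=p.R_fl)
        assert C.C1 == pytest.approx(F_fib, rel=1e-12)
        assert C.C4 == pytest.approx(M_fib, rel=1e-12)

    def test_model2_returns_four_coefficients(self):
        C = assemble_rft_coefficients(ComplexParams(model=2))
        assert math.isnan(C.C2) and math.isnan(C.C5)
        assert C.C3 < 0 and C.C6 < 0

    def test_smaller_zeta_slows_rft_model1(self):
        # substituting the Stokes-extracted (smaller) friction coefficient
        # lowers the RFT translocation speed toward the FEM curve
        p = ComplexParams(model=1)
        u_default = abs(rft_translocation_speed(
            p, friction_for(p, zeta_perp_fib=0.00906)).U)
        u_stokes = abs(rft_translocation_speed(
            p, friction_for(p, zeta_perp_fib=0.00763)).U)
        assert u_stokes < u_default


class TestRftTrends:
    @pytest.mark.parametrize("model,direction", [(1, -1), (2, 1)])
    def test_tail_length_trends(self, model, direction):
        # |U| decays with tail length for the smooth flagellum and grows
        # toward the rigid-riding limit for the grooved one
        for L_fib in (200.0, 80.0):
            us = [abs(rft_translocation_speed(
                ComplexParams(model=model, L_fib=L_fib, L_t=lt)).U)
                for lt in (60.0, 120.0, 220.0, 440.0, 880.0)]
            diffs = np.diff(us)
            assert np.all(direction * diffs > 0)

    def test_model2_below_limit_and_monotone_approach(self):
        p0 = ComplexParams(model=2)
        lim = limiting_translocation_speed(p0.omega_fl, p0.R_fl, p0.alpha)
        errs = []
        for lt in (110.0, 220.0, 440.0, 880.0, 1760.0, 3520.0):
            u = abs(rft_translocation_speed(p0.with_(L_t=lt)).U)
            assert u < lim
            errs.append(lim - u)
        assert np.all(np.diff(errs) < 0)

    def test_head_size_trend_model2(self):
        # a bigger head, like a longer tail, suppresses phage co-rotation,
        # moving |U| up toward the rigid-riding limit
        us = [abs(rft_translocation_speed(
            ComplexParams(model=2, a_h=ah)).U) for ah in (15.0, 30.0, 60.0)]
        assert us[0] < us[1] < us[2]

    def test_groove_coverage_trend_model2(self):
        us = [abs(rft_translocation_speed(
            ComplexParams(model=2, f_cov=fc)).U)
            for fc in (0.25, 0.5, 0.75)]
        assert us[0] > us[1] > us[2]

    def test_speed_scale_is_order_micron_per_second(self):
        for model in (1, 2):
            u = abs(rft_translocation_speed(ComplexParams(model=model)).U)
            assert 100.0 < u < 10000.0   # 0.1..10 um/s

    def test_chirality_antisymmetry(self):
        for model in (1, 2):
            p = ComplexParams(model=model)
            u = rft_translocation_speed(p).U
            um = rft_translocation_speed(p.with_(h=-1)).U
            assert um == pytest.approx(-u, rel=1e-10)
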