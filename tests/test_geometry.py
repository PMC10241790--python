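"""Geometry: centrelines, frames, scene surfaces."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nutbolt.params import ComplexParams
from nutbolt.geometry import (build_bodies, build_scene, fibre_centreline,
                              fibre_centreline_points, fibre_frame,
                              gap_sheet_points, tail_axis)


class TestCentreline:
    def test_model1_start_point(self):
        p = ComplexParams(model=1, z_0=0.0)   # R_fl=10, d=2
        cl = fibre_centreline(p, 5)
        np.testing.assert_allclose(cl.points[0], [12.0, 0.0, 0.0], atol=1e-12)

    def test_model2_lies_on_flagellum_surface(self):
        p = ComplexParams(model=2)
        cl = fibre_centreline(p, 257)
        rho = np.hypot(cl.points[:, 0], cl.points[:, 1])
        np.testing.assert_allclose(rho, p.R_fl, rtol=1e-12)

    def test_axial_rise_per_turn(self):
        # one turn spans delta_l = 2*pi*R/sin(a); the rise is delta_l*cos(a)
        p = ComplexParams(model=2, L_fib=500.0)
        rise_expected = 2 * math.pi * p.R_fl / math.tan(p.alpha_rad)
        assert rise_expected == pytest.approx(50.88, abs=0.01)
        dl = 2 * math.pi * p.R_fl / math.sin(p.alpha_rad)
        pts = fibre_centreline_points(p, np.array([0.0, dl]))
        np.testing.assert_allclose(pts[1, :2], pts[0, :2], atol=1e-9)
        assert pts[1, 2] - pts[0, 2] == pytest.approx(rise_expected, rel=1e-12)

    def test_number_of_turns_at_defaults(self):
        p = ComplexParams(model=2)
        turns = p.L_fib * math.sin(p.alpha_rad) / (2 * math.pi * p.R_fl)
        assert turns == pytest.approx(2.473, abs=0.001)

    def test_arclength_strictly_increasing_and_unit_speed(self):
        p = ComplexParams(model=1)
        cl = fibre_centreline(p, 2001)
        assert np.all(np.diff(cl.arclength) > 0)
        assert cl.arclength[0] == 0.0
        assert cl.arclength[-1] == p.L_fib
        seglen = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        np.testing.assert_allclose(seglen, np.diff(cl.arclength), rtol=1e-5)

    def test_tangent_matches_finite_difference(self):
        p = ComplexParams(model=2)
        cl = fibre_centreline(p, 4001)
        fd = np.gradient(cl.points, cl.arclength, axis=0)
        # second-order finite differences: error ~ (dl^2/6)*|t''| ~ 1.4e-6
        np.testing.assert_allclose(cl.frames[1:-1, 0, :], fd[1:-1], atol=5e-6)

    def test_mirror_symmetry_of_centreline(self):
        p = ComplexParams(model=1)
        cl = fibre_centreline(p, 101)
        clm = fibre_centreline(p.with_(h=-1), 101)
        mirrored = cl.points * np.array([1.0, -1.0, 1.0])
        np.testing.assert_allclose(clm.points, mirrored, atol=1e-9)

    def test_n_points_validation(self):
        with pytest.raises(ValueError):
            fibre_centreline(ComplexParams(), 1)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ComplexParams(model=3)
        with pytest.raises(ValueError):
            ComplexParams(L_fib=-1.0)


class TestFrames:
    @given(st.floats(min_value=0.0, max_value=200.0),
           st.sampled_from([1, -1]),
           st.floats(min_value=5.0, max_value=85.0))
    def test_orthonormality(self, l, h, alpha):
        p = ComplexParams(model=2, h=h, alpha=alpha)
        F = fibre_frame(p, l)
        np.testing.assert_allclose(F @ F.T, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(np.cross(F[0], F[1]), F[2], atol=1e-12)

    def test_binormal_z_component_is_sin_alpha(self):
        p = ComplexParams(model=2, alpha=51.0)
        for l in (0.0, 37.0, 180.0):
            F = fibre_frame(p, l)
            assert abs(F[2, 2]) == pytest.approx(math.sin(math.radians(51.0)),
                                                 rel=1e-12)
            assert abs(F[2, 2]) == pytest.approx(0.7771, abs=1e-4)

    def test_normal_points_toward_axis(self):
        p = ComplexParams(model=2)
        cl = fibre_centreline(p, 33)
        radial = cl.points.copy()
        radial[:, 2] = 0.0
        inward = -radial / np.linalg.norm(radial, axis=1)[:, None]
        np.testing.assert_allclose(cl.frames[:, 1, :], inward, atol=1e-12)

    def test_small_helix_angle_binormal_in_xy_plane(self):
        p = ComplexParams(model=2, alpha=1e-4)
        F = fibre_frame(p, 50.0)
        assert abs(F[2, 2]) < 1e-5

    def test_out_of_range_arclength(self):
        with pytest.raises(ValueError):
            fibre_frame(ComplexParams(), 201.0)


@pytest.fixture(scope="module")
def scene1():
    return build_scene(ComplexParams(model=1), scale=1.0)


@pytest.fixture(scope="module")
def scene2():
    return build_scene(ComplexParams(model=2), scale=1.0)


class TestScene:
    def test_watertight_model1(self, scene1):
        assert all(scene1.watertight().values())

    def test_watertight_model2(self, scene2):
        assert all(scene2.watertight().values())

    def test_fibre_tube_volume(self, scene1):
        p = scene1.params
        expected = math.pi * p.r_fib ** 2 * p.L_fib
        assert scene1.volumes()["fibre"] == pytest.approx(expected, rel=0.01)

    def test_model1_fibre_flagellum_clearance(self, scene1):
        # centreline standoff d = 2*r_fib minus the tube radius -> 1 nm
        p = scene1.params
        expected = p.d_eff - p.r_fib
        clear = scene1.min_clearance("fibre", "flagellum")
        assert expected * 0.9 <= clear <= expected * 1.05

    def test_model2_groove_clearance(self, scene2):
        p = scene2.params
        clear = scene2.min_clearance("fibre", "flagellum")
        assert 0.8 * p.h_gap_eff <= clear <= 1.05 * p.h_gap_eff

    def test_model2_groove_removes_volume(self, scene2):
        p = scene2.params
        smooth = math.pi * p.R_fl ** 2 * p.L_fl
        assert scene2.volumes()["flagellum"] < 0.995 * smooth

    def test_fcov_zero_disables_groove(self):
        p = ComplexParams(model=2, f_cov=0.0)
        bodies = build_bodies(p)
        probe = np.array([[p.R_fl - 0.3, 0.0, 0.0]])
        assert bodies["flagellum"].sdf(probe)[0] < 0  # solid: nothing carved

    def test_positive_clearances_everywhere(self, scene1):
        for a, b in (("tail", "flagellum"), ("tail", "fibre"),
                     ("head", "flagellum")):
            assert scene1.min_clearance(a, b) > 0

    def test_tail_overlap_detected(self):
        with pytest.raises(ValueError, match="tail overlaps"):
            build_bodies_and_check(ComplexParams(model=1, tail_tilt=170.0))

    def test_groove_too_deep_detected(self):
        with pytest.raises(ValueError, match="groove"):
            build_bodies_and_check(ComplexParams(model=2, h_gap=12.0))

    def test_gap_sheet_points_lie_in_fluid(self):
        for model in (1, 2):
            p = ComplexParams(model=model, L_fib=80.0)
            bodies = build_bodies(p)
            pts = gap_sheet_points(p, 1.3)
            assert len(pts) > 50
            for body in bodies.values():
                assert np.all(body.sdf(pts) > 0)

    def test_head_tangent_to_tail_end(self):
        p = ComplexParams()
        t0, t1, u, head_c = tail_axis(p)
        assert np.linalg.norm(head_c - t1) == pytest.approx(p.a_h, rel=1e-12)


def build_bodies_and_check(params):
    from nutbolt.geometry import _check_scene
    bodies = build_bodies(params)
    _check_scene(params, bodies)
    return bodies
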