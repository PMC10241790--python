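"""Penalty Stokes solver: reference element, energy oracles, sphere flows."""

import math

import numpy as np
import pytest

from nutbolt.benchmarks import (sphere_fluid_mesh, stokes_drag,
                                stokes_spin_torque, container_drag_correction)
from nutbolt.stokes import (StokesCase, tet10_shape, tet_quadrature,
                            tet_quadrature_p1)
from nutbolt.mobility import BoundarySpec
from nutbolt.motions import Rest, RotationZ, TranslationZ, Superposed
from nutbolt.loads import axial_force_and_torque

MU = 1.0e-3


@pytest.fixture(scope="module")
def coarse_case():
    mesh = sphere_fluid_mesh(a=1.0, outer_radius=20.0, near=0.6, far=5.0,
                             seed=0)
    return StokesCase(mesh, mu=MU)


class TestReferenceElement:
    def test_shape_functions_partition_of_unity(self):
        q, _ = tet_quadrature(3)
        N, dN = tet10_shape(q)
        np.testing.assert_allclose(N.sum(axis=1), 1.0, atol=1e-13)
        np.testing.assert_allclose(dN.sum(axis=1), 0.0, atol=1e-13)

    def test_shape_functions_kronecker_at_nodes(self):
        corners = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        edges = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
        nodes = np.vstack([corners] + [0.5 * (corners[i] + corners[j])
                                       for i, j in edges])
        N, _ = tet10_shape(nodes)
        np.testing.assert_allclose(N, np.eye(10), atol=1e-13)

    @pytest.mark.parametrize("abc", [(2, 2, 1), (5, 0, 0), (0, 3, 2),
                                     (1, 1, 1)])
    def test_quadrature_exact_to_degree_five(self, abc):
        a, b, c = abc
        q, w = tet_quadrature(3)
        val = np.sum(w * q[:, 0] ** a * q[:, 1] ** b * q[:, 2] ** c)
        exact = (math.factorial(a) * math.factorial(b) * math.factorial(c)
                 / math.factorial(a + b + c + 3))
        assert val == pytest.approx(exact, rel=1e-13)

    def test_penalty_rule_is_centroid(self):
        q, w = tet_quadrature_p1()
        np.testing.assert_allclose(q, [[0.25, 0.25, 0.25]])
        assert w.sum() == pytest.approx(1.0 / 6.0)


class TestEnergyFunctional:
    def test_rigid_motions_have_zero_energy(self, coarse_case):
        n = coarse_case.mesh.n_nodes
        nodes = coarse_case.mesh.nodes
        fields = []
        u = np.zeros((n, 3)); u[:, 2] = 1.0
        fields.append(u)
        u = np.stack([-nodes[:, 1], nodes[:, 0], np.zeros(n)], axis=1)
        fields.append(u)
        gamma, V = 0.7, coarse_case.mesh.volume_p2()
        shear_J = MU * gamma ** 2 * V
        # roundoff floor scales with the penalty stiffness lambda
        for u in fields:
            assert abs(coarse_case.energy(u)) < 1e-6 * shear_J

    def test_pure_shear_energy_closed_form(self, coarse_case):
        # u = gamma*y: dissipation density 2*mu*(2*eps_xy^2) = mu*gamma^2
        nodes = coarse_case.mesh.nodes
        gamma = 0.7
        u = np.zeros((coarse_case.mesh.n_nodes, 3))
        u[:, 0] = gamma * nodes[:, 1]
        V = coarse_case.mesh.volume_p2()
        assert coarse_case.energy(u) == pytest.approx(MU * gamma ** 2 * V,
                                                      rel=1e-9)

    def test_dilatation_energy_includes_penalty(self, coarse_case):
        # u = x has div = 3 and eps = I exactly (isoparametric elements
        # reproduce affine fields); the penalty term sees the volume through
        # its own one-point rule, the viscous term through the full rule
        nodes = coarse_case.mesh.nodes
        V_visc = coarse_case.mesh.volume_p2()
        V_pen = float(np.sum(coarse_case._detp @ coarse_case._wp))
        expected = coarse_case.lam * 9.0 * V_pen + 2.0 * MU * 3.0 * V_visc
        assert coarse_case.energy(nodes) == pytest.approx(expected, rel=1e-9)


class TestSolve:
    def test_all_rest_gives_zero_field(self, coarse_case):
        sol = coarse_case.solve(BoundarySpec({"sphere": Rest()}))
        assert np.abs(sol.velocity).max() == 0.0
        assert sol.functional_value == 0.0

    def test_translating_sphere_drag(self, sphere_case):
        sol = sphere_case.solve(BoundarySpec({"sphere": TranslationZ(1.0)},
                                             name="translate"))
        F_z, _ = axial_force_and_torque(sphere_case, sol, ("sphere",))
        expected = -stokes_drag(MU, 1.0, 1.0) * container_drag_correction(
            1.0, sphere_case.mesh.outer_radius)
        assert F_z == pytest.approx(expected, rel=0.03)
        assert sol.residual < 1e-10

    def test_rotating_sphere_torque(self, sphere_case):
        sol = sphere_case.solve(BoundarySpec({"sphere": RotationZ(1.0)},
                                             name="rotate"))
        F_z, M_z = axial_force_and_torque(sphere_case, sol, ("sphere",))
        assert M_z == pytest.approx(-stokes_spin_torque(MU, 1.0, 1.0),
                                    rel=0.03)
        assert abs(F_z) < 0.01 * abs(M_z)

    def test_linearity_in_epsilon(self, sphere_case):
        s1 = sphere_case.solve(BoundarySpec({"sphere": TranslationZ(1.0)}))
        s2 = sphere_case.solve(BoundarySpec({"sphere": TranslationZ(2.0)}))
        np.testing.assert_allclose(s2.velocity, 2.0 * s1.velocity, atol=1e-12)

    def test_superposition_of_boundary_data(self, sphere_case):
        st_ = sphere_case.solve(BoundarySpec({"sphere": TranslationZ(1.0)}))
        sr = sphere_case.solve(BoundarySpec({"sphere": RotationZ(1.0)}))
        sboth = sphere_case.solve(BoundarySpec(
            {"sphere": Superposed(TranslationZ(1.0), RotationZ(1.0))}))
        num = np.linalg.norm(sboth.velocity - st_.velocity - sr.velocity)
        den = np.linalg.norm(sboth.velocity)
        assert num / den < 1e-8

    def test_divergence_scales_inversely_with_penalty(self):
        mesh = sphere_fluid_mesh(a=1.0, outer_radius=20.0, near=0.6, far=5.0,
                                 seed=0)
        divs = []
        for lam in (1e5 * MU, 1e6 * MU):
            case = StokesCase(mesh, mu=MU, lam=lam)
            sol = case.solve(BoundarySpec({"sphere": TranslationZ(1.0)}))
            divs.append(sol.divergence_norm)
        assert divs[1] == pytest.approx(divs[0] / 10.0, rel=0.15)

    def test_pressure_recovered_from_divergence(self, sphere_case):
        sol = sphere_case.solve(BoundarySpec({"sphere": TranslationZ(1.0)}))
        # Stokeslet pressure scale mu*U/a: the recovered field must sit on
        # that order of magnitude, not on lambda's
        p_scale = MU * 1.0 / 1.0
        p99 = np.percentile(np.abs(sol.pressure), 99)
        assert 0.01 * p_scale < p99 < 50.0 * p_scale

    def test_penalty_parameter_floor(self, sphere_case):
        with pytest.raises(ValueError):
            StokesCase(sphere_case.mesh, mu=MU, lam=MU)
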