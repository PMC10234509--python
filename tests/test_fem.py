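"""Tests of the explicit total-Lagrangian FE solver."""

import numpy as np
import pytest

from myofe.constitutive import MaterialPointState, initial_state, sigma_pe
from myofe.errors import InvalidDeformationError
from myofe.fem import (
    BoundaryCondition,
    ExplicitSettings,
    ExplicitState,
    _deformation_gradients,
    _Precomp,
    critical_time_step,
    internal_forces,
    run_fusiform_elongation,
    run_uniaxial_box,
    step_explicit,
    vm_percentile,
    von_mises,
)
from myofe.fixtures import FusiformSpec, make_box, make_fusiform
from myofe.uniaxial import ElongationProtocol, run_elongation


def frozen_states(mesh, u, params, settings=None):
    """Element states consistent with the current passive deformation."""
    pre = _Precomp(mesh, settings or ExplicitSettings())
    F = _deformation_gradients(mesh, u, pre)
    J = np.linalg.det(F)
    a = np.einsum("eij,ej->ei", F, mesh.fibers)
    lam_fb = J ** (-1 / 3) * np.linalg.norm(a, axis=1)
    m = mesh.n_elements
    return MaterialPointState(
        lambda_s=np.ones(m), lambda_m=lam_fb,
        sigma_see=np.zeros(m),
        sigma_pe=np.asarray(sigma_pe(lam_fb, params)))


class TestInternalForces:
    def test_zero_displacement_zero_forces(self, params):
        mesh = make_box(0.01, 0.01, 0.01)
        u = np.zeros((mesh.n_nodes, 3))
        f = internal_forces(mesh, u, frozen_states(mesh, u, params), params)
        assert np.abs(f).max() == 0.0

    def test_rigid_translation_zero_forces(self, params):
        mesh = make_box(0.01, 0.01, 0.01, 2, 1, 1)
        u = np.tile([0.003, -0.001, 0.002], (mesh.n_nodes, 1))
        f = internal_forces(mesh, u, frozen_states(mesh, u, params), params)
        assert np.abs(f).max() < 1e-9

    @pytest.mark.parametrize("single_tet", [True, False],
                             ids=["single-tet", "box"])
    def test_energy_gradient_oracle(self, params, rng, single_tet):
        """Nodal forces match the (independent) central finite-difference
        gradient of the total passive strain energy.  On a single
        tetrahedron the volumetric term is the plain per-element one; on
        a multi-element mesh the oracle energy uses the same
        volume-weighted nodal Jacobian average the solver discretizes."""
        from myofe.mesh import Mesh
        if single_tet:
            mesh = Mesh(nodes=np.array([[0.0, 0, 0], [0.01, 0, 0],
                                        [0, 0.01, 0], [0, 0, 0.01]]),
                        tets=np.array([[0, 1, 2, 3]]))
            mesh.set_uniform_fibers([1.0, 0.0, 0.0])
        else:
            mesh = make_box(0.01, 0.01, 0.01)
        pre = _Precomp(mesh, ExplicitSettings())
        u0 = rng.normal(scale=2e-4, size=(mesh.n_nodes, 3))

        def energy(u):
            F = _deformation_gradients(mesh, u, pre)
            J = np.linalg.det(F)
            I1b = J ** (-2 / 3) * np.einsum("eij,eij->e", F, F)
            a = np.einsum("eij,ej->ei", F, mesh.fibers)
            lam_fb = J ** (-1 / 3) * np.linalg.norm(a, axis=1)
            Wm = params.c * np.expm1(params.b * (I1b - 3.0))
            Wpe = np.where(lam_fb > 1.0,
                           params.sigma0 * params.A / 3 * (lam_fb - 1) ** 3,
                           0.0)
            if single_tet:
                Jv = J
            else:  # volume-weighted nodal average, then back to elements
                Jn = np.zeros(mesh.n_nodes)
                np.add.at(Jn, mesh.tets.ravel(),
                          np.repeat(pre.vol / 4 * J, 4))
                Jv = (Jn / pre.node_vol)[mesh.tets].mean(axis=1)
            Wv = (Jv - 1.0) ** 2 / params.D
            return float(np.sum(pre.vol * (Wm + Wpe + Wv)))

        f = internal_forces(mesh, u0, frozen_states(mesh, u0, params),
                            params)
        h = 1e-8
        for node in range(mesh.n_nodes):
            for dof in range(3):
                up, um = u0.copy(), u0.copy()
                up[node, dof] += h
                um[node, dof] -= h
                fd = -(energy(up) - energy(um)) / (2 * h)
                assert f[node, dof] == pytest.approx(
                    fd, rel=1e-6, abs=1e-6 * np.abs(f).max())

    def test_inverted_element_reported(self, params):
        mesh = make_box(0.01, 0.01, 0.01)
        u = np.zeros((mesh.n_nodes, 3))
        u[mesh.node_sets["x1"], 0] = -0.02   # pushes through itself
        with pytest.raises(InvalidDeformationError, match="element"):
            internal_forces(mesh, u, frozen_states(
                mesh, np.zeros_like(u), params), params)


class TestExplicitStepping:
    def test_no_loads_state_unchanged(self, params):
        mesh = make_box(0.01, 0.01, 0.01)
        settings = ExplicitSettings(mass_scale=1e4)
        pre = _Precomp(mesh, settings)
        dt = 0.5 * critical_time_step(mesh, settings, params)
        sim = ExplicitState(u=np.zeros((mesh.n_nodes, 3)),
                            v=np.zeros((mesh.n_nodes, 3)),
                            states=initial_state(np.ones(mesh.n_elements)))
        for _ in range(10):
            step_explicit(mesh, sim, settings, [], params, pre, dt)
        assert np.abs(sim.u).max() == 0.0
        assert np.abs(sim.v).max() == 0.0

    def test_momentum_conserved_in_free_motion(self, params, rng):
        """Without constraints or damping the assembled forces sum to
        zero, so total linear momentum is conserved to round-off."""
        mesh = make_box(0.01, 0.01, 0.01, 2, 1, 1)
        settings = ExplicitSettings(mass_scale=1e6, damping=0.0)
        pre = _Precomp(mesh, settings)
        dt = 0.3 * critical_time_step(mesh, settings, params)
        v0 = rng.normal(scale=1e-4, size=(mesh.n_nodes, 3))
        sim = ExplicitState(u=np.zeros((mesh.n_nodes, 3)), v=v0.copy(),
                            states=initial_state(np.ones(mesh.n_elements)))
        p0 = (pre.mass[:, None] * sim.v).sum(axis=0)
        for _ in range(100):
            step_explicit(mesh, sim, settings, [], params, pre, dt)
        p1 = (pre.mass[:, None] * sim.v).sum(axis=0)
        assert np.abs(p1 - p0).max() <= 1e-12 * np.abs(p0).max() + 1e-18

    def test_patch_consistency(self, params):
        """A 2x2x2 patch with homogeneous boundary displacement relaxes
        to the same (uniform) element stress state as a single-cell mesh
        under the same affine map."""
        H = np.array([[0.02, 0.004, 0.0],
                      [0.0, -0.008, 0.003],
                      [0.0, 0.0, -0.007]])

        def relaxed_F(nx):
            mesh = make_box(0.01, 0.01, 0.01, nx, nx, nx)
            settings = ExplicitSettings(mass_scale=1e6, damping=500.0)
            pre = _Precomp(mesh, settings)
            dt = 0.5 * critical_time_step(mesh, settings, params)
            u = mesh.nodes @ H.T
            boundary = np.unique(mesh.boundary())
            interior = np.setdiff1d(np.arange(mesh.n_nodes), boundary)
            u[interior] += 1e-4 * 0.01  # perturb interior, then relax
            sim = ExplicitState(
                u=u, v=np.zeros((mesh.n_nodes, 3)),
                states=initial_state(np.ones(mesh.n_elements)))
            bcs = [BoundaryCondition(boundary, (0, 1, 2), 0.0)]
            for _ in range(3000):
                step_explicit(mesh, sim, settings, bcs, params, pre, dt)
            return _deformation_gradients(mesh, sim.u, pre)

        F1 = relaxed_F(1)
        F8 = relaxed_F(2)
        target = np.eye(3) + H
        assert np.abs(F1 - target).max() < 1e-8
        assert np.abs(F8 - target).max() < 1e-8

    def test_divergence_reported(self, params):
        mesh = make_box(0.01, 0.01, 0.01)
        settings = ExplicitSettings(mass_scale=1.0)
        pre = _Precomp(mesh, settings)
        sim = ExplicitState(u=np.zeros((mesh.n_nodes, 3)),
                            v=np.zeros((mesh.n_nodes, 3)),
                            states=initial_state(np.ones(mesh.n_elements)))
        sim.u[0] = np.nan
        from myofe.errors import ConvergenceError
        with pytest.raises(ConvergenceError):
            step_explicit(mesh, sim, settings, [], params, pre, 1e-6)


@pytest.fixture(scope="module")
def box_run(params):
    mesh = make_box(0.01, 0.01, 0.01, 1, 1, 1, fiber=(1, 0, 0))
    settings = ExplicitSettings(mass_scale=1e4, damping=1e3,
                                output_every=500)
    return run_uniaxial_box(mesh, strain_rate=0.1, final_strain=0.10,
                            settings=settings, params=params,
                            settle_time=0.5)


@pytest.fixture(scope="module")
def fusiform_protocol():
    # fast ramp + damped settle: the reaction is read in a relaxed
    # state, and passive response is rate-independent
    return ElongationProtocol.passive(
        pull_velocity=0.05, pull_duration=0.1, time_step=1e-3)


@pytest.fixture(scope="module")
def fusiform_settings():
    return ExplicitSettings(mass_scale=1e3, damping=2.0,
                            output_every=2000)


class TestCrossModuleEquivalence:
    def test_single_element_matches_homogeneous_driver(self, box_run,
                                                       params):
        """Uniaxial FE stress within 2% of the material-point driver at
        10% strain (passive)."""
        protocol = ElongationProtocol.passive(
            pull_velocity=0.005, pull_duration=1.0, time_step=5e-3)
        curve = run_elongation(protocol, params)
        ref = np.interp(0.10, curve.strain, curve.stress)
        assert box_run["eng_stress"][-1] == pytest.approx(ref, rel=0.02)

    def test_energy_balance(self, box_run):
        """External work = kinetic + internal + damping dissipation,
        within a 1% drift allowance."""
        W = box_run["external"][-1]
        K = box_run["kinetic"][-1]
        E = box_run["internal"][-1]
        D = box_run["damping"][-1]
        assert abs(W - K - E - D) <= 0.01 * max(W, E, D)

    def test_quasi_static(self, box_run):
        assert box_run["kinetic"][-1] <= 0.05 * box_run["internal"][-1]


class TestFusiformRuns:
    def test_mesh_refinement_reaction_stable(self, params,
                                             fusiform_protocol,
                                             fusiform_settings):
        protocol, settings = fusiform_protocol, fusiform_settings
        """Reaction force at 10% strain changes < 5% between the coarse
        and a 2x refined fusiform mesh (axial grips, so the comparison
        is not polluted by grip boundary layers)."""
        def reaction_force(nc, na):
            mesh = make_fusiform(FusiformSpec(n_cross=nc, n_axial=na))
            hist = run_fusiform_elongation(mesh, protocol, settings,
                                           params, settle_time=0.25,
                                           grip="axial")
            return -hist["reaction"][-1][2]

        coarse = reaction_force(2, 6)
        fine = reaction_force(4, 12)
        assert coarse == pytest.approx(fine, rel=0.05)

    def test_active_reaction_exceeds_passive(self, params,
                                             fusiform_protocol,
                                             fusiform_settings):
        protocol, settings = fusiform_protocol, fusiform_settings
        mesh = make_fusiform(FusiformSpec(n_cross=3, n_axial=8))
        passive = run_fusiform_elongation(mesh, protocol, settings, params,
                                          settle_time=0.25)
        active_protocol = ElongationProtocol(
            pull_velocity=0.05, pull_duration=0.1, hold_duration=0.1,
            time_step=1e-3)
        active = run_fusiform_elongation(mesh, active_protocol, settings,
                                         params, settle_time=0.25)
        assert active["eng_stress_mid"][-1] > passive["eng_stress_mid"][-1]

    def test_zero_velocity_run_zero_reaction(self, params,
                                             fusiform_settings):
        settings = fusiform_settings
        mesh = make_fusiform(FusiformSpec(n_cross=3, n_axial=6))
        protocol = ElongationProtocol.passive(
            pull_velocity=0.0, pull_duration=0.1, time_step=1e-3)
        hist = run_fusiform_elongation(mesh, protocol, settings, params,
                                       settle_time=0.05)
        assert abs(hist["eng_stress_mid"][-1]) < 100.0


class TestStressPostprocessing:
    def test_constant_field_any_percentile(self):
        field = np.full(37, 3.14e5)
        for q in (0.0, 50.0, 95.0, 100.0):
            assert vm_percentile(field, q) == pytest.approx(3.14e5)

    def test_order_statistics_interpolation(self):
        field = np.arange(1.0, 101.0)
        val = vm_percentile(field, 95.0)
        assert 95.0 <= val <= 96.0
        assert val == pytest.approx(np.percentile(field, 95))

    def test_extremes(self):
        field = np.array([5.0, 1.0, 9.0])
        assert vm_percentile(field, 0.0) == 1.0
        assert vm_percentile(field, 100.0) == 9.0

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError):
            vm_percentile(np.array([]), 95.0)

    def test_von_mises_of_pure_shear(self):
        sig = np.zeros((1, 3, 3))
        sig[0, 0, 1] = sig[0, 1, 0] = 1.0e4
        assert von_mises(sig)[0] == pytest.approx(np.sqrt(3) * 1.0e4)

    def test_von_mises_insensitive_to_pressure(self):
        sig = -2.5e6 * np.eye(3)
        assert von_mises(sig) == pytest.approx(0.0, abs=1e-6)
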