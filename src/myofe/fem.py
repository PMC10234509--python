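"""Minimal explicit total-Lagrangian finite-element solver.

Linear displacement tetrahedra with the active-muscle constitutive law at
one integration point per element, lumped mass, central-difference time
integration with optional mass-proportional damping, prescribed-velocity
and fixed boundary conditions enforced exactly, and optional cohesive
surface pairs.  Optional mass scaling buys a larger stable increment for
quasi-static runs; the kinetic/internal energy ratio is reported so its
admissibility can be checked.

The solver is deliberately desk-scale: whole meshes advance vectorized
(numpy) with the constitutive increment solved for all elements at once.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohesive import CohesiveParams, CohesivePairing, cohesive_tractions
from .constitutive import (
    MaterialPointState,
    advance_fiber_state,
    cauchy_stress_batch,
    initial_state,
)
from .errors import ConvergenceError, InvalidDeformationError
from .mesh import Mesh
from .params import MaterialParams
from .uniaxial import ElongationProtocol

__all__ = [
    "ExplicitSettings",
    "BoundaryCondition",
    "ExplicitState",
    "internal_forces",
    "step_explicit",
    "run_explicit",
    "run_fusiform_elongation",
    "run_uniaxial_box",
    "von_mises",
    "vm_percentile",
    "critical_time_step",
]


@dataclasses.dataclass(frozen=True)
class ExplicitSettings:
    """Time integration settings.

    density : muscle mass density [kg/m^3]; 1060 is typical skeletal
        muscle.  ``mass_scale`` multiplies it to enlarge the stable
        increment in quasi-static runs.
    dt : fixed time step [s], or None for automatic (safety * critical).
    damping : mass-proportional damping coefficient [1/s].
    """

    density: float = 1060.0
    dt: float | None = None
    total_time: float = 1.0
    damping: float = 0.0
    mass_scale: float = 1.0
    safety: float = 0.8
    output_every: int = 100

    def __post_init__(self) -> None:
        if self.density <= 0.0 or self.mass_scale <= 0.0:
            raise ValueError("density and mass_scale must be positive")
        if self.dt is not None and self.dt <= 0.0:
            raise ValueError("dt must be positive")


@dataclasses.dataclass(frozen=True)
class BoundaryCondition:
    """Prescribed nodal motion: velocity(t) on the given dofs of a node set.

    ``velocity`` is a callable t -> float, a constant, or 0 for fixed.
    """

    nodes: np.ndarray
    dofs: tuple = (0, 1, 2)
    velocity: object = 0.0

    def value(self, t: float) -> float:
        return float(self.velocity(t)) if callable(self.velocity) \
            else float(self.velocity)


@dataclasses.dataclass
class ExplicitState:
    """Mutable simulation state of the explicit solver."""

    u: np.ndarray             # (n, 3) displacements
    v: np.ndarray             # (n, 3) half-step velocities
    states: MaterialPointState  # vectorized element states
    time: float = 0.0
    internal_energy: float = 0.0
    external_work: float = 0.0
    damping_dissipation: float = 0.0
    P_prev: np.ndarray | None = None

    def kinetic_energy(self, mass: np.ndarray) -> float:
        return float(0.5 * np.sum(mass[:, None] * self.v ** 2))


class _Precomp:
    """Reference shape gradients, volumes and lumped mass of a mesh."""

    def __init__(self, mesh: Mesh, settings: ExplicitSettings):
        X = mesh.nodes[mesh.tets]
        Dm = X[:, 1:] - X[:, :1]
        det = np.linalg.det(Dm)
        if np.any(det <= 0.0):
            raise InvalidDeformationError("mesh has inverted elements")
        self.vol = det / 6.0
        g123 = np.transpose(np.linalg.inv(Dm), (0, 2, 1))
        self.grads = np.concatenate([-g123.sum(axis=1, keepdims=True),
                                     g123], axis=1)   # (m, 4, 3)
        rho = settings.density * settings.mass_scale
        self.mass = np.zeros(mesh.n_nodes)
        np.add.at(self.mass, mesh.tets.ravel(),
                  np.repeat(rho * self.vol / 4.0, 4))
        # nodal reference volumes for the averaged volumetric treatment
        self.node_vol = np.zeros(mesh.n_nodes)
        np.add.at(self.node_vol, mesh.tets.ravel(),
                  np.repeat(self.vol / 4.0, 4))
        # characteristic length: inscribed-sphere style 3V / max face area
        areas = []
        local = [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]
        for (a, b, c) in local:
            e1 = X[:, b] - X[:, a]
            e2 = X[:, c] - X[:, a]
            areas.append(0.5 * np.linalg.norm(np.cross(e1, e2), axis=1))
        self.char_len = 3.0 * self.vol / np.max(np.stack(areas), axis=0)


def critical_time_step(mesh: Mesh, settings: ExplicitSettings,
                       params: MaterialParams) -> float:
    """Stable-increment estimate h_min / c with an effective stiffness
    dominated by the volumetric penalty 2/D (plus the matrix modulus)."""
    pre = _Precomp(mesh, settings)
    stiff = 2.0 / params.D + 4.0 * params.c * params.b
    wave = np.sqrt(stiff / (settings.density * settings.mass_scale))
    return float(np.min(pre.char_len) / wave)


def settle_damping_estimate(mesh: Mesh, settings: ExplicitSettings,
                            params: MaterialParams) -> float:
    """Near-critical mass-proportional damping for the lowest structural
    mode: overdamping slows the decay to omega^2/c, so 'more' is not
    safer for settling.  The governing mode rides on the *soft*
    (deviatoric matrix + fiber) stiffness — the volumetric penalty only
    sets the stable increment — so the wave speed uses a soft-modulus
    scale, not 2/D."""
    soft = 4.0 * params.c * params.b + 0.1 * params.sigma0
    wave = np.sqrt(soft / (settings.density * settings.mass_scale))
    extent = float(np.max(mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)))
    return float(2.0 * np.pi * wave / extent)


def _deformation_gradients(mesh: Mesh, u: np.ndarray,
                           pre: _Precomp) -> np.ndarray:
    F = np.einsum("eai,eaj->eij", u[mesh.tets], pre.grads)
    F[:, 0, 0] += 1.0
    F[:, 1, 1] += 1.0
    F[:, 2, 2] += 1.0
    return F


def _stress_and_pk1(mesh: Mesh, F: np.ndarray, sig_fiber, params,
                    pre: "_Precomp"):
    """Cauchy stress (for output) and total PK1 (for assembly) with the
    nodal-averaged volumetric term.

    Linear tetrahedra lock volumetrically at near-incompressibility;
    the volumetric energy is therefore evaluated on the element Jacobian
    smoothed through volume-weighted nodal averages (average-nodal-
    pressure tetrahedra).  The force term is the exact gradient of that
    averaged energy, so the energy ledger stays consistent; for a single
    element or any homogeneous deformation the scheme coincides with the
    standard formulation.
    """
    J = np.linalg.det(F)
    Finv_T = np.transpose(np.linalg.inv(F), (0, 2, 1))
    sig_dev = cauchy_stress_batch(F, mesh.fibers, sig_fiber, params,
                                  volumetric=False)
    P = J[:, None, None] * np.einsum("eij,ejk->eik", sig_dev, Finv_T)

    quarter = pre.vol / 4.0
    Jbar_n = np.zeros(mesh.n_nodes)
    np.add.at(Jbar_n, mesh.tets.ravel(), np.repeat(quarter * J, 4))
    Jbar_n /= pre.node_vol
    Jtil = Jbar_n[mesh.tets].mean(axis=1)
    p = 2.0 / params.D * (Jtil - 1.0)
    # adjoint of the averaging: effective per-element pressure weight
    s_n = np.zeros(mesh.n_nodes)
    np.add.at(s_n, mesh.tets.ravel(), np.repeat(quarter * p, 4))
    pi_e = quarter * (s_n / pre.node_vol)[mesh.tets].sum(axis=1)
    P = P + (pi_e / pre.vol * J)[:, None, None] * Finv_T

    sig = sig_dev + p[:, None, None] * np.eye(3)
    return sig, P


def _assemble(mesh: Mesh, P: np.ndarray, pre: _Precomp) -> np.ndarray:
    # nodal force exerted by element stresses: f_a = -V * P . grad(N_a)
    fe = -pre.vol[:, None, None] * np.einsum("eij,eaj->eai", P, pre.grads)
    f = np.zeros((mesh.n_nodes, 3))
    np.add.at(f, mesh.tets.reshape(-1), fe.reshape(-1, 3))
    return f


def internal_forces(mesh: Mesh, displacements: np.ndarray,
                    states: MaterialPointState, params: MaterialParams,
                    settings: ExplicitSettings | None = None) -> np.ndarray:
    """Nodal forces from the element stresses at the given (frozen) states.

    Raises :class:`InvalidDeformationError` naming the first inverted
    element if any Jacobian is non-positive.
    """
    settings = settings or ExplicitSettings()
    pre = _Precomp(mesh, settings)
    F = _deformation_gradients(mesh, np.asarray(displacements, float), pre)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        bad = int(np.argmin(J))
        raise InvalidDeformationError(
            f"element {bad} inverted (J = {J[bad]:.3e})")
    sig_fiber = np.asarray(states.sigma_pe) + np.asarray(states.sigma_see)
    _, P = _stress_and_pk1(mesh, F, sig_fiber, params, pre)
    return _assemble(mesh, P, pre)


def step_explicit(mesh: Mesh, sim: ExplicitState, settings: ExplicitSettings,
                  bcs: list, params: MaterialParams, pre: _Precomp,
                  dt: float, activation_level: float = 0.0,
                  pairing: CohesivePairing | None = None,
                  cohesive: CohesiveParams | None = None,
                  damping: float | None = None) -> np.ndarray:
    """Advance one central-difference step; returns assembled stress forces.

    Element states are advanced with the constitutive increment solve,
    forces assembled from the first Piola-Kirchhoff stress, the nodal
    update damped by mass-proportional damping, and boundary conditions
    applied exactly (prescribed velocity overwrites the computed one).
    """
    F = _deformation_gradients(mesh, sim.u, pre)
    J = np.linalg.det(F)
    if np.any(J <= 0.0) or not np.all(np.isfinite(sim.u)):
        raise ConvergenceError(
            "explicit step diverged (inverted element or NaN displacement); "
            "reduce the time step or increase damping")
    a_cur = np.einsum("eij,ej->ei", F, mesh.fibers)
    lam_f = np.linalg.norm(a_cur, axis=1)
    lam_f_bar = J ** (-1.0 / 3.0) * lam_f

    sim.states = advance_fiber_state(sim.states, lam_f_bar, dt,
                                     activation_level, params)
    sig_fiber = np.asarray(sim.states.sigma_pe) \
        + np.asarray(sim.states.sigma_see)
    _, P = _stress_and_pk1(mesh, F, sig_fiber, params, pre)
    f = _assemble(mesh, P, pre)
    f_coh = None
    if pairing is not None:
        f_coh, _ = cohesive_tractions(pairing, sim.u, cohesive
                                      or CohesiveParams())
        f = f + f_coh

    # incremental internal energy: P : dF (trapezoidal in P)
    if sim.P_prev is None:
        sim.P_prev = np.zeros_like(P)

    m = pre.mass[:, None]
    c = settings.damping if damping is None else damping
    v_new = ((1.0 - 0.5 * c * dt) * sim.v + dt * f / m) \
        / (1.0 + 0.5 * c * dt)

    # boundary conditions: overwrite velocities
    t_new = sim.time + dt
    for bc in bcs:
        val = bc.value(t_new)
        for dof in bc.dofs:
            v_new[bc.nodes, dof] = val

    du = dt * v_new
    dF = np.einsum("eai,eaj->eij", du[mesh.tets], pre.grads)
    sim.internal_energy += float(np.sum(
        pre.vol * np.einsum("eij,eij->e", 0.5 * (P + sim.P_prev), dF)))
    sim.P_prev = P

    # external work done by the constraints: reaction = m a - f + damping
    vmid = 0.5 * (sim.v + v_new)
    for bc in bcs:
        for dof in bc.dofs:
            acc = (v_new[bc.nodes, dof] - sim.v[bc.nodes, dof]) / dt
            r = pre.mass[bc.nodes] * acc - f[bc.nodes, dof] \
                + c * pre.mass[bc.nodes] * vmid[bc.nodes, dof]
            sim.external_work += float(np.sum(r * du[bc.nodes, dof]))

    # dissipation measured against du = dt * v_new, consistent with the
    # displacement update (the residual is the scheme's numerical
    # dissipation, positive and O(dt))
    sim.damping_dissipation += float(
        np.sum(c * pre.mass[:, None] * vmid * v_new) * dt)

    sim.u = sim.u + du
    sim.v = v_new
    sim.time = t_new
    return f


def run_explicit(mesh: Mesh, settings: ExplicitSettings, bcs: list,
                 params: MaterialParams,
                 activation=None,
                 pairing: CohesivePairing | None = None,
                 cohesive: CohesiveParams | None = None,
                 reaction_set: str | None = None,
                 record_fields: bool = False,
                 damping_fn=None):
    """Time-march the explicit solver over ``settings.total_time``.

    ``damping_fn(t)`` optionally overrides the constant damping
    coefficient — mass-proportional damping drags on rigid motion, so
    quasi-static runs with mass scaling ramp with light damping and
    settle under heavy damping.  Returns a history dict with times,
    reaction forces on ``reaction_set`` (if given), energies, and
    optionally per-element von Mises stress snapshots at the output
    cadence.
    """
    if mesh.fibers is None:
        raise ConvergenceError("mesh needs a fiber field")
    pre = _Precomp(mesh, settings)
    dt = settings.dt
    if dt is None:
        dt = settings.safety * critical_time_step(mesh, settings, params)
    n_steps = max(1, int(np.ceil(settings.total_time / dt)))

    m = mesh.n_elements
    sim = ExplicitState(
        u=np.zeros((mesh.n_nodes, 3)),
        v=np.zeros((mesh.n_nodes, 3)),
        states=initial_state(np.ones(m)),
    )
    react_nodes = mesh.node_sets[reaction_set] if reaction_set else None
    hist = {"time": [], "reaction": [], "kinetic": [], "internal": [],
            "external": [], "damping": [], "J_min": [], "J_max": [],
            "vm": [], "u_max": []}

    for step in range(n_steps):
        f = step_explicit(
            mesh, sim, settings, bcs, params, pre, dt,
            activation_level=(activation(sim.time + dt)
                              if callable(activation)
                              else (activation or 0.0)),
            pairing=pairing, cohesive=cohesive,
            damping=(damping_fn(sim.time) if damping_fn else None))
        if step % settings.output_every == 0 or step == n_steps - 1:
            hist["time"].append(sim.time)
            if react_nodes is not None:
                hist["reaction"].append(-f[react_nodes].sum(axis=0))
            F = _deformation_gradients(mesh, sim.u, pre)
            J = np.linalg.det(F)
            hist["J_min"].append(float(J.min()))
            hist["J_max"].append(float(J.max()))
            hist["kinetic"].append(sim.kinetic_energy(pre.mass))
            hist["internal"].append(sim.internal_energy)
            hist["external"].append(sim.external_work)
            hist["damping"].append(sim.damping_dissipation)
            hist["u_max"].append(float(np.abs(sim.u).max()))
            if record_fields:
                sig_fiber = np.asarray(sim.states.sigma_pe) \
                    + np.asarray(sim.states.sigma_see)
                sig = cauchy_stress_batch(F, mesh.fibers, sig_fiber, params)
                hist["vm"].append(von_mises(sig))
    hist = {k: (np.asarray(v) if k != "vm" else v) for k, v in hist.items()}
    hist["dt"] = dt
    hist["final"] = sim
    return hist


def run_fusiform_elongation(mesh: Mesh, protocol: ElongationProtocol,
                            settings: ExplicitSettings,
                            params: MaterialParams,
                            reference_area: str = "mid",
                            record_fields: bool = False,
                            settle_time: float = 0.0,
                            settle_damping: float | None = None,
                            grip: str = "clamped"):
    """Uniaxial elongation of a meshed specimen along z.

    One end (``fixed_end``) is held, the other (``pulled_end``) moves at
    the protocol velocity along the axis after the isometric hold, then
    holds for ``settle_time`` (under ``settle_damping``, default
    near-critical) so inertial ringing decays before the final reaction
    is read.  ``grip='clamped'`` fixes the end caps laterally (rigid
    grips, with their incompressibility boundary layers);
    ``grip='axial'`` constrains only the axial motion and pins one
    near-axis node per cap against rigid lateral drift, leaving the caps
    free to contract.  Engineering stress uses the mid-belly
    cross-sectional area by default (``reference_area='end'`` switches
    to the end-cap area); both normalizations of the same reaction force
    are returned.
    """
    for name in ("fixed_end", "pulled_end"):
        if name not in mesh.node_sets:
            raise ConvergenceError(f"mesh lacks node set {name!r}")
    if grip not in ("clamped", "axial"):
        raise ConvergenceError(f"unknown grip {grip!r}")
    pull_end = protocol.hold_duration + protocol.pull_duration

    def pull(t):
        return protocol.pull_velocity \
            if protocol.hold_duration < t <= pull_end else 0.0

    fixed = mesh.node_sets["fixed_end"]
    pulled = mesh.node_sets["pulled_end"]
    bcs = [
        BoundaryCondition(nodes=fixed, dofs=(2,), velocity=0.0),
        BoundaryCondition(nodes=pulled, dofs=(2,), velocity=pull),
    ]
    if grip == "clamped":
        bcs += [BoundaryCondition(nodes=fixed, dofs=(0, 1), velocity=0.0),
                BoundaryCondition(nodes=pulled, dofs=(0, 1), velocity=0.0)]
    else:
        r2 = mesh.nodes[:, 0] ** 2 + mesh.nodes[:, 1] ** 2
        pins = np.array([cap[np.argmin(r2[cap])] for cap in (fixed, pulled)])
        bcs += [BoundaryCondition(nodes=pins, dofs=(0, 1), velocity=0.0)]
    act = (lambda t: float(protocol.activation_level(t, params))) \
        if protocol.active else 0.0
    settings = dataclasses.replace(
        settings, total_time=pull_end + settle_time)
    c_settle = settle_damping if settle_damping is not None \
        else max(settings.damping,
                 settle_damping_estimate(mesh, settings, params))
    hist = run_explicit(
        mesh, settings, bcs, params, activation=act,
        reaction_set="fixed_end", record_fields=record_fields,
        damping_fn=lambda t: settings.damping if t <= pull_end
        else c_settle)

    z = mesh.nodes[:, 2]
    length = float(z.max() - z.min())
    end_area = _cap_area(mesh, "inlet")
    mid_area = _midbelly_area(mesh)
    area = mid_area if reference_area == "mid" else end_area
    t = hist["time"]
    disp = np.array([pull_dist(tt, protocol) for tt in t])
    hist["strain"] = disp / length
    # axial force transmitted through the fixed section (tension positive)
    fz = -hist["reaction"][:, 2] if len(hist["reaction"]) else np.array([])
    hist["eng_stress"] = fz / area
    hist["eng_stress_mid"] = fz / mid_area
    hist["eng_stress_end"] = fz / end_area
    hist["reference_area"] = area
    return hist


def pull_dist(t: float, protocol: ElongationProtocol) -> float:
    return protocol.pull_velocity * min(
        max(0.0, t - protocol.hold_duration), protocol.pull_duration)


def _cap_area(mesh: Mesh, facet_set: str) -> float:
    if facet_set in mesh.facet_sets:
        return float(np.sum(mesh.facet_areas(mesh.facet_sets[facet_set])))
    raise ConvergenceError(f"mesh lacks facet set {facet_set!r}")


def _midbelly_area(mesh: Mesh) -> float:
    """Cross-sectional area at mid-length, estimated from the element
    volume density: A(z_mid) ~ dV/dz via a thin slab around the mid plane."""
    z = mesh.nodes[:, 2]
    z_mid = 0.5 * (z.max() + z.min())
    cent = mesh.element_centroids()[:, 2]
    vols = mesh.volumes()
    h = 0.08 * (z.max() - z.min())
    for _ in range(6):  # widen until the slab holds elements
        sel = np.abs(cent - z_mid) < h / 2.0
        if np.count_nonzero(sel) >= 4:
            return float(vols[sel].sum() / h)
        h *= 2.0
    return float(vols.sum() / (z.max() - z.min()))


def run_uniaxial_box(mesh: Mesh, strain_rate: float, final_strain: float,
                     settings: ExplicitSettings, params: MaterialParams,
                     activation=0.0, settle_time: float = 0.0):
    """Uniaxial pull of a box mesh along x with symmetry conditions.

    Faces x0/y0/z0 are constrained in their normal directions, the x1
    face moves at ``strain_rate * Lx``; lateral faces are free, so the
    stress state is homogeneous uniaxial.  After the ramp the end is
    held for ``settle_time`` so the (stiff) lateral/volumetric modes
    equilibrate before the reaction is read.  Returns the run_explicit
    history plus the engineering stress (x-reaction / reference area).
    """
    lx = float(mesh.nodes[:, 0].max())
    v = strain_rate * lx
    ramp = final_strain / strain_rate
    settings = dataclasses.replace(settings, total_time=ramp + settle_time)
    bcs = [
        BoundaryCondition(mesh.node_sets["x0"], (0,), 0.0),
        BoundaryCondition(mesh.node_sets["y0"], (1,), 0.0),
        BoundaryCondition(mesh.node_sets["z0"], (2,), 0.0),
        BoundaryCondition(mesh.node_sets["x1"], (0,),
                          lambda t: v if t <= ramp else 0.0),
    ]
    c_settle = max(settings.damping,
                   settle_damping_estimate(mesh, settings, params))
    hist = run_explicit(
        mesh, settings, bcs, params, activation=activation,
        reaction_set="x0",
        damping_fn=lambda t: settings.damping if t <= ramp
        else c_settle)
    area = float(mesh.nodes[:, 1].max() * mesh.nodes[:, 2].max())
    hist["strain"] = np.minimum(hist["time"], ramp) * v / lx
    hist["eng_stress"] = -hist["reaction"][:, 0] / area
    return hist


def von_mises(sig: np.ndarray) -> np.ndarray:
    """Von Mises effective stress of a batch of stress tensors."""
    tr = np.trace(sig, axis1=-2, axis2=-1) / 3.0
    dev = sig - tr[..., None, None] * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def vm_percentile(field, q: float) -> float:
    """q-th percentile of an element stress field (linear interpolation
    between order statistics; q=0 the minimum, q=100 the maximum)."""
    field = np.asarray(field, dtype=float)
    if field.size == 0:
        raise ValueError("empty stress field")
    if not 0.0 <= q <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(field, q, method="linear"))
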