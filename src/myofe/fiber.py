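"""Flow-based estimation of muscle fiber architecture.

Muscle origin and insertion patches are treated as inlet and outlet of an
incompressible flow through the muscle volume, with the remaining surface
impenetrable; the interior velocity directions then trace fiber-like
streamlines from origin to insertion.  Because only the *directions* are
consumed, a steady incompressible potential flow (a Laplace problem for
the velocity potential, solved with linear finite elements) is used: in
channel-like domains its streamlines align closely with those of a
viscous flow, at a fraction of the cost.

Boundary conditions: uniform normal flux on inlet and outlet (total flux
+Q and -Q, so discrete mass balance holds exactly), natural zero-flux on
walls, and one pinned potential node for uniqueness.  A Dirichlet variant
(uniform potential on inlet/outlet) is available by flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError
from .mesh import Mesh

__all__ = ["FlowProblem", "FlowSolution", "FiberField", "solve_flow",
           "to_fiber_field", "export_fibers", "estimate_fibers"]


@dataclasses.dataclass(frozen=True)
class FlowProblem:
    """Potential-flow boundary-value problem on a tet mesh."""

    mesh: Mesh
    inlet: str = "inlet"
    outlet: str = "outlet"
    flux: float = 1.0
    dirichlet: bool = False

    def __post_init__(self) -> None:
        for name in (self.inlet, self.outlet):
            facets = self.mesh.facet_sets.get(name)
            if facets is None or len(facets) == 0:
                raise ConfigurationError(
                    f"facet set {name!r} missing or empty")
        if self.flux <= 0.0:
            raise ConfigurationError("flux must be positive")
        a = set(map(tuple, np.sort(self.mesh.facet_sets[self.inlet], axis=1)
                    .tolist()))
        b = set(map(tuple, np.sort(self.mesh.facet_sets[self.outlet], axis=1)
                    .tolist()))
        if a & b:
            raise ConfigurationError("inlet and outlet facet sets overlap")


@dataclasses.dataclass
class FlowSolution:
    """Nodal potential and element velocities of a solved flow problem."""

    potential: np.ndarray        # (n_nodes,)
    velocity: np.ndarray         # (n_elements, 3)
    residual: np.ndarray         # assembled nodal residual K phi - b
    flux: float


@dataclasses.dataclass
class FiberField:
    """Per-element unit fiber directions, oriented inlet -> outlet."""

    directions: np.ndarray       # (n_elements, 3), unit norm


def _shape_gradients(mesh: Mesh):
    """Per-element constant shape-function gradients and volumes."""
    X = mesh.nodes[mesh.tets]                      # (m, 4, 3)
    Dm = X[:, 1:] - X[:, :1]                       # (m, 3, 3) rows=edges
    det = np.linalg.det(Dm)
    vol = det / 6.0
    Dm_inv = np.linalg.inv(Dm)                     # (m, 3, 3)
    # gradient of barycentric coords 1..3 are rows of Dm^{-T}... build all 4
    g123 = np.transpose(Dm_inv, (0, 2, 1))         # rows i: grad N_{i+1}
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)     # (m, 4, 3)
    return grads, vol


def _assemble_laplacian(mesh: Mesh) -> sp.csr_matrix:
    grads, vol = _shape_gradients(mesh)
    ke = np.einsum("e,eai,ebi->eab", vol, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix((ke.reshape(-1), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes))
    return K.tocsr()


def _facet_flux_load(mesh: Mesh, facets: np.ndarray, total_flux: float,
                     b: np.ndarray) -> None:
    areas = mesh.facet_areas(facets)
    q = total_flux / np.sum(areas)          # uniform normal flux
    contrib = q * areas / 3.0
    for corner in range(3):
        np.add.at(b, facets[:, corner], contrib)


def solve_flow(problem: FlowProblem) -> FlowSolution:
    """Solve the potential-flow problem; velocity = -grad(potential).

    The inlet carries total flux +Q into the domain and the outlet -Q, so
    the discrete balance is exact by construction; the returned residual
    lets callers verify interior (divergence) consistency.
    """
    mesh = problem.mesh
    K = _assemble_laplacian(mesh)
    b = np.zeros(mesh.n_nodes)
    inlet = mesh.facet_sets[problem.inlet]
    outlet = mesh.facet_sets[problem.outlet]
    _facet_flux_load(mesh, inlet, problem.flux, b)
    _facet_flux_load(mesh, outlet, -problem.flux, b)

    if problem.dirichlet:
        # uniform potential on inlet (1) and outlet (0)
        fixed = np.unique(np.concatenate([inlet.ravel(), outlet.ravel()]))
        vals = np.zeros(mesh.n_nodes)
        vals[np.unique(inlet.ravel())] = 1.0
        free = np.setdiff1d(np.arange(mesh.n_nodes), fixed)
        phi = vals.copy()
        rhs = -K[free][:, fixed] @ vals[fixed]
        phi[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    else:
        pin = int(np.unique(inlet.ravel())[0])
        keep = np.setdiff1d(np.arange(mesh.n_nodes), [pin])
        phi = np.zeros(mesh.n_nodes)
        Kff = K[keep][:, keep].tocsc()
        phi[keep] = spla.spsolve(Kff, b[keep])

    grads, _ = _shape_gradients(mesh)
    vel = -np.einsum("ea,eai->ei", phi[mesh.tets], grads)
    residual = K @ phi - b
    return FlowSolution(potential=phi, velocity=vel, residual=residual,
                        flux=problem.flux)


def to_fiber_field(solution: FlowSolution | np.ndarray,
                   problem: FlowProblem) -> FiberField:
    """Normalize element velocities into unit fiber directions.

    The sign convention orients every fiber with a positive component
    along the inlet-to-outlet centroid axis.
    """
    vel = solution.velocity if isinstance(solution, FlowSolution) \
        else np.asarray(solution, dtype=float)
    mesh = problem.mesh
    speed = np.linalg.norm(vel, axis=1)
    dead = speed < 1e-12 * float(np.max(speed, initial=0.0))
    if np.any(dead) or vel.size == 0:
        bad = np.where(dead)[0][:5].tolist()
        raise ConfigurationError(
            f"zero-velocity elements {bad} (disconnected region?)")
    dirs = vel / speed[:, None]
    inlet_c = mesh.nodes[np.unique(mesh.facet_sets[problem.inlet])].mean(0)
    outlet_c = mesh.nodes[np.unique(mesh.facet_sets[problem.outlet])].mean(0)
    axis = outlet_c - inlet_c
    axis = axis / np.linalg.norm(axis)
    flip = dirs @ axis < 0.0
    dirs[flip] *= -1.0
    return FiberField(directions=dirs)


def estimate_fibers(mesh: Mesh, inlet: str = "inlet", outlet: str = "outlet",
                    dirichlet: bool = False) -> FiberField:
    """Convenience wrapper: solve the flow and return the fiber field."""
    problem = FlowProblem(mesh=mesh, inlet=inlet, outlet=outlet,
                          dirichlet=dirichlet)
    return to_fiber_field(solve_flow(problem), problem)


def export_fibers(field: FiberField, mesh: Mesh, path) -> None:
    """Write the fiber field as VTK cell-data vectors."""
    from .meshio_vtk import write_mesh
    if field.directions.shape != (mesh.n_elements, 3):
        raise ConfigurationError("field size does not match mesh")
    out = Mesh(nodes=mesh.nodes, tets=mesh.tets, node_sets=mesh.node_sets,
               facet_sets=mesh.facet_sets, fibers=field.directions)
    write_mesh(out, path)
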