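"""Programmatic test geometries.

All meshes are built from a structured Kuhn (6-tet) subdivision of a box
grid.  Solids of revolution (cylinder, fusiform specimen, curved tube)
map the square cross-section onto a disk with the standard elliptical
mapping, which is smooth, bijective and puts grid corners exactly on the
circle, so no degenerate elements appear on the axis.

The fusiform specimen mimics a spindle-shaped muscle: length L with end
diameter (minimum cross-section) and mid-belly diameter (maximum), the
radius profile blending the two as ``r(z) = r_end + (r_mid - r_end)
sin^2(pi z / L)`` — smooth, mirror-symmetric, and matching both printed
diameters exactly.  Default dimensions are 50 mm length, 9 mm end and
17.5 mm mid-belly diameters.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .errors import ConfigurationError
from .mesh import Mesh, tet_volumes

__all__ = [
    "FusiformSpec",
    "make_fusiform",
    "make_cylinder",
    "make_tube",
    "make_two_block",
    "make_box",
    "centerline_tangent_tube",
]


@dataclasses.dataclass(frozen=True)
class FusiformSpec:
    """Dimensions and resolution of the fusiform specimen (SI units)."""

    length: float = 0.050
    end_diameter: float = 0.009
    mid_diameter: float = 0.0175
    n_cross: int = 6    # cells across the square parameter cross-section
    n_axial: int = 20   # axial layers

    def __post_init__(self) -> None:
        if not (self.mid_diameter >= self.end_diameter > 0.0):
            raise ConfigurationError(
                "need mid_diameter >= end_diameter > 0")
        if not self.length > 0.0:
            raise ConfigurationError("length must be positive")
        if self.n_cross < 2 or self.n_axial < 2:
            raise ConfigurationError("resolutions must be >= 2")


def _kuhn_tets(nx: int, ny: int, nz: int) -> np.ndarray:
    """Consistent 6-tet subdivision of an (nx, ny, nz)-cell box grid."""

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    perms = list(itertools.permutations(range(3)))
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                p0 = np.array([i, j, k])
                for perm in perms:
                    a = p0.copy()
                    path = [a.copy()]
                    for axis in perm:
                        a = a.copy()
                        a[axis] += 1
                        path.append(a.copy())
                    tets.append([nid(*p) for p in path])
    return np.asarray(tets, dtype=np.int64)


def _fix_orientation(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    vols = tet_volumes(nodes, tets)
    flip = vols < 0.0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


def _square_to_disk(x: np.ndarray, y: np.ndarray):
    """Elliptical square-to-disk mapping on [-1, 1]^2."""
    return (x * np.sqrt(1.0 - 0.5 * y ** 2),
            y * np.sqrt(1.0 - 0.5 * x ** 2))


def _end_sets(mesh: Mesh, axis_coord, z_lo: float, z_hi: float,
              tol: float) -> None:
    """Tag end caps (node sets + facet sets) and the lateral wall."""
    z = axis_coord
    mesh.node_sets["fixed_end"] = np.where(np.abs(z - z_lo) < tol)[0]
    mesh.node_sets["pulled_end"] = np.where(np.abs(z - z_hi) < tol)[0]
    bnd = mesh.boundary()
    on_lo = np.all(np.abs(z[bnd] - z_lo) < tol, axis=1)
    on_hi = np.all(np.abs(z[bnd] - z_hi) < tol, axis=1)
    mesh.facet_sets["inlet"] = bnd[on_lo]
    mesh.facet_sets["outlet"] = bnd[on_hi]
    mesh.facet_sets["wall"] = bnd[~(on_lo | on_hi)]


def _revolved_mesh(radius_of_z, length: float, n_cross: int,
                   n_axial: int) -> Mesh:
    n = n_cross
    u = np.linspace(-1.0, 1.0, n + 1)
    zs = np.linspace(0.0, length, n_axial + 1)
    X, Y, Z = np.meshgrid(u, u, zs, indexing="ij")
    xd, yd = _square_to_disk(X, Y)
    r = radius_of_z(Z)
    nodes = np.stack([xd * r, yd * r, Z], axis=-1).reshape(-1, 3)
    tets = _fix_orientation(nodes, _kuhn_tets(n, n, n_axial))
    mesh = Mesh(nodes=nodes, tets=tets)
    tol = 1e-9 * max(length, 1.0)
    _end_sets(mesh, nodes[:, 2], 0.0, length, tol)
    mesh.set_uniform_fibers([0.0, 0.0, 1.0])
    return mesh


def make_fusiform(spec: FusiformSpec | None = None) -> Mesh:
    """Watertight tet mesh of the fusiform specimen.

    End caps are tagged ``fixed_end``/``pulled_end`` (node sets) and
    ``inlet``/``outlet`` (facet sets, for flow-based fiber estimation);
    the lateral surface is ``wall``.  Default fibers run along the axis.
    """
    spec = spec or FusiformSpec()
    r_end = spec.end_diameter / 2.0
    r_mid = spec.mid_diameter / 2.0

    def radius(z):
        return r_end + (r_mid - r_end) * np.sin(np.pi * z / spec.length) ** 2

    mesh = _revolved_mesh(radius, spec.length, spec.n_cross, spec.n_axial)
    mesh.validate()
    return mesh


def make_cylinder(length: float, diameter: float, n_cross: int = 6,
                  n_axial: int = 10) -> Mesh:
    """Straight circular cylinder along z with tagged end caps."""
    if length <= 0.0 or diameter <= 0.0:
        raise ConfigurationError("dimensions must be positive")
    r = diameter / 2.0
    mesh = _revolved_mesh(lambda z: r + 0.0 * z, length, n_cross, n_axial)
    mesh.validate()
    return mesh


def make_tube(bend_angle: float, bend_radius: float, tube_diameter: float,
              n_cross: int = 4, n_axial: int = 24) -> Mesh:
    """Circular tube swept along a circular arc in the x-z plane.

    The centerline is ``c(phi) = (R sin phi, 0, R (1 - cos phi))`` for
    phi in [0, bend_angle]; inlet at phi = 0, outlet at the far end.
    Default fibers follow the local centerline tangent.
    """
    if not (0.0 < bend_angle <= np.pi):
        raise ConfigurationError("bend_angle must be in (0, pi]")
    if tube_diameter >= 2.0 * bend_radius:
        raise ConfigurationError("tube must not self-intersect the bend")
    r = tube_diameter / 2.0
    n = n_cross
    u = np.linspace(-1.0, 1.0, n + 1)
    s = np.linspace(0.0, 1.0, n_axial + 1)
    X, Y, S = np.meshgrid(u, u, s, indexing="ij")
    xd, yd = _square_to_disk(X, Y)
    phi = bend_angle * S
    # local frame: normal (radial, in-plane), binormal (out of plane)
    cx = bend_radius * np.sin(phi)
    cz = bend_radius * (1.0 - np.cos(phi))
    nx_, nz_ = -np.sin(phi), np.cos(phi)
    px = cx + r * xd * nx_
    py = r * yd
    pz = cz + r * xd * nz_
    nodes = np.stack([px, py, pz], axis=-1).reshape(-1, 3)
    tets = _fix_orientation(nodes, _kuhn_tets(n, n, n_axial))
    mesh = Mesh(nodes=nodes, tets=tets)

    sflat = S.reshape(-1)
    tol = 1e-9
    mesh.node_sets["fixed_end"] = np.where(sflat < tol)[0]
    mesh.node_sets["pulled_end"] = np.where(sflat > 1.0 - tol)[0]
    bnd = mesh.boundary()
    on_lo = np.all(sflat[bnd] < tol, axis=1)
    on_hi = np.all(sflat[bnd] > 1.0 - tol, axis=1)
    mesh.facet_sets["inlet"] = bnd[on_lo]
    mesh.facet_sets["outlet"] = bnd[on_hi]
    mesh.facet_sets["wall"] = bnd[~(on_lo | on_hi)]

    cent = mesh.element_centroids()
    phi_c = np.arctan2(cent[:, 0], bend_radius - cent[:, 2])
    fibers = np.stack([np.cos(phi_c), np.zeros_like(phi_c),
                       np.sin(phi_c)], axis=1)
    mesh.fibers = fibers
    mesh.validate()
    return mesh


def centerline_tangent_tube(mesh: Mesh, bend_radius: float) -> np.ndarray:
    """Analytic centerline tangents at element centroids of a bent tube."""
    cent = mesh.element_centroids()
    phi = np.arctan2(cent[:, 0], bend_radius - cent[:, 2])
    return np.stack([np.cos(phi), np.zeros_like(phi), np.sin(phi)], axis=1)


def make_two_block(gap: float, size: float, n: int = 2):
    """Two cubic blocks separated along z by ``gap``, with facing
    cohesive facet sets.

    Returns a single :class:`Mesh` holding both blocks with sets
    ``block_a``/``block_b`` (nodes), ``bottom_a``/``top_b`` (outer faces)
    and ``cohesive_a``/``cohesive_b`` (the facing surfaces).
    """
    if gap < 0.0 or size <= 0.0:
        raise ConfigurationError("need gap >= 0 and size > 0")
    u = np.linspace(0.0, size, n + 1)
    X, Y, Z = np.meshgrid(u, u, u, indexing="ij")
    nodes_a = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    nodes_b = nodes_a + np.array([0.0, 0.0, size + gap])
    tets_a = _fix_orientation(nodes_a, _kuhn_tets(n, n, n))
    nodes = np.vstack([nodes_a, nodes_b])
    tets = np.vstack([tets_a, tets_a + nodes_a.shape[0]])
    mesh = Mesh(nodes=nodes, tets=tets)

    na = nodes_a.shape[0]
    z = nodes[:, 2]
    tol = 1e-9 * size
    mesh.node_sets["block_a"] = np.arange(na)
    mesh.node_sets["block_b"] = np.arange(na, nodes.shape[0])
    mesh.node_sets["bottom_a"] = np.where(np.abs(z) < tol)[0]
    mesh.node_sets["top_b"] = np.where(np.abs(z - (2 * size + gap)) < tol)[0]
    bnd = mesh.boundary()
    top_a = np.all((np.abs(z[bnd] - size) < tol) & (bnd < na), axis=1)
    bot_b = np.all((np.abs(z[bnd] - (size + gap)) < tol) & (bnd >= na),
                   axis=1)
    mesh.facet_sets["cohesive_a"] = bnd[top_a]
    mesh.facet_sets["cohesive_b"] = bnd[bot_b]
    mesh.set_uniform_fibers([0.0, 0.0, 1.0])
    mesh.validate()
    return mesh


def make_box(lx: float, ly: float, lz: float, nx: int = 1, ny: int = 1,
             nz: int = 1, fiber=(1.0, 0.0, 0.0)) -> Mesh:
    """Axis-aligned box mesh with face node sets ``x0/x1/y0/y1/z0/z1``.

    Used for single-element and patch uniaxial tests (symmetry boundary
    conditions on the x0/y0/z0 faces, pull on x1).
    """
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    tets = _fix_orientation(nodes, _kuhn_tets(nx, ny, nz))
    mesh = Mesh(nodes=nodes, tets=tets)
    tol = 1e-12 + 1e-9 * max(lx, ly, lz)
    for axis, name, length in ((0, "x", lx), (1, "y", ly), (2, "z", lz)):
        c = nodes[:, axis]
        mesh.node_sets[f"{name}0"] = np.where(np.abs(c) < tol)[0]
        mesh.node_sets[f"{name}1"] = np.where(np.abs(c - length) < tol)[0]
    mesh.set_uniform_fibers(fiber)
    mesh.validate()
    return mesh
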