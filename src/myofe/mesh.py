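"""Tetrahedral mesh container with named boundary sets.

Nodes are reference coordinates in metres.  Boundary conditions and
contact surfaces are addressed through named node sets and triangular
facet sets; per-element reference fiber directions ride along as a
unit-vector field.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import ConfigurationError, InvalidDeformationError

__all__ = ["Mesh", "tet_volumes", "boundary_facets"]


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0


def boundary_facets(tets: np.ndarray) -> np.ndarray:
    """Triangular facets that belong to exactly one tetrahedron,
    oriented outward (right-hand normal pointing away from the element)."""
    local = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    faces = tets[:, local].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
    return faces[counts[inverse] == 1]


@dataclasses.dataclass
class Mesh:
    """Tetrahedral volume mesh.

    Attributes
    ----------
    nodes : (n, 3) float array, metres
    tets : (m, 4) int array, positively oriented
    node_sets : dict[str, int array]
    facet_sets : dict[str, (f, 3) int array]
        Boundary triangles, outward oriented.
    fibers : (m, 3) float array or None
        Per-element unit reference fiber direction.
    """

    nodes: np.ndarray
    tets: np.ndarray
    node_sets: dict = dataclasses.field(default_factory=dict)
    facet_sets: dict = dataclasses.field(default_factory=dict)
    fibers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ConfigurationError("nodes must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ConfigurationError("tets must be (m, 4)")
        if self.fibers is not None:
            self.fibers = np.asarray(self.fibers, dtype=float)
            if self.fibers.shape != (self.n_elements, 3):
                raise ConfigurationError("fibers must be (m, 3)")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def total_volume(self) -> float:
        return float(np.sum(self.volumes()))

    def boundary(self) -> np.ndarray:
        return boundary_facets(self.tets)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def facet_areas(self, facets: np.ndarray) -> np.ndarray:
        a = self.nodes[facets[:, 1]] - self.nodes[facets[:, 0]]
        b = self.nodes[facets[:, 2]] - self.nodes[facets[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def facet_normals(self, facets: np.ndarray) -> np.ndarray:
        a = self.nodes[facets[:, 1]] - self.nodes[facets[:, 0]]
        b = self.nodes[facets[:, 2]] - self.nodes[facets[:, 0]]
        n = np.cross(a, b)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def set_uniform_fibers(self, direction) -> None:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        self.fibers = np.tile(d, (self.n_elements, 1))

    def validate(self, check_duplicates: bool = True) -> None:
        """Raise on inverted elements, dangling set references, non-unit
        fibers or duplicate nodes (within 1e-12 m)."""
        vols = self.volumes()
        if np.any(vols <= 0.0):
            bad = int(np.argmin(vols))
            raise InvalidDeformationError(
                f"non-positive volume in element {bad}: {vols[bad]:.3e}")
        for name, idx in self.node_sets.items():
            if np.any(np.asarray(idx) >= self.n_nodes):
                raise ConfigurationError(f"node set {name!r} out of range")
        for name, facets in self.facet_sets.items():
            if np.any(np.asarray(facets) >= self.n_nodes):
                raise ConfigurationError(f"facet set {name!r} out of range")
        if self.fibers is not None:
            norms = np.linalg.norm(self.fibers, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-10):
                raise ConfigurationError("fiber vectors must be unit length")
        if check_duplicates:
            rounded = np.round(self.nodes / 1e-12).astype(np.int64)
            uniq = np.unique(rounded, axis=0)
            if uniq.shape[0] != self.n_nodes:
                raise ConfigurationError("duplicate nodes within 1e-12 m")
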