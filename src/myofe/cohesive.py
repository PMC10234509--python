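"""Cohesive traction-separation contact between paired surfaces.

Models the epimysium-mediated interaction between adjacent muscles (and
muscle and bone): tension normal to the interface is resisted by a linear
traction-separation spring, tangential sliding by independent tangential
springs — no friction coupling — so structures stay tethered while still
sliding relative to each other.  Each separation component is linear up
to its damage-initiation separation; beyond it the traction is held at
the initiation value (the interface tethers, it does not fracture), or
released to zero when ``release_after_damage`` is set.

Pairing is nearest-point projection of each facet centroid of surface A
onto surface B, computed once in the reference configuration.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import trimesh

from .errors import ConfigurationError
from .mesh import Mesh

__all__ = ["CohesiveParams", "CohesivePairing", "build_pairing",
           "cohesive_tractions"]


@dataclasses.dataclass(frozen=True)
class CohesiveParams:
    """Cohesive stiffnesses [Pa/m] and damage-initiation separations [m].

    The canonical muscle-interaction values are 0.05 N/mm^3 stiffness on
    all three components and 30 mm initiation separation; use
    :meth:`from_mm` for mm-based input.
    """

    K_nn: float = 5.0e7
    K_ss: float = 5.0e7
    K_tt: float = 5.0e7
    D_nn: float = 0.030
    D_ss: float = 0.030
    D_tt: float = 0.030
    release_after_damage: bool = False

    def __post_init__(self) -> None:
        for name in ("K_nn", "K_ss", "K_tt", "D_nn", "D_ss", "D_tt"):
            if not getattr(self, name) > 0.0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_mm(cls, K_n_per_mm3: float = 0.05, D_mm: float = 30.0,
                **kw) -> "CohesiveParams":
        """Build from N/mm^3 stiffness and mm separation (SI conversion:
        1 N/mm^3 = 1e9 Pa/m)."""
        K = K_n_per_mm3 * 1.0e9
        D = D_mm * 1.0e-3
        return cls(K_nn=K, K_ss=K, K_tt=K, D_nn=D, D_ss=D, D_tt=D, **kw)


@dataclasses.dataclass
class CohesivePairing:
    """Reference-configuration pairing of surface A points onto surface B."""

    facets_a: np.ndarray      # (p, 3) node ids of A facets
    facets_b: np.ndarray      # (p, 3) node ids of the paired B facets
    bary_b: np.ndarray        # (p, 3) barycentric weights on the B facet
    normals: np.ndarray       # (p, 3) reference outward normals of A
    tangents1: np.ndarray     # (p, 3)
    tangents2: np.ndarray     # (p, 3)
    areas: np.ndarray         # (p,) reference areas of A facets
    ref_gap: np.ndarray       # (p, 3) reference vector A point -> B point


def build_pairing(mesh: Mesh, set_a: str, set_b: str) -> CohesivePairing:
    """Pair each facet centroid of ``set_a`` with its nearest point on
    ``set_b`` (reference configuration, fixed thereafter)."""
    for name in (set_a, set_b):
        if name not in mesh.facet_sets or len(mesh.facet_sets[name]) == 0:
            raise ConfigurationError(f"facet set {name!r} missing or empty")
    fa = np.asarray(mesh.facet_sets[set_a], dtype=np.int64)
    fb = np.asarray(mesh.facet_sets[set_b], dtype=np.int64)
    pts_a = mesh.nodes[fa].mean(axis=1)

    surf_b = trimesh.Trimesh(vertices=mesh.nodes, faces=fb, process=False)
    # all-pairs query: cohesive surface pairs are small by construction
    closest, _, tri_id = trimesh.proximity.closest_point_naive(surf_b, pts_a)
    bary = trimesh.triangles.points_to_barycentric(
        mesh.nodes[fb[tri_id]], closest)

    normals = mesh.facet_normals(fa)
    t1 = np.cross(normals, np.where(
        np.abs(normals[:, [0]]) < 0.9,
        np.tile([1.0, 0.0, 0.0], (len(fa), 1)),
        np.tile([0.0, 1.0, 0.0], (len(fa), 1))))
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    return CohesivePairing(
        facets_a=fa, facets_b=fb[tri_id], bary_b=np.asarray(bary),
        normals=normals, tangents1=t1, tangents2=t2,
        areas=mesh.facet_areas(fa), ref_gap=closest - pts_a)


def _component(delta, limit, K, release):
    """Linear traction with plateau (or release) past damage initiation."""
    lin = K * delta
    cap = K * limit
    if release:
        return np.where(np.abs(delta) > limit, 0.0, lin)
    return np.clip(lin, -cap, cap)


def cohesive_tractions(pairing: CohesivePairing, displacements: np.ndarray,
                       cohesive: CohesiveParams):
    """Nodal force contributions of the cohesive interface.

    Parameters
    ----------
    pairing : CohesivePairing
    displacements : (n_nodes, 3) array
    cohesive : CohesiveParams

    Returns
    -------
    (forces, tractions) : ((n_nodes, 3) array, (p, 3) array)
        Assembled nodal forces (equal and opposite on the two surfaces)
        and the per-pair traction vectors [Pa] acting on surface A.

    The separation is the change of the A-point to B-point gap vector
    relative to the reference configuration, decomposed in the reference
    normal/tangent frame of A; traction is componentwise
    stiffness * separation below damage initiation.
    """
    u = np.asarray(displacements, dtype=float)
    ua = u[pairing.facets_a].mean(axis=1)
    ub = np.einsum("pa,pai->pi", pairing.bary_b, u[pairing.facets_b])
    delta = ub - ua   # change of gap vector; positive normal comp = opening
    # NOTE: A's outward normal points toward B, so gap growth along +n
    # means the surfaces separate.
    dn = np.einsum("pi,pi->p", delta, pairing.normals)
    ds = np.einsum("pi,pi->p", delta, pairing.tangents1)
    dt_ = np.einsum("pi,pi->p", delta, pairing.tangents2)

    rel = cohesive.release_after_damage
    tn = _component(dn, cohesive.D_nn, cohesive.K_nn, rel)
    ts = _component(ds, cohesive.D_ss, cohesive.K_ss, rel)
    tt = _component(dt_, cohesive.D_tt, cohesive.K_tt, rel)
    trac = (tn[:, None] * pairing.normals
            + ts[:, None] * pairing.tangents1
            + tt[:, None] * pairing.tangents2)

    # traction pulls A toward B (restores the reference gap); reaction on B
    f_pair = trac * pairing.areas[:, None]
    forces = np.zeros_like(u)
    for corner in range(3):
        np.add.at(forces, pairing.facets_a[:, corner], f_pair / 3.0)
        np.add.at(forces, pairing.facets_b[:, corner],
                  -pairing.bary_b[:, corner, None] * f_pair)
    return forces, trac
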