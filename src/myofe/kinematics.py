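"""Deformation-gradient derived kinematic measures.

The constitutive split works with the isochoric/volumetric decomposition:
``J = det F``, ``C = F^T F``, the isochoric first invariant
``I1bar = J^(-2/3) tr C`` and the modified (volume-eliminated) fiber
stretch ``lambda_f_bar = J^(-1/3) lambda_f`` with
``lambda_f = sqrt(a0 . C a0)`` for a unit reference fiber direction a0.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import InvalidDeformationError

__all__ = ["KinematicMeasures", "kinematics_from_deformation"]


@dataclasses.dataclass(frozen=True)
class KinematicMeasures:
    """Bundle of deformation measures at a material point."""

    F: np.ndarray
    J: float
    C: np.ndarray
    I1bar: float
    a0: np.ndarray
    lambda_f: float
    lambda_f_bar: float


def kinematics_from_deformation(F, a0) -> KinematicMeasures:
    """Compute all kinematic measures from a deformation gradient.

    Parameters
    ----------
    F : (3, 3) array_like
        Deformation gradient with positive determinant.
    a0 : (3,) array_like
        Reference fiber direction; must be unit length.  Deviations below
        1e-6 are renormalized with a warning, larger ones are an error.

    Raises
    ------
    InvalidDeformationError
        If ``det F <= 0`` or ``a0`` is far from unit length.
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    if F.shape != (3, 3) or a0.shape != (3,):
        raise InvalidDeformationError(
            f"expected F (3,3) and a0 (3,), got {F.shape} and {a0.shape}")
    J = float(np.linalg.det(F))
    if not J > 0.0:
        raise InvalidDeformationError(f"non-positive Jacobian det(F) = {J}")
    norm = float(np.linalg.norm(a0))
    dev = abs(norm - 1.0)
    if dev > 1e-10:
        if dev < 1e-6:
            warnings.warn(
                f"fiber direction off unit length by {dev:.2e}; renormalizing",
                stacklevel=2)
            a0 = a0 / norm
        else:
            raise InvalidDeformationError(
                f"fiber direction norm {norm} deviates from 1 by {dev:.2e}")
    C = F.T @ F
    I1bar = float(J ** (-2.0 / 3.0) * np.trace(C))
    lambda_f = float(np.sqrt(a0 @ C @ a0))
    lambda_f_bar = float(J ** (-1.0 / 3.0) * lambda_f)
    return KinematicMeasures(F=F, J=J, C=C, I1bar=I1bar, a0=a0,
                             lambda_f=lambda_f, lambda_f_bar=lambda_f_bar)
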