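"""Tension-only ligament/graft elements with a piecewise quadratic--linear law.

Each ligament (or reconstruction graft) is a *functional bundle*: a straight
line-of-action element between one femoral and one tibial insertion.  Its
engineering strain is ``D = (L - L0) / L0`` and the tension follows the
standard toe-region law used for knee ligaments:

* ``F = 0``                        when slack (``D < 0``),
* ``F = k * D^2 / (4 * DL)``       in the quadratic toe region (``0 <= D <= 2*DL``),
* ``F = k * (D - DL)``             in the linear region (``D > 2*DL``),

where ``k`` is a stiffness in N (force per unit strain) and ``DL`` is the
transition strain, 0.03 by default.  The two branches agree in value and in
first derivative at ``D = 2*DL``, so the law is C1; bundles never transmit
compression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from kneemech.errors import (
    DegenerateElementError,
    InvalidGeometryError,
    InvalidParameterError,
)
from kneemech.rigid import RigidTransform

DEFAULT_TRANSITION_STRAIN = 0.03


@dataclass(frozen=True)
class LigamentBundle:
    """One tension-only functional bundle (also used for the graft).

    Insertions are in mm, each in the frame of the bone it attaches to.
    ``stiffness_k`` is in N (tension per unit strain in the linear region);
    ``reference_length_L0`` is the zero-load length in mm.
    """

    name: str
    femur_insertion: np.ndarray
    tibia_insertion: np.ndarray
    stiffness_k: float
    reference_length_L0: float
    transition_strain_DL: float = DEFAULT_TRANSITION_STRAIN

    def __post_init__(self):
        object.__setattr__(self, "femur_insertion", np.asarray(self.femur_insertion, dtype=float))
        object.__setattr__(self, "tibia_insertion", np.asarray(self.tibia_insertion, dtype=float))
        if self.reference_length_L0 <= 0:
            raise InvalidGeometryError(
                f"bundle {self.name!r}: reference length must be > 0, got {self.reference_length_L0}"
            )
        if self.stiffness_k < 0:
            raise InvalidParameterError(f"bundle {self.name!r}: stiffness must be >= 0")
        if self.transition_strain_DL <= 0:
            raise InvalidParameterError(f"bundle {self.name!r}: transition strain must be > 0")

    def with_parameters(self, stiffness_k=None, reference_length_L0=None) -> "LigamentBundle":
        changes = {}
        if stiffness_k is not None:
            changes["stiffness_k"] = float(stiffness_k)
        if reference_length_L0 is not None:
            changes["reference_length_L0"] = float(reference_length_L0)
        return replace(self, **changes)


def strain(L, L0):
    """Engineering strain ``(L - L0) / L0`` of a bundle of current length L.

    Negative when the bundle is slack.  Lengths in mm; L0 must be positive.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise InvalidGeometryError("current length must be >= 0")
    if np.any(np.asarray(L0, dtype=float) <= 0):
        raise InvalidGeometryError("reference length must be > 0")
    out = (L - L0) / L0
    return float(out) if np.ndim(out) == 0 else out


def bundle_force(D, k, DL=DEFAULT_TRANSITION_STRAIN):
    """Tension (N) of a bundle at strain D: zero / quadratic toe / linear.

    Accepts scalars or arrays of D.
    """
    if np.any(np.asarray(k, dtype=float) < 0):
        raise InvalidParameterError("stiffness k must be >= 0")
    if np.any(np.asarray(DL, dtype=float) <= 0):
        raise InvalidParameterError("transition strain DL must be > 0")
    D = np.asarray(D, dtype=float)
    toe = 0.25 * k * D * D / DL
    linear = k * (D - DL)
    out = np.where(D < 0.0, 0.0, np.where(D <= 2.0 * DL, toe, linear))
    return float(out) if np.ndim(out) == 0 else out


def bundle_force_inverse(F, k, DL=DEFAULT_TRANSITION_STRAIN):
    """Strain at which a bundle carries tension F (inverse of :func:`bundle_force`).

    Used when setting a graft's reference length from a pretension target.
    """
    if F < 0:
        raise InvalidParameterError("tension must be >= 0")
    if k <= 0:
        raise InvalidParameterError("stiffness must be > 0 to invert the force law")
    if DL <= 0:
        raise InvalidParameterError("transition strain DL must be > 0")
    if F == 0.0:
        return 0.0
    # Force at the branch point D = 2*DL is k*DL.
    if F <= k * DL:
        return 2.0 * np.sqrt(F * DL / k)
    return F / k + DL


def _world_insertions(bundle: LigamentBundle, femur_pose: RigidTransform, tibia_pose: RigidTransform):
    return femur_pose.apply(bundle.femur_insertion), tibia_pose.apply(bundle.tibia_insertion)


def bundle_length(bundle: LigamentBundle, femur_pose: RigidTransform, tibia_pose: RigidTransform) -> float:
    """Current straight-line length (mm) of the bundle at the given poses."""
    pf, pt = _world_insertions(bundle, femur_pose, tibia_pose)
    return float(np.linalg.norm(pf - pt))


def bundle_force_vector(bundle: LigamentBundle, femur_pose: RigidTransform, tibia_pose: RigidTransform):
    """World-frame force the bundle exerts on the tibia, plus scalar tension.

    The line of action runs from the tibial insertion toward the femoral
    insertion (a taut bundle pulls the tibia toward the femur); a slack
    bundle exerts nothing.

    Returns
    -------
    (force, tension) : (ndarray shape (3,), float)
    """
    pf, pt = _world_insertions(bundle, femur_pose, tibia_pose)
    d = pf - pt
    length = float(np.linalg.norm(d))
    if length == 0.0:
        raise DegenerateElementError(f"bundle {bundle.name!r} has coincident insertions")
    D = strain(length, bundle.reference_length_L0)
    tension = bundle_force(D, bundle.stiffness_k, bundle.transition_strain_DL)
    if tension == 0.0:
        return np.zeros(3), 0.0
    return (tension / length) * d, float(tension)
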