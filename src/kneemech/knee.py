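"""Rigid femur--tibia knee model and quasi-static laxity solver.

Coordinate convention (right knee, tibia-fixed frame): +X anterior,
+Y superior (tibial long axis), +Z lateral.  All lengths are mm, forces N
and moments N*mm internally; torques cross the API in N*m.

Flexion is prescribed by rotating the femur about a fixed mediolateral
axis.  Two tibial degrees of freedom remain free: anterior translation
along +X and internal rotation about the tibial long axis (+Y, positive
internal for a right knee).  Equilibrium under an applied anterior force
and axial torque is found with a damped Newton iteration on the 2-D
residual (net anterior force, net axial moment).

Reported translations and rotations are *laxity* values: the displacement
produced by the applied load, i.e. the solved pose minus the same
scenario's unloaded equilibrium at that flexion angle.  This mirrors how
anterior-drawer laxity is measured experimentally and makes scenarios with
pretensioned grafts (whose unloaded equilibrium sits slightly posterior)
directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from kneemech.errors import (
    InvalidParameterError,
    ModelConfigurationError,
    SolverError,
    ValidationError,
)
from kneemech.ligaments import (
    LigamentBundle,
    bundle_force_inverse,
    bundle_force_vector,
    bundle_length,
)
from kneemech.rigid import RigidTransform

ACL_PREFIX = "ACL"
GRAFT_NAME = "graft"

STANDARD_FLEXION_ANGLES = (0.0, 30.0, 60.0, 90.0)


@dataclass(frozen=True)
class RestraintSpring:
    """Bilinear point-to-point spring standing in for capsule/meniscus restraint.

    The spring connects a femoral and a tibial attachment point and resists
    excursions of the free DOFs from the zero-DOF pose at the current
    flexion angle (its rest length is taken there), so it contributes
    stiffness without imposing a flexion-dependent neutral shift.
    """

    name: str
    femur_point: np.ndarray
    tibia_point: np.ndarray
    stiffness: float  # N/mm

    def __post_init__(self):
        object.__setattr__(self, "femur_point", np.asarray(self.femur_point, dtype=float))
        object.__setattr__(self, "tibia_point", np.asarray(self.tibia_point, dtype=float))
        if self.stiffness < 0:
            raise InvalidParameterError(f"restraint {self.name!r}: stiffness must be >= 0")


@dataclass(frozen=True)
class TorsionalRestraint:
    """Lumped capsule restraint about the tibial long axis.

    Point-to-point springs between the bones cannot supply the knee's
    axial-rotation stiffness without also adding spurious anterior-posterior
    stiffness, so the peripheral capsule/meniscus contribution to rotation
    is lumped into one torsional element.  Its stiffness decays with
    flexion from the extended-knee value toward the flexed-knee plateau
    (the capsule is wound tight in extension and slackens quickly):

        k(phi) = k_90 + (k_0 - k_90) * exp(-phi / tau)

    with all stiffnesses in N*mm per degree and ``tau`` in degrees.
    """

    stiffness_0_Nmm_per_deg: float
    stiffness_90_Nmm_per_deg: float
    decay_deg: float = 30.0

    def __post_init__(self):
        if self.stiffness_0_Nmm_per_deg < 0 or self.stiffness_90_Nmm_per_deg < 0:
            raise InvalidParameterError("torsional stiffness must be >= 0")
        if self.decay_deg <= 0:
            raise InvalidParameterError("torsional decay constant must be > 0")

    def stiffness_at(self, flexion_deg: float) -> float:
        return self.stiffness_90_Nmm_per_deg + (
            self.stiffness_0_Nmm_per_deg - self.stiffness_90_Nmm_per_deg
        ) * math.exp(-max(flexion_deg, 0.0) / self.decay_deg)


@dataclass(frozen=True)
class KneeGeometry:
    """Bundle set, restraint springs and flexion axis of one knee.

    ``acl_footprint_femur``/``acl_footprint_tibia`` are the native ACL
    insertion centroids (the tunnel sites used for reconstruction); they are
    stored explicitly so they survive ACL resection.
    """

    bundles: tuple
    restraint_springs: tuple
    flexion_axis_point: np.ndarray
    flexion_axis_direction: np.ndarray
    acl_footprint_femur: np.ndarray
    acl_footprint_tibia: np.ndarray
    torsional_restraint: Optional[TorsionalRestraint] = None

    def __post_init__(self):
        object.__setattr__(self, "bundles", tuple(self.bundles))
        object.__setattr__(self, "restraint_springs", tuple(self.restraint_springs))
        for attr in ("flexion_axis_point", "flexion_axis_direction",
                     "acl_footprint_femur", "acl_footprint_tibia"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if np.linalg.norm(self.flexion_axis_direction) == 0:
            raise ValidationError("flexion axis direction must be non-zero")

    def acl_bundles(self):
        return [b for b in self.bundles if b.name.startswith(ACL_PREFIX)]

    def bundle(self, name: str) -> LigamentBundle:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    def validate_intact(self):
        """Check the intact bundle set names all four principal ligaments."""
        names = {b.name.split("_")[0] for b in self.bundles}
        missing = {"ACL", "PCL", "MCL", "LCL"} - names
        if missing:
            raise ValidationError(f"intact geometry is missing ligaments: {sorted(missing)}")
        if len(self.acl_bundles()) < 2:
            raise ValidationError("intact geometry needs >= 2 ACL functional sub-bundles")


@dataclass(frozen=True)
class KneePose:
    """Prescribed flexion plus the two free DOFs."""

    flexion_deg: float
    anterior_translation_mm: float = 0.0
    internal_rotation_deg: float = 0.0


@dataclass(frozen=True)
class LoadCase:
    """One load point of a protocol plus the schedule it belongs to."""

    anterior_force_N: float = 0.0
    torque_Nm: float = 0.0
    force_increment_N: float = 26.8
    torque_increment_Nm: float = 2.0
    force_max_N: float = 134.0
    torque_max_Nm: float = 10.0

    def __post_init__(self):
        if self.anterior_force_N < 0:
            raise ValidationError("anterior force must be >= 0 (posterior loads unsupported)")
        for maximum, increment, what in (
            (self.force_max_N, self.force_increment_N, "force"),
            (self.torque_max_Nm, self.torque_increment_Nm, "torque"),
        ):
            n = maximum / increment
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(f"{what} maximum must be an integer multiple of its increment")


@dataclass(frozen=True)
class Scenario:
    """A simulation arm: intact, ACL-deficient, or anatomic reconstruction."""

    kind: str
    geometry: KneeGeometry
    fixation_flexion_deg: float = 0.0
    graft_pretension_N: float = 0.0

    def tension_bundles(self):
        """Bundles whose summed tension is the reported ACL/graft tension."""
        if self.kind == "intact":
            return self.geometry.acl_bundles()
        if self.kind == "anatomic":
            return [b for b in self.geometry.bundles if b.name == GRAFT_NAME]
        return []


@dataclass(frozen=True)
class SolverConfig:
    tol_force_N: float = 1e-6
    tol_torque_Nmm: float = 1e-6
    max_iterations: int = 200
    fd_step: float = 1e-6
    lock_rotation: bool = False
    lock_translation: bool = False


@dataclass(frozen=True)
class KinematicsResult:
    """Laxity at one (scenario, flexion, load) point.

    ``anterior_translation_mm`` / ``internal_rotation_deg`` are load-induced
    displacements relative to the unloaded equilibrium; the absolute DOF
    values are kept alongside.
    """

    scenario_kind: str
    flexion_deg: float
    load: LoadCase
    anterior_translation_mm: float
    internal_rotation_deg: float
    acl_or_graft_tension_N: float
    residual_norm: float
    dof_translation_mm: float = 0.0
    dof_rotation_deg: float = 0.0
    iterations: int = 0


def pose_at_flexion(geometry: KneeGeometry, flexion_deg: float,
                    anterior_translation_mm: float = 0.0,
                    internal_rotation_deg: float = 0.0):
    """World placements (femur_pose, tibia_pose) at a prescribed flexion.

    The femur rotates about the geometry's flexion axis; the tibia carries
    the free DOFs: rotation about its long axis (+Y through the tibial
    origin) followed by anterior translation.
    """
    if not (0.0 <= flexion_deg <= 120.0):
        raise ValidationError("flexion must lie in [0, 120] degrees")
    femur_pose = RigidTransform.about_axis(
        geometry.flexion_axis_point, geometry.flexion_axis_direction, flexion_deg
    )
    tibia_pose = RigidTransform.translation_of([anterior_translation_mm, 0.0, 0.0]).compose(
        RigidTransform.about_axis(np.zeros(3), np.array([0.0, 1.0, 0.0]), internal_rotation_deg)
    )
    return femur_pose, tibia_pose


def footprint_distance(geometry: KneeGeometry, flexion_deg: float,
                       anterior_translation_mm: float = 0.0,
                       internal_rotation_deg: float = 0.0) -> float:
    """Distance (mm) between the ACL footprint centers at the given pose."""
    femur_pose, tibia_pose = pose_at_flexion(
        geometry, flexion_deg, anterior_translation_mm, internal_rotation_deg
    )
    pf = femur_pose.apply(geometry.acl_footprint_femur)
    pt = tibia_pose.apply(geometry.acl_footprint_tibia)
    return float(np.linalg.norm(pf - pt))


def make_scenario(geometry: KneeGeometry, kind: str, fixation_flexion_deg: float = 0.0,
                  graft_pretension_N: float = 0.0, graft_stiffness_N: float = 10000.0,
                  graft_transition_strain: float = 0.03) -> Scenario:
    """Build a simulation arm from the intact geometry.

    * ``intact``   -- geometry unchanged.
    * ``deficient`` -- all ACL functional sub-bundles removed.
    * ``anatomic`` -- ACL sub-bundles replaced by a single graft bundle
      spanning the native footprint centers.  The graft reference length is
      set so that at the fixation flexion angle, with the free DOFs at
      zero, the graft carries exactly ``graft_pretension_N``.
    """
    if kind == "intact":
        return Scenario(kind="intact", geometry=geometry)

    non_acl = [b for b in geometry.bundles if not b.name.startswith(ACL_PREFIX)]
    if kind == "deficient":
        return Scenario(kind="deficient", geometry=replace(geometry, bundles=tuple(non_acl)))

    if kind != "anatomic":
        raise ValidationError(f"unknown scenario kind {kind!r}")
    if fixation_flexion_deg not in (0.0, 30.0, 0, 30):
        raise ValidationError("graft fixation flexion must be 0 or 30 degrees")
    if graft_pretension_N < 0:
        raise ValidationError("graft pretension must be >= 0")

    length_at_fixation = footprint_distance(geometry, fixation_flexion_deg)
    strain_at_fixation = bundle_force_inverse(
        graft_pretension_N, graft_stiffness_N, graft_transition_strain
    )
    L0 = length_at_fixation / (1.0 + strain_at_fixation)
    graft = LigamentBundle(
        name=GRAFT_NAME,
        femur_insertion=geometry.acl_footprint_femur,
        tibia_insertion=geometry.acl_footprint_tibia,
        stiffness_k=graft_stiffness_N,
        reference_length_L0=L0,
        transition_strain_DL=graft_transition_strain,
    )
    return Scenario(
        kind="anatomic",
        geometry=replace(geometry, bundles=tuple(non_acl) + (graft,)),
        fixation_flexion_deg=float(fixation_flexion_deg),
        graft_pretension_N=float(graft_pretension_N),
    )


def _spring_rest_lengths(geometry: KneeGeometry, flexion_deg: float):
    femur_pose, tibia_pose = pose_at_flexion(geometry, flexion_deg)
    rests = []
    for s in geometry.restraint_springs:
        pf = femur_pose.apply(s.femur_point)
        pt = tibia_pose.apply(s.tibia_point)
        rests.append(float(np.linalg.norm(pf - pt)))
    return np.array(rests)


def _residual(geometry: KneeGeometry, flexion_deg: float, q, load_force_N: float,
              load_torque_Nmm: float, spring_rest: np.ndarray):
    """Net (anterior force N, axial moment N*mm) on the tibia at DOFs q."""
    x, theta = q
    femur_pose, tibia_pose = pose_at_flexion(geometry, flexion_deg, x, theta)
    axis_point = np.array([x, 0.0, 0.0])  # tibial long axis passes through the translated origin
    fx = load_force_N
    my = load_torque_Nmm
    for b in geometry.bundles:
        force, tension = bundle_force_vector(b, femur_pose, tibia_pose)
        if tension == 0.0:
            continue
        p = tibia_pose.apply(b.tibia_insertion)
        fx += force[0]
        r = p - axis_point
        my += r[2] * force[0] - r[0] * force[2]
    for s, rest in zip(geometry.restraint_springs, spring_rest):
        pf = femur_pose.apply(s.femur_point)
        pt = tibia_pose.apply(s.tibia_point)
        d = pf - pt
        length = float(np.linalg.norm(d))
        if length == 0.0:
            continue
        force = s.stiffness * (length - rest) / length * d
        fx += force[0]
        r = pt - axis_point
        my += r[2] * force[0] - r[0] * force[2]
    if geometry.torsional_restraint is not None:
        my -= geometry.torsional_restraint.stiffness_at(flexion_deg) * theta
    return np.array([fx, my])


def _solve_newton(geometry, flexion_deg, load_force_N, load_torque_Nmm, spring_rest,
                  q0, cfg: SolverConfig):
    """Damped Newton on the 2-D residual with a numerical Jacobian."""
    free = [i for i, locked in enumerate((cfg.lock_translation, cfg.lock_rotation)) if not locked]
    if not free:
        raise ModelConfigurationError("both DOFs are locked; nothing to solve")
    scale = np.array([cfg.tol_force_N, cfg.tol_torque_Nmm])
    q = np.asarray(q0, dtype=float).copy()

    def res(qv):
        return _residual(geometry, flexion_deg, qv, load_force_N, load_torque_Nmm, spring_rest)

    r = res(q)[free]
    for iteration in range(cfg.max_iterations):
        if np.all(np.abs(r) <= scale[free]):
            return q, float(np.linalg.norm(r)), iteration
        J = np.zeros((len(free), len(free)))
        h = cfg.fd_step
        for col, j in enumerate(free):
            qp = q.copy()
            qp[j] += h
            qm = q.copy()
            qm[j] -= h
            J[:, col] = (res(qp)[free] - res(qm)[free]) / (2.0 * h)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise ModelConfigurationError(
                "singular Jacobian: a free DOF has no restraining elements"
            ) from exc
        if np.max(np.abs(J)) == 0.0:
            raise ModelConfigurationError("free DOF has no restraining elements")
        # Backtracking on the scaled residual norm.
        norm0 = np.linalg.norm(r / scale[free])
        lam = 1.0
        for _ in range(30):
            q_try = q.copy()
            for col, j in enumerate(free):
                q_try[j] += lam * step[col]
            r_try = res(q_try)[free]
            if np.linalg.norm(r_try / scale[free]) < norm0 or lam < 1e-6:
                break
            lam *= 0.5
        q, r = q_try, r_try
    if np.all(np.abs(r) <= scale[free]):
        return q, float(np.linalg.norm(r)), cfg.max_iterations
    raise SolverError(
        f"equilibrium not converged after {cfg.max_iterations} iterations",
        residual=float(np.linalg.norm(r)),
        context={"flexion_deg": flexion_deg, "force_N": load_force_N,
                 "torque_Nmm": load_torque_Nmm},
    )


def _tension_sum(scenario: Scenario, flexion_deg: float, q) -> float:
    femur_pose, tibia_pose = pose_at_flexion(scenario.geometry, flexion_deg, q[0], q[1])
    total = 0.0
    for b in scenario.tension_bundles():
        _, tension = bundle_force_vector(b, femur_pose, tibia_pose)
        total += tension
    return total


def unloaded_equilibrium(scenario: Scenario, flexion_deg: float,
                         cfg: Optional[SolverConfig] = None):
    """Free-DOF pose with no applied load (the laxity reference).

    If the rest pose (0, 0) already satisfies the residual tolerance it is
    accepted directly; this covers minimal models in which an unloaded
    solve would be singular because every element is slack.
    """
    cfg = cfg or SolverConfig()
    spring_rest = _spring_rest_lengths(scenario.geometry, flexion_deg)
    r0 = _residual(scenario.geometry, flexion_deg, (0.0, 0.0), 0.0, 0.0, spring_rest)
    if abs(r0[0]) <= cfg.tol_force_N and abs(r0[1]) <= cfg.tol_torque_Nmm:
        return np.zeros(2)
    q, _, _ = _solve_newton(scenario.geometry, flexion_deg, 0.0, 0.0, spring_rest,
                            np.zeros(2), cfg)
    return q


def solve_equilibrium(scenario: Scenario, flexion_deg: float, load: LoadCase,
                      solver_cfg: Optional[SolverConfig] = None,
                      initial_guess=None, baseline=None) -> KinematicsResult:
    """Quasi-static equilibrium under one load point.

    ``baseline`` (the unloaded equilibrium DOFs) may be passed in by a
    protocol runner to avoid recomputing it at every increment.
    """
    cfg = solver_cfg or SolverConfig()
    if load.anterior_force_N > load.force_max_N + 1e-9:
        raise ValidationError("anterior force exceeds the protocol maximum")
    if abs(load.torque_Nm) > load.torque_max_Nm + 1e-9:
        raise ValidationError("torque exceeds the protocol maximum")
    spring_rest = _spring_rest_lengths(scenario.geometry, flexion_deg)
    if baseline is None:
        baseline = unloaded_equilibrium(scenario, flexion_deg, cfg)
    q0 = np.asarray(baseline if initial_guess is None else initial_guess, dtype=float)
    q, residual, iterations = _solve_newton(
        scenario.geometry, flexion_deg, load.anterior_force_N,
        load.torque_Nm * 1000.0, spring_rest, q0, cfg,
    )
    return KinematicsResult(
        scenario_kind=scenario.kind,
        flexion_deg=float(flexion_deg),
        load=load,
        anterior_translation_mm=float(q[0] - baseline[0]),
        internal_rotation_deg=float(q[1] - baseline[1]),
        acl_or_graft_tension_N=_tension_sum(scenario, flexion_deg, q),
        residual_norm=residual,
        dof_translation_mm=float(q[0]),
        dof_rotation_deg=float(q[1]),
        iterations=iterations,
    )


def anterior_protocol(force_max_N: float = 134.0, force_increment_N: float = 26.8) -> list:
    """Anterior-drawer schedule: force steps up to the maximum, no torque."""
    n = round(force_max_N / force_increment_N)
    return [LoadCase(anterior_force_N=force_increment_N * i, torque_Nm=0.0,
                     force_max_N=force_max_N, force_increment_N=force_increment_N)
            for i in range(1, n + 1)]


def rotation_protocol(torque_max_Nm: float = 10.0, torque_increment_Nm: float = 2.0) -> list:
    """Internal-rotation schedule: torque steps up to the maximum, no force."""
    n = round(torque_max_Nm / torque_increment_Nm)
    return [LoadCase(anterior_force_N=0.0, torque_Nm=torque_increment_Nm * i,
                     torque_max_Nm=torque_max_Nm, torque_increment_Nm=torque_increment_Nm)
            for i in range(1, n + 1)]


def run_protocol(scenario: Scenario, flexion_list: Sequence[float], load_schedule: Sequence[LoadCase],
                 solver_cfg: Optional[SolverConfig] = None) -> list:
    """One result per (flexion, load increment), warm-started across increments."""
    cfg = solver_cfg or SolverConfig()
    results = []
    for flexion in flexion_list:
        try:
            baseline = unloaded_equilibrium(scenario, flexion, cfg)
        except SolverError as exc:
            raise SolverError(
                f"unloaded solve failed at flexion {flexion}", residual=exc.residual,
                context={"flexion_deg": flexion, "load": "unloaded"},
            ) from exc
        guess = baseline
        for load in load_schedule:
            try:
                result = solve_equilibrium(scenario, flexion, load, cfg,
                                           initial_guess=guess, baseline=baseline)
            except SolverError as exc:
                raise SolverError(
                    f"solve failed at flexion {flexion}, load {load.anterior_force_N} N / "
                    f"{load.torque_Nm} N*m",
                    residual=exc.residual,
                    context={"flexion_deg": flexion, "load": load},
                ) from exc
            results.append(result)
            guess = np.array([result.dof_translation_mm, result.dof_rotation_deg])
    return results


def percent_difference(value: float, reference: float) -> float:
    """Signed percent difference of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValidationError("percent difference is undefined for a zero reference")
    return 100.0 * (value - reference) / reference


def results_to_records(results) -> list:
    """Tidy rows (dicts) for CSV/DataFrame export."""
    rows = []
    for r in results:
        rows.append({
            "scenario": r.scenario_kind,
            "flexion_deg": r.flexion_deg,
            "force_N": r.load.anterior_force_N,
            "torque_Nm": r.load.torque_Nm,
            "att_mm": r.anterior_translation_mm,
            "ir_deg": r.internal_rotation_deg,
            "tension_N": r.acl_or_graft_tension_N,
            "residual": r.residual_norm,
        })
    return rows
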