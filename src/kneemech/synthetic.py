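"""Synthetic inputs: template knee geometry, patient cohorts, tunnel phantoms.

Everything the pipeline consumes can be generated here, deterministically
per seed.  The template knee is an idealized *synthetic* geometry (no
cadaver coordinates are published for the system this package models): a
right tibia-fixed frame with +X anterior, +Y superior, +Z lateral, units
mm.  Insertion-site generation emulates surface digitization with an
isotropic placement error of 0.2 mm SD; cohort generation draws tunnel
angles as independent per-group normals with the published group means,
SDs and sizes (54 stable / 36 unstable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from kneemech.errors import ValidationError
from kneemech.knee import KneeGeometry, RestraintSpring, TorsionalRestraint
from kneemech.ligaments import LigamentBundle
from kneemech.tunnels import ImagingSpec, TunnelPhantom

# --------------------------------------------------------------------------
# Template knee geometry (synthetic, idealized; mm)
# --------------------------------------------------------------------------
# The ACL femoral footprint sits close to the flexion axis (the near-isometry
# of the native ligament), slightly posterior-proximal so the inter-footprint
# distance shortens with flexion: a graft fixed in extension slackens as the
# knee flexes, and one fixed at 30 deg tightens toward extension.
CANONICAL_TEMPLATE = {
    "flexion_axis_point": [-2.0, 26.0, 0.0],
    "flexion_axis_direction": [0.0, 0.0, 1.0],
    "bundles": {
        # name: (femur_insertion, tibia_insertion)
        # reciprocal mediolateral obliquity of the two functional bundles:
        # the native ligament restrains axial rotation far better than the
        # single central graft strand that replaces it
        "ACL_am": ([-3.5, 26.5, 8.0], [3.0, 0.0, -6.0]),
        "ACL_pl": ([-5.5, 24.5, 0.0], [9.0, 0.0, 6.0]),
        "PCL": ([-4.0, 24.0, -4.0], [-28.0, -6.0, -2.0]),
        # collateral femoral insertions sit posterior-proximal to the
        # flexion axis so both ligaments are taut in extension and slacken
        # with flexion; their tibial insertions are offset posteriorly so
        # the oblique fibers also restrain anterior drawer while taut
        "MCL": ([-7.0, 29.0, -42.0], [-16.0, -70.0, -38.0]),
        "LCL": ([-9.0, 29.0, 44.0], [-18.0, -55.0, 46.0]),
    },
    "springs": {
        # name: (femur_point, tibia_point); femoral points sit near the
        # flexion axis so the spring obliquity stays stable across flexion
        "ap_medial": ([0.0, 18.0, -15.0], [-25.0, -5.0, -15.0]),
        "ap_lateral": ([0.0, 18.0, 15.0], [-25.0, -5.0, 15.0]),
        "post_medial": ([-6.0, 30.0, -20.0], [-30.0, -8.0, -20.0]),
        "post_lateral": ([-6.0, 30.0, 20.0], [-30.0, -8.0, 20.0]),
    },
}

DIGITIZATION_SD_MM = 0.2


@dataclass(frozen=True)
class GeometryTemplate:
    """Canonical insertion coordinates plus digitization-noise settings."""

    coordinates: dict = field(default_factory=lambda: CANONICAL_TEMPLATE)
    placement_noise_sd_mm: float = DIGITIZATION_SD_MM
    seed: int = 0

    def __post_init__(self):
        if self.placement_noise_sd_mm < 0:
            raise ValidationError("placement noise SD must be >= 0")


def build_geometry(coordinates: Optional[dict] = None, bundle_parameters: Optional[dict] = None,
                   spring_stiffness: Optional[dict] = None,
                   torsional_stiffness: Optional[tuple] = None) -> KneeGeometry:
    """Assemble a :class:`KneeGeometry` from template coordinates.

    ``bundle_parameters`` maps bundle name -> (stiffness_k, L0_scale), where
    the reference length is ``L0_scale`` times the inter-insertion distance
    at full extension with the free DOFs at zero (scale < 1: taut in
    extension).  Missing entries default to (1000 N, 1.0).
    """
    coords = coordinates or CANONICAL_TEMPLATE
    bundle_parameters = bundle_parameters or {}
    spring_stiffness = spring_stiffness or {}
    bundles = []
    for name, (fem, tib) in coords["bundles"].items():
        fem = np.asarray(fem, dtype=float)
        tib = np.asarray(tib, dtype=float)
        k, scale = bundle_parameters.get(name, (1000.0, 1.0))
        natural = float(np.linalg.norm(fem - tib))
        bundles.append(LigamentBundle(
            name=name, femur_insertion=fem, tibia_insertion=tib,
            stiffness_k=float(k), reference_length_L0=natural * float(scale),
        ))
    springs = [
        RestraintSpring(name=name, femur_point=np.asarray(fem, dtype=float),
                        tibia_point=np.asarray(tib, dtype=float),
                        stiffness=float(spring_stiffness.get(name, 10.0)))
        for name, (fem, tib) in coords["springs"].items()
    ]
    acl_fem = [b.femur_insertion for b in bundles if b.name.startswith("ACL")]
    acl_tib = [b.tibia_insertion for b in bundles if b.name.startswith("ACL")]
    return KneeGeometry(
        bundles=tuple(bundles),
        restraint_springs=tuple(springs),
        flexion_axis_point=np.asarray(coords["flexion_axis_point"], dtype=float),
        flexion_axis_direction=np.asarray(coords["flexion_axis_direction"], dtype=float),
        acl_footprint_femur=np.mean(acl_fem, axis=0),
        acl_footprint_tibia=np.mean(acl_tib, axis=0),
        torsional_restraint=(None if torsional_stiffness is None
                             else TorsionalRestraint(*torsional_stiffness)),
    )


def generate_geometry(template: GeometryTemplate, bundle_parameters: Optional[dict] = None,
                      spring_stiffness: Optional[dict] = None,
                      torsional_stiffness: Optional[tuple] = None) -> KneeGeometry:
    """Emulate insertion-site digitization of the template knee.

    Every insertion coordinate is perturbed by isotropic Gaussian noise with
    the template's placement SD (0.2 mm by default, the stated accuracy of
    the digitizing arm); footprint centers are recomputed from the perturbed
    ACL sub-bundle insertions.  Deterministic per template seed.
    """
    rng = np.random.default_rng(template.seed)
    coords = {
        "flexion_axis_point": list(template.coordinates["flexion_axis_point"]),
        "flexion_axis_direction": list(template.coordinates["flexion_axis_direction"]),
        "bundles": {},
        "springs": {name: (list(f), list(t))
                    for name, (f, t) in template.coordinates["springs"].items()},
    }
    sd = template.placement_noise_sd_mm
    for name, (fem, tib) in template.coordinates["bundles"].items():
        fem = np.asarray(fem, dtype=float) + rng.normal(0.0, sd, size=3)
        tib = np.asarray(tib, dtype=float) + rng.normal(0.0, sd, size=3)
        coords["bundles"][name] = (fem.tolist(), tib.tolist())
    return build_geometry(coords, bundle_parameters, spring_stiffness, torsional_stiffness)


# --------------------------------------------------------------------------
# Patient cohorts
# --------------------------------------------------------------------------

ANGLE_VARIABLES = ("tibia_coronal_deg", "tibia_sagittal_deg",
                   "femur_coronal_deg", "femur_sagittal_deg")

#: Published group parameters: per-variable (mean, SD) and group sizes.
DEFAULT_COHORT_PARAMETERS = {
    "stable": {
        "n": 54,
        "tibia_coronal_deg": (28.43, 6.35),
        "tibia_sagittal_deg": (63.37, 6.25),
        "femur_coronal_deg": (33.73, 7.39),
        "femur_sagittal_deg": (27.46, 5.59),
        "age_years": (43.2, 10.5),
        "male_fraction": 31 / 54,
    },
    "unstable": {
        "n": 36,
        "tibia_coronal_deg": (22.45, 6.32),
        "tibia_sagittal_deg": (58.34, 7.47),
        "femur_coronal_deg": (40.43, 13.38),
        "femur_sagittal_deg": (33.46, 9.49),
        "age_years": (44.5, 9.8),
        "male_fraction": 21 / 36,
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Per-group sample sizes and normal parameters for cohort generation."""

    parameters: dict = field(default_factory=lambda: DEFAULT_COHORT_PARAMETERS)
    seed: int = 0

    def __post_init__(self):
        for group, p in self.parameters.items():
            if p["n"] <= 0:
                raise ValidationError(f"group {group!r}: n must be > 0")
            for var in ANGLE_VARIABLES + ("age_years",):
                if p[var][1] < 0:
                    raise ValidationError(f"group {group!r}, {var}: SD must be >= 0")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic patient cohort as a tidy DataFrame.

    Angle variables are independent normals per group (no covariance
    structure is assumed); ages are normal, sexes Bernoulli.  One row per
    patient with columns patient_id, group, age_years, sex and the four
    tunnel-angle variables.  Deterministic per spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pid = 0
    for group in sorted(spec.parameters):
        p = spec.parameters[group]
        n = int(p["n"])
        draws = {var: rng.normal(p[var][0], p[var][1], size=n) for var in ANGLE_VARIABLES}
        ages = rng.normal(p["age_years"][0], p["age_years"][1], size=n)
        male = rng.random(n) < p["male_fraction"]
        for i in range(n):
            pid += 1
            rows.append({
                "patient_id": f"P{pid:03d}",
                "group": group,
                "age_years": float(ages[i]),
                "sex": "male" if male[i] else "female",
                **{var: float(draws[var][i]) for var in ANGLE_VARIABLES},
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Tunnel phantoms and follow-up diameter reads
# --------------------------------------------------------------------------

def _axis_from_plane_angles(coronal_deg: float, sagittal_deg: float) -> np.ndarray:
    """Unit axis whose coronal/sagittal plane angles match the request.

    The coronal angle is measured between the (superior, lateral) projection
    and the superior axis; the sagittal angle between the (anterior,
    superior) projection and the superior axis.
    """
    if not (0.0 <= coronal_deg < 90.0 and 0.0 <= sagittal_deg < 90.0):
        raise ValidationError("plane angles must lie in [0, 90) degrees")
    v = np.array([
        math.tan(math.radians(sagittal_deg)),  # anterior
        1.0,                                   # superior
        math.tan(math.radians(coronal_deg)),   # lateral
    ])
    return v / np.linalg.norm(v)


def generate_tunnel_phantom(coronal_deg: float, sagittal_deg: float,
                            diameter_mm: float = 7.0, length_mm: float = 40.0,
                            spec: Optional[ImagingSpec] = None,
                            mode: str = "landmark") -> TunnelPhantom:
    """Construct a tunnel phantom with prescribed plane angles.

    ``landmark`` mode emits exact entry/exit points realizing the angles;
    ``voxel`` mode additionally rasterizes the cylinder into a volume on
    the imaging grid (in-plane pixels FOV/matrix, slice spacing thickness +
    gap), which is what measurement-quantization tests exercise.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValidationError("diameter and length must be > 0")
    spec = spec or ImagingSpec()
    axis = _axis_from_plane_angles(coronal_deg, sagittal_deg)
    margin = diameter_mm + 4.0
    entry = np.array([margin, spec.slice_spacing_mm, margin])
    exit_ = entry + length_mm * axis
    phantom = TunnelPhantom(mode=mode, entry_point=entry, exit_point=exit_,
                            diameter_mm=float(diameter_mm), length_mm=float(length_mm),
                            spec=spec)
    if mode == "landmark":
        return phantom
    if mode != "voxel":
        raise ValidationError(f"unknown phantom mode {mode!r}")

    spacing = np.array(spec.voxel_spacing_mm)
    extent = np.abs(exit_ - entry) + 2 * margin
    shape = np.maximum(np.ceil(extent / spacing).astype(int) + 1, 4)
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * spacing  # voxel centers in mm, axis order (ant, sup, lat)
    rel = centers - entry
    t = rel @ axis
    radial = rel - np.outer(t, axis)
    inside = (t >= 0.0) & (t <= length_mm) & (np.linalg.norm(radial, axis=1) <= diameter_mm / 2.0)
    volume = np.zeros(shape, dtype=np.uint8)
    volume.reshape(-1)[inside] = 1
    if not volume.any():
        raise ValidationError("rasterized phantom contains no voxels; enlarge the volume")
    return TunnelPhantom(mode="voxel", entry_point=entry, exit_point=exit_,
                         diameter_mm=float(diameter_mm), length_mm=float(length_mm),
                         spec=spec, volume=volume)


def generate_follow_up_diameters(intraop_mm: float, true_change_percent: float,
                                 read_noise_sd_mm: float = 0.1, seed: int = 0) -> np.ndarray:
    """Triplicate follow-up diameter reads at the three tunnel stations.

    Returns a 3x3 array (station x repeat): the true follow-up diameter
    ``intraop * (1 + change/100)`` plus zero-mean per-read noise, emulating
    the repeated caliper reads that are averaged per station.
    """
    if intraop_mm <= 0:
        raise ValidationError("intraoperative diameter must be > 0")
    if read_noise_sd_mm < 0:
        raise ValidationError("read noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    true = intraop_mm * (1.0 + true_change_percent / 100.0)
    return true + rng.normal(0.0, read_noise_sd_mm, size=(3, 3))
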