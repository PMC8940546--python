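"""Bone-tunnel morphometry: axis angles, thirds-based diameters, enlargement.

Image coordinates are mm with the origin at the volume corner and axis
order (anterior, superior, lateral); voxel indices are 0-based.  The
imaging geometry is a knee MRI protocol: 180 x 180 mm field of view on a
320 x 256 in-plane matrix (axial slices spanning anterior x lateral),
4 mm slices with a 0.5--1 mm gap, so the slice axis is the superior one.

Tunnel angles are measured between the tunnel-axis projection onto the
coronal (superior-lateral) or sagittal (anterior-superior) plane and the
bone's long (superior) axis, reported in [0, 90] degrees.  Diameters are
measured at the centers of the three equal thirds of the tunnel (distal,
mid, proximal), each as the average of three repeated reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import nibabel as nib

from kneemech.errors import DegenerateElementError, ValidationError

_AXIS_NAMES = ("anterior", "superior", "lateral")
_SUPERIOR = 1  # index of the long-bone axis in image coordinates


@dataclass(frozen=True)
class ImagingSpec:
    """Acquisition geometry: FOV/matrix in-plane, slice thickness + gap."""

    fov_mm: tuple = (180.0, 180.0)
    matrix: tuple = (320, 256)
    slice_thickness_mm: float = 4.0
    slice_gap_mm: float = 0.5

    def __post_init__(self):
        if any(f <= 0 for f in self.fov_mm) or any(m <= 0 for m in self.matrix):
            raise ValidationError("FOV and matrix entries must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ValidationError("slice thickness must be > 0")
        if not (0.0 <= self.slice_gap_mm):
            raise ValidationError("slice gap must be >= 0")

    @property
    def pixel_spacing_mm(self) -> tuple:
        """In-plane spacing (anterior, lateral) = FOV / matrix per axis."""
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def voxel_spacing_mm(self) -> tuple:
        """Spacing in image axis order (anterior, superior, lateral)."""
        px = self.pixel_spacing_mm
        return (px[0], self.slice_spacing_mm, px[1])

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_spacing_mm
        return aff


@dataclass(frozen=True)
class TunnelPhantom:
    """A synthetic single-tunnel object, in landmark or voxel form."""

    mode: str
    entry_point: np.ndarray
    exit_point: np.ndarray
    diameter_mm: float
    length_mm: float
    spec: ImagingSpec
    volume: Optional[np.ndarray] = None

    def to_nifti(self) -> "nib.Nifti1Image":
        if self.volume is None:
            raise ValidationError("only voxel-mode phantoms can be written as NIfTI")
        return nib.Nifti1Image(self.volume.astype(np.uint8), self.spec.affine())

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass(frozen=True)
class TunnelMeasurement:
    """Morphometry of one tunnel: axis angles and station diameters."""

    bone: str
    entry_point: np.ndarray
    exit_point: np.ndarray
    station_diameters_mm: tuple     # (distal, mid, proximal), triplicate means
    coronal_angle_deg: float
    sagittal_angle_deg: float
    intraop_diameter_mm: float = 7.0
    raw_triplicates: Optional[np.ndarray] = None  # 3x3 (station x repeat)

    def __post_init__(self):
        if any(d <= 0 for d in self.station_diameters_mm):
            raise ValidationError("station diameters must be > 0")
        for angle in (self.coronal_angle_deg, self.sagittal_angle_deg):
            if not (0.0 <= angle <= 90.0):
                raise ValidationError("plane angles must lie in [0, 90] degrees")

    @property
    def mean_diameter_mm(self) -> float:
        return float(np.mean(self.station_diameters_mm))

    def enlargement_rate_percent(self) -> float:
        return enlargement_rate(self.mean_diameter_mm, self.intraop_diameter_mm)


def tunnel_axis(entry_point, exit_point) -> np.ndarray:
    """Unit tunnel direction, oriented distal-to-proximal (superior > 0)."""
    entry_point = np.asarray(entry_point, dtype=float)
    exit_point = np.asarray(exit_point, dtype=float)
    d = exit_point - entry_point
    n = np.linalg.norm(d)
    if n == 0.0:
        raise DegenerateElementError("tunnel entry and exit points coincide")
    d = d / n
    if d[_SUPERIOR] < 0:
        d = -d
    return d


def plane_angle(axis, plane: str) -> float:
    """Angle (deg) between the axis projection onto a plane and the long axis.

    ``coronal`` drops the anterior component (projection onto the
    superior-lateral plane); ``sagittal`` drops the lateral component.
    Invariant to the sign and scale of ``axis``.
    """
    axis = np.asarray(axis, dtype=float)
    if plane == "coronal":
        transverse = axis[2]
    elif plane == "sagittal":
        transverse = axis[0]
    else:
        raise ValidationError(f"unknown plane {plane!r} (expected coronal or sagittal)")
    longitudinal = axis[_SUPERIOR]
    if transverse == 0.0 and longitudinal == 0.0:
        raise ValidationError("axis is normal to the requested plane; angle undefined")
    return float(np.degrees(np.arctan2(abs(transverse), abs(longitudinal))))


def station_positions(entry_point, exit_point) -> np.ndarray:
    """Centers of the three equal thirds of the tunnel segment.

    Fractions 1/6, 1/2, 5/6 of the way from entry to exit, i.e. the
    (distal, mid, proximal) section centers when entry is distal.
    """
    entry_point = np.asarray(entry_point, dtype=float)
    exit_point = np.asarray(exit_point, dtype=float)
    if np.array_equal(entry_point, exit_point):
        raise DegenerateElementError("tunnel entry and exit points coincide")
    fractions = np.array([1.0 / 6.0, 0.5, 5.0 / 6.0])
    return entry_point + np.outer(fractions, exit_point - entry_point)


def triplicate_mean(reads) -> float:
    """Average of exactly three positive repeated diameter reads."""
    reads = np.asarray(reads, dtype=float)
    if reads.shape != (3,):
        raise ValidationError(f"expected exactly 3 reads, got shape {reads.shape}")
    if np.any(reads <= 0):
        raise ValidationError("diameter reads must be > 0")
    return float(np.mean(reads))


def enlargement_rate(followup_mm: float, intraop_mm: float) -> float:
    """Signed percent change of the follow-up diameter versus the bore.

    Positive = enlargement, negative = narrowing.
    """
    if intraop_mm <= 0:
        raise ValidationError("intraoperative diameter must be > 0")
    return 100.0 * (followup_mm - intraop_mm) / intraop_mm


def _fit_axis_from_volume(volume: np.ndarray, spacing) -> tuple:
    """Per-slice centroid line fit; returns (entry, exit) points in mm."""
    spacing = np.asarray(spacing, dtype=float)
    slices = [j for j in range(volume.shape[_SUPERIOR]) if volume[:, j, :].any()]
    if not slices:
        raise ValidationError("phantom volume contains no tunnel voxels")
    if len(slices) < 2:
        raise ValidationError("tunnel spans fewer than two slices; axis undetermined")
    if len(slices) >= 4:
        # End slices cut the cylinder obliquely (partial disks) and bias the
        # per-slice centroid; drop them from the line fit.
        slices = slices[1:-1]
    centroids = []
    for j in slices:
        ii, kk = np.nonzero(volume[:, j, :])
        centroids.append([ii.mean() * spacing[0], j * spacing[1], kk.mean() * spacing[2]])
    centroids = np.asarray(centroids)
    y = centroids[:, 1]
    # Anterior and lateral centroid coordinates are linear in the slice
    # position; two independent 1-D least-squares fits give the axis.
    coef_a = np.polyfit(y, centroids[:, 0], 1)
    coef_l = np.polyfit(y, centroids[:, 2], 1)
    y0, y1 = y.min(), y.max()
    entry = np.array([np.polyval(coef_a, y0), y0, np.polyval(coef_l, y0)])
    exit_ = np.array([np.polyval(coef_a, y1), y1, np.polyval(coef_l, y1)])
    return entry, exit_


def _slice_width(volume: np.ndarray, slice_index: int, direction_inplane, spacing) -> float:
    """Full width of the tunnel mask in one slice along an in-plane direction."""
    ii, kk = np.nonzero(volume[:, slice_index, :])
    if ii.size == 0:
        raise ValidationError(f"no tunnel voxels in slice {slice_index}")
    u = np.asarray(direction_inplane, dtype=float)
    u = u / np.linalg.norm(u)
    proj = ii * spacing[0] * u[0] + kk * spacing[2] * u[1]
    # Voxel centers under-measure the mask by one voxel footprint.
    voxel_width = abs(u[0]) * spacing[0] + abs(u[1]) * spacing[2]
    return float(proj.max() - proj.min() + voxel_width)


def measure_phantom(phantom: TunnelPhantom, spec: Optional[ImagingSpec] = None,
                    bone: str = "tibia", intraop_diameter_mm: float = 7.0) -> TunnelMeasurement:
    """Recover axis, angles and station diameters from a phantom.

    Landmark phantoms are measured exactly from their endpoints; voxel
    phantoms go through a per-slice centroid line fit and in-slice width
    measurement, so recovery is only exact up to the voxel quantization of
    the imaging spec.
    """
    spec = spec or phantom.spec
    if phantom.mode == "landmark":
        entry, exit_ = phantom.entry_point, phantom.exit_point
        diameters = (phantom.diameter_mm,) * 3
        raw = np.full((3, 3), phantom.diameter_mm)
    else:
        if phantom.volume is None:
            raise ValidationError("voxel phantom has no volume")
        spacing = spec.voxel_spacing_mm
        entry, exit_ = _fit_axis_from_volume(phantom.volume, spacing)
        axis = tunnel_axis(entry, exit_)
        # Width is taken along the in-plane direction perpendicular to the
        # axis projection: the minor axis of the elliptical cross-section,
        # which equals the true tunnel diameter for a tilted cylinder.
        inplane = np.array([axis[0], axis[2]])
        if np.linalg.norm(inplane) < 1e-12:
            perp = np.array([1.0, 0.0])
        else:
            inplane = inplane / np.linalg.norm(inplane)
            perp = np.array([-inplane[1], inplane[0]])
        stations = station_positions(entry, exit_)
        reads = []
        for p in stations:
            j = int(round(p[_SUPERIOR] / spacing[_SUPERIOR]))
            j = min(max(j, 0), phantom.volume.shape[_SUPERIOR] - 1)
            width = _slice_width(phantom.volume, j, perp, spacing)
            reads.append([width] * 3)
        raw = np.asarray(reads)
        diameters = tuple(triplicate_mean(r) for r in raw)
    axis = tunnel_axis(entry, exit_)
    return TunnelMeasurement(
        bone=bone,
        entry_point=np.asarray(entry, dtype=float),
        exit_point=np.asarray(exit_, dtype=float),
        station_diameters_mm=diameters,
        coronal_angle_deg=plane_angle(axis, "coronal"),
        sagittal_angle_deg=plane_angle(axis, "sagittal"),
        intraop_diameter_mm=intraop_diameter_mm,
        raw_triplicates=raw,
    )


def load_phantom_nifti(path, spec: Optional[ImagingSpec] = None) -> TunnelPhantom:
    """Read a voxel phantom back from NIfTI (spacing taken from the affine)."""
    img = nib.load(str(path))
    volume = np.asarray(img.dataobj).astype(np.uint8)
    if spec is None:
        zooms = img.header.get_zooms()[:3]
        spec = ImagingSpec(
            fov_mm=(zooms[0] * volume.shape[0], zooms[2] * volume.shape[2]),
            matrix=(volume.shape[0], volume.shape[2]),
            slice_thickness_mm=float(zooms[1]),
            slice_gap_mm=0.0,
        )
    entry, exit_ = _fit_axis_from_volume(volume, img.header.get_zooms()[:3])
    return TunnelPhantom(mode="voxel", entry_point=entry, exit_point=exit_,
                         diameter_mm=float("nan"), length_mm=float(np.linalg.norm(exit_ - entry)),
                         spec=spec, volume=volume)
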