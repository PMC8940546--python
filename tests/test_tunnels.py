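"""Tunnel morphometry: axes, plane angles, station diameters, enlargement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneemech.errors import DegenerateElementError, ValidationError
from kneemech.synthetic import generate_tunnel_phantom
from kneemech.tunnels import (
    ImagingSpec,
    enlargement_rate,
    measure_phantom,
    plane_angle,
    station_positions,
    triplicate_mean,
    tunnel_axis,
)


class TestTunnelAxis:
    @pytest.mark.parametrize("entry, exit_, expected", [
        ((0, 0, 0), (0, 10, 0), (0, 1, 0)),
        ((0, 0, 0), (0, -10, 0), (0, 1, 0)),   # flipped to point superior
        ((0, 0, 0), (3, 4, 0), (0.6, 0.8, 0)),
    ])
    def test_unit_direction_oriented_superior(self, entry, exit_, expected):
        assert tunnel_axis(entry, exit_) == pytest.approx(expected)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateElementError):
            tunnel_axis((1, 2, 3), (1, 2, 3))


class TestPlaneAngle:
    sqrt2 = np.sqrt(2) / 2

    @pytest.mark.parametrize("axis, plane, expected", [
        ((0, 1, 0), "coronal", 0.0),
        ((0, 1, 0), "sagittal", 0.0),
        ((0, sqrt2, sqrt2), "coronal", 45.0),
        ((0.5, sqrt2, 0.5), "coronal", 35.26438968),  # atan2(0.5, 0.7071)
    ])
    def test_known_angles(self, axis, plane, expected):
        assert plane_angle(axis, plane) == pytest.approx(expected, abs=1e-6)

    def test_axis_normal_to_plane_undefined(self):
        with pytest.raises(ValidationError):
            plane_angle((1.0, 0.0, 0.0), "coronal")

    @settings(deadline=None, derandomize=True)
    @given(v=st.tuples(st.floats(-1, 1), st.floats(0.05, 1), st.floats(-1, 1)),
           scale=st.floats(0.1, 10.0), plane=st.sampled_from(["coronal", "sagittal"]))
    def test_invariant_to_sign_and_scale(self, v, scale, plane):
        v = np.asarray(v)
        base = plane_angle(v, plane)
        assert plane_angle(-v, plane) == pytest.approx(base, abs=1e-9)
        assert plane_angle(scale * v, plane) == pytest.approx(base, abs=1e-9)


class TestStationPositions:
    def test_thirds_of_a_length_six_segment(self):
        stations = station_positions((0, 0, 0), (0, 6, 0))
        assert np.allclose(stations, [[0, 1, 0], [0, 3, 0], [0, 5, 0]])

    def test_stations_equidistant(self):
        stations = station_positions((1.0, -2.0, 0.5), (4.0, 9.0, -3.0))
        d1 = np.linalg.norm(stations[1] - stations[0])
        d2 = np.linalg.norm(stations[2] - stations[1])
        assert d1 == pytest.approx(d2)

    def test_reversed_segment_gives_reversed_stations(self):
        forward = station_positions((0, 0, 0), (0, 6, 0))
        backward = station_positions((0, 6, 0), (0, 0, 0))
        assert backward == pytest.approx(forward[::-1])


class TestDiameters:
    @pytest.mark.parametrize("reads, expected", [
        ((7.0, 7.0, 7.0), 7.0),
        ((6.9, 7.0, 7.1), 7.0),
        ((6.0, 7.0, 8.0), 7.0),
    ])
    def test_triplicate_mean(self, reads, expected):
        assert triplicate_mean(reads) == pytest.approx(expected)

    def test_wrong_count_or_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            triplicate_mean((7.0, 7.0))
        with pytest.raises(ValidationError):
            triplicate_mean((7.0, -1.0, 7.0))

    @pytest.mark.parametrize("followup, intraop, expected", [
        (7.0, 7.0, 0.0),
        (7.7, 7.0, 10.0),
        (6.2125, 7.0, -11.25),
    ])
    def test_enlargement_rate(self, followup, intraop, expected):
        assert enlargement_rate(followup, intraop) == pytest.approx(expected)

    def test_enlargement_sign_convention(self):
        assert enlargement_rate(8.0, 7.0) > 0       # widening is positive
        assert enlargement_rate(6.0, 7.0) < 0
        with pytest.raises(ValidationError):
            enlargement_rate(7.0, 0.0)


class TestImagingSpec:
    def test_pixel_spacing_is_fov_over_matrix(self):
        spec = ImagingSpec()
        assert spec.pixel_spacing_mm == pytest.approx((0.5625, 0.703125))
        assert spec.slice_spacing_mm == pytest.approx(4.5)

    def test_affine_diagonal_matches_spacing(self):
        spec = ImagingSpec()
        assert np.diag(spec.affine())[:3] == pytest.approx(spec.voxel_spacing_mm)


class TestPhantomRoundTrip:
    @pytest.mark.parametrize("coronal, sagittal", [(30.0, 60.0), (0.0, 0.0), (25.0, 35.0)])
    def test_landmark_phantom_exact(self, coronal, sagittal):
        phantom = generate_tunnel_phantom(coronal, sagittal, mode="landmark")
        m = measure_phantom(phantom)
        assert m.coronal_angle_deg == pytest.approx(coronal, abs=1e-9)
        assert m.sagittal_angle_deg == pytest.approx(sagittal, abs=1e-9)
        assert m.station_diameters_mm == pytest.approx((7.0,) * 3)

    @pytest.mark.parametrize("coronal, sagittal", [(30.0, 10.0), (20.0, 25.0)])
    def test_voxel_phantom_angle_within_quantization_bound(self, coronal, sagittal):
        """Centroid line fit across 4.5 mm slices recovers the axis to < 1 deg."""
        phantom = generate_tunnel_phantom(coronal, sagittal, length_mm=60.0, mode="voxel")
        m = measure_phantom(phantom)
        assert m.coronal_angle_deg == pytest.approx(coronal, abs=1.0)
        assert m.sagittal_angle_deg == pytest.approx(sagittal, abs=1.0)

    def test_voxel_phantom_diameter_within_two_pixels(self):
        spec = ImagingSpec()
        phantom = generate_tunnel_phantom(15.0, 10.0, diameter_mm=7.0, length_mm=60.0,
                                          mode="voxel", spec=spec)
        m = measure_phantom(phantom)
        tolerance = 2.0 * max(spec.pixel_spacing_mm)
        for d in m.station_diameters_mm:
            assert d == pytest.approx(7.0, abs=tolerance)

    def test_nifti_round_trip(self, tmp_path):
        from kneemech.tunnels import load_phantom_nifti
        phantom = generate_tunnel_phantom(25.0, 15.0, length_mm=50.0, mode="voxel")
        path = tmp_path / "phantom.nii"
        phantom.save(path)
        loaded = load_phantom_nifti(path)
        m = measure_phantom(loaded, spec=phantom.spec)
        assert m.coronal_angle_deg == pytest.approx(25.0, abs=1.0)

    def test_unrealizable_angles_rejected(self):
        with pytest.raises(ValidationError):
            generate_tunnel_phantom(90.0, 90.0)
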