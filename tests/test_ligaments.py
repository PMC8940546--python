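"""Constitutive law of the tension-only ligament/graft elements."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from kneemech.errors import (
    DegenerateElementError,
    InvalidGeometryError,
    InvalidParameterError,
)
from kneemech.ligaments import (
    LigamentBundle,
    bundle_force,
    bundle_force_inverse,
    bundle_force_vector,
    strain,
)
from kneemech.rigid import RigidTransform


class TestStrain:
    @pytest.mark.parametrize("L, L0, expected", [
        (1.03, 1.0, 0.03),
        (1.0, 1.0, 0.0),
        (0.97, 1.0, -0.03),
        (31.302, 30.0, 0.0434),
    ])
    def test_engineering_strain(self, L, L0, expected):
        assert strain(L, L0) == pytest.approx(expected)

    def test_invalid_reference_length(self):
        with pytest.raises(InvalidGeometryError):
            strain(1.0, 0.0)
        with pytest.raises(InvalidGeometryError):
            strain(1.0, -2.0)


class TestBundleForce:
    @pytest.mark.parametrize("D, k, DL, expected", [
        (-0.01, 1000.0, 0.03, 0.0),          # slack branch
        (0.06, 1000.0, 0.03, 30.0),          # branch point: both branches agree
        (0.03, 1000.0, 0.03, 7.5),           # toe region, (1/4)*1000*0.0009/0.03
    ])
    def test_piecewise_values(self, D, k, DL, expected):
        assert bundle_force(D, k, DL) == pytest.approx(expected)

    def test_invalid_transition_strain(self):
        with pytest.raises(InvalidParameterError):
            bundle_force(0.01, 1000.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(k=st.floats(1.0, 5e4), DL=st.floats(1e-4, 0.2))
    def test_branches_continuous_and_smooth_at_transition(self, k, DL):
        """Value and slope of the toe and linear branches agree at D = 2*DL."""
        D = 2.0 * DL
        toe = 0.25 * k * D * D / DL
        linear = k * (D - DL)
        assert toe == pytest.approx(linear, rel=1e-12)
        h = 1e-7 * DL
        slope_below = (bundle_force(D, k, DL) - bundle_force(D - h, k, DL)) / h
        slope_above = (bundle_force(D + h, k, DL) - bundle_force(D, k, DL)) / h
        assert slope_below == pytest.approx(k, rel=1e-4)
        assert slope_above == pytest.approx(k, rel=1e-4)

    @settings(deadline=None, derandomize=True)
    @given(k=st.floats(1.0, 5e4), DL=st.floats(1e-4, 0.2),
           strains=st.lists(st.floats(-0.5, 0.5), min_size=2, max_size=10))
    def test_monotone_and_tension_only(self, k, DL, strains):
        forces = bundle_force(np.sort(strains), k, DL)
        assert np.all(np.diff(forces) >= 0)
        assert np.all(np.asarray(bundle_force(np.minimum(strains, 0.0), k, DL)) == 0.0)

    @pytest.mark.parametrize("F, k, DL", [
        (7.5, 1000.0, 0.03), (30.0, 1000.0, 0.03), (134.0, 10000.0, 0.03),
        (0.0, 5000.0, 0.03), (250.0, 3000.0, 0.05),
    ])
    def test_inverse_matches_root_finding(self, F, k, DL):
        D = bundle_force_inverse(F, k, DL)
        assert bundle_force(D, k, DL) == pytest.approx(F, abs=1e-9)
        if F > 0:
            D_brent = brentq(lambda d: bundle_force(d, k, DL) - F, 0.0, 10.0, xtol=1e-14)
            assert D == pytest.approx(D_brent, abs=1e-10)


class TestBundleForceVector:
    def make_bundle(self, length):
        return LigamentBundle(
            name="b", femur_insertion=[0.0, 0.0, 0.0],
            tibia_insertion=[length, 0.0, 0.0],
            stiffness_k=10000.0, reference_length_L0=30.0,
        )

    def test_slack_bundle_exerts_nothing(self):
        force, tension = bundle_force_vector(
            self.make_bundle(29.0), RigidTransform.identity(), RigidTransform.identity())
        assert tension == 0.0
        assert np.allclose(force, 0.0)

    def test_toe_region_tension_and_direction(self):
        # D = 1.302/30 = 0.0434 <= 2*DL: F = (1/4)*10000*D^2/0.03 = 156.963 N,
        # pulling the tibia toward the femur (-X).
        expected = 0.25 * 10000.0 * (1.302 / 30.0) ** 2 / 0.03
        force, tension = bundle_force_vector(
            self.make_bundle(31.302), RigidTransform.identity(), RigidTransform.identity())
        assert tension == pytest.approx(expected, abs=1e-9)
        assert force == pytest.approx([-expected, 0.0, 0.0], abs=1e-9)

    def test_linear_branch_tension(self):
        # D = 3/30 = 0.1 > 2*DL: F = 10000*(0.1 - 0.03) = 700 N
        _, tension = bundle_force_vector(
            self.make_bundle(33.0), RigidTransform.identity(), RigidTransform.identity())
        assert tension == pytest.approx(700.0, abs=1e-9)

    def test_swapping_bones_flips_the_force(self):
        bundle = self.make_bundle(31.302)
        swapped = LigamentBundle(
            name="b", femur_insertion=bundle.tibia_insertion,
            tibia_insertion=bundle.femur_insertion,
            stiffness_k=10000.0, reference_length_L0=30.0,
        )
        f1, _ = bundle_force_vector(bundle, RigidTransform.identity(), RigidTransform.identity())
        f2, _ = bundle_force_vector(swapped, RigidTransform.identity(), RigidTransform.identity())
        assert np.allclose(f1, -f2)

    def test_coincident_insertions_are_degenerate(self):
        bundle = self.make_bundle(30.5)
        shift = RigidTransform.translation_of([-30.5, 0.0, 0.0])
        with pytest.raises(DegenerateElementError):
            bundle_force_vector(bundle, RigidTransform.identity(), shift)


class TestBundleValidation:
    def test_nonpositive_reference_length_rejected(self):
        with pytest.raises(InvalidGeometryError):
            LigamentBundle(name="x", femur_insertion=[0, 0, 0], tibia_insertion=[1, 0, 0],
                           stiffness_k=100.0, reference_length_L0=0.0)

    def test_negative_stiffness_rejected(self):
        with pytest.raises(InvalidParameterError):
            LigamentBundle(name="x", femur_insertion=[0, 0, 0], tibia_insertion=[1, 0, 0],
                           stiffness_k=-1.0, reference_length_L0=1.0)
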