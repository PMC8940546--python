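"""Rigid-body poses, scenario construction and the equilibrium solver."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from kneemech.errors import ValidationError
from kneemech.knee import (
    LoadCase,
    Scenario,
    SolverConfig,
    anterior_protocol,
    make_scenario,
    percent_difference,
    pose_at_flexion,
    footprint_distance,
    results_to_records,
    rotation_protocol,
    run_protocol,
    solve_equilibrium,
)
from kneemech.ligaments import bundle_force, bundle_length, strain
from kneemech.calibrate import apply_parameters, initial_parameters


@pytest.fixture(scope="module")
def template_knee():
    return apply_parameters(initial_parameters())


class TestPoseAtFlexion:
    def test_zero_flexion_is_identity(self, template_knee):
        femur, tibia = pose_at_flexion(template_knee, 0.0)
        assert np.allclose(femur.rotation, np.eye(3))
        assert np.allclose(femur.translation, 0.0)
        assert np.allclose(tibia.rotation, np.eye(3))

    def test_flexion_composes_to_identity(self, template_knee):
        femur30, _ = pose_at_flexion(template_knee, 30.0)
        inverse = femur30.inverse()
        composed = inverse.compose(femur30)
        assert np.allclose(composed.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(composed.translation, 0.0, atol=1e-12)

    def test_bundle_length_matches_trigonometric_oracle(self, template_knee):
        """Brute-force rotation of the insertion about the axis."""
        bundle = template_knee.bundle("PCL")
        femur, tibia = pose_at_flexion(template_knee, 30.0)
        length = bundle_length(bundle, femur, tibia)

        p = np.asarray(bundle.femur_insertion) - template_knee.flexion_axis_point
        angle = math.radians(30.0)
        c, s = math.cos(angle), math.sin(angle)
        rotated = np.array([p[0] * c - p[1] * s, p[0] * s + p[1] * c, p[2]])
        world = rotated + template_knee.flexion_axis_point
        assert length == pytest.approx(np.linalg.norm(world - bundle.tibia_insertion), abs=1e-12)

    def test_flexion_outside_range_rejected(self, template_knee):
        with pytest.raises(ValidationError):
            pose_at_flexion(template_knee, 150.0)


class TestMakeScenario:
    def test_intact_keeps_geometry(self, template_knee):
        scenario = make_scenario(template_knee, "intact")
        assert scenario.geometry is template_knee

    def test_deficient_removes_all_acl_bundles(self, template_knee):
        scenario = make_scenario(template_knee, "deficient")
        assert not [b for b in scenario.geometry.bundles if b.name.startswith("ACL")]
        assert len(scenario.geometry.bundles) == len(template_knee.bundles) - 2

    def test_anatomic_zero_pretension_gives_zero_strain_at_fixation(self, template_knee):
        scenario = make_scenario(template_knee, "anatomic", fixation_flexion_deg=0.0,
                                 graft_pretension_N=0.0)
        graft = scenario.geometry.bundle("graft")
        femur, tibia = pose_at_flexion(scenario.geometry, 0.0)
        assert strain(bundle_length(graft, femur, tibia), graft.reference_length_L0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_pretension_reference_length_matches_root_finding(self, template_knee):
        """1-D bisection oracle for the graft L0 that yields 40 N at fixation."""
        pretension, k = 40.0, 10000.0
        scenario = make_scenario(template_knee, "anatomic", fixation_flexion_deg=0.0,
                                 graft_pretension_N=pretension, graft_stiffness_N=k)
        graft = scenario.geometry.bundle("graft")
        length = footprint_distance(template_knee, 0.0)

        def tension_given_L0(L0):
            return bundle_force(strain(length, L0), k, graft.transition_strain_DL) - pretension

        L0_oracle = brentq(tension_given_L0, length * 0.5, length, xtol=1e-12)
        assert graft.reference_length_L0 == pytest.approx(L0_oracle, abs=1e-9)

    def test_unknown_kind_and_negative_pretension_rejected(self, template_knee):
        with pytest.raises(ValidationError):
            make_scenario(template_knee, "bionic")
        with pytest.raises(ValidationError):
            make_scenario(template_knee, "anatomic", graft_pretension_N=-1.0)


class TestSolveEquilibrium:
    def test_rest_pose_is_equilibrium(self, single_bundle_knee):
        scenario = Scenario(kind="intact", geometry=single_bundle_knee)
        cfg = SolverConfig(lock_rotation=True)
        res = solve_equilibrium(scenario, 0.0, LoadCase(anterior_force_N=0.0), cfg)
        assert res.anterior_translation_mm == pytest.approx(0.0, abs=1e-9)
        assert res.residual_norm <= 1e-6

    def test_matches_closed_form_for_single_bundle(self, single_bundle_knee):
        """134 N < k*DL = 300 N lies in the toe region: F = k D^2 / (4 DL)
        inverts to D = 2 sqrt(F DL / k), i.e. 30 * 0.040100 = 1.20299 mm."""
        scenario = Scenario(kind="intact", geometry=single_bundle_knee)
        cfg = SolverConfig(lock_rotation=True)
        res = solve_equilibrium(scenario, 0.0, LoadCase(anterior_force_N=134.0), cfg)
        x_closed_form = 30.0 * 2.0 * math.sqrt(134.0 * 0.03 / 10000.0)
        assert res.anterior_translation_mm == pytest.approx(x_closed_form, abs=1e-6)
        assert res.acl_or_graft_tension_N == pytest.approx(134.0, abs=1e-5)

    def test_matches_bisection_oracle_for_single_bundle(self, single_bundle_knee):
        """Independent 1-D bisection on the anterior force balance."""
        applied = 80.4
        scenario = Scenario(kind="intact", geometry=single_bundle_knee)
        cfg = SolverConfig(lock_rotation=True)
        res = solve_equilibrium(scenario, 0.0, LoadCase(anterior_force_N=applied), cfg)

        def net_force(x):
            length = 30.0 + x
            return applied - bundle_force(strain(length, 30.0), 1e4, 0.03)

        x_oracle = brentq(net_force, 0.0, 10.0, xtol=1e-12)
        assert res.anterior_translation_mm == pytest.approx(x_oracle, abs=1e-6)

    def test_load_beyond_protocol_maximum_rejected(self, single_bundle_knee):
        scenario = Scenario(kind="intact", geometry=single_bundle_knee)
        with pytest.raises(ValidationError):
            solve_equilibrium(scenario, 0.0, LoadCase(anterior_force_N=200.0))


class TestRunProtocol:
    def test_anterior_protocol_has_five_increments(self):
        loads = anterior_protocol()
        assert len(loads) == 5
        assert loads[-1].anterior_force_N == pytest.approx(134.0)
        assert loads[0].anterior_force_N == pytest.approx(26.8)

    def test_protocol_yields_flexions_times_increments_rows(self, template_knee):
        scenario = make_scenario(template_knee, "intact")
        results = run_protocol(scenario, [0.0, 30.0, 60.0, 90.0], anterior_protocol())
        assert len(results) == 20
        assert all(r.residual_norm <= 1e-5 for r in results)

    def test_translation_monotone_in_load(self, template_knee):
        scenario = make_scenario(template_knee, "intact")
        results = run_protocol(scenario, [30.0], anterior_protocol())
        translations = [r.anterior_translation_mm for r in results]
        assert all(b >= a - 1e-9 for a, b in zip(translations, translations[1:]))

    def test_rotation_monotone_in_torque(self, template_knee):
        scenario = make_scenario(template_knee, "intact")
        results = run_protocol(scenario, [30.0], rotation_protocol())
        rotations = [r.internal_rotation_deg for r in results]
        assert all(b >= a - 1e-9 for a, b in zip(rotations, rotations[1:]))

    def test_rerun_is_bit_identical(self, template_knee):
        scenario = make_scenario(template_knee, "anatomic", 0.0, 40.0)
        first = results_to_records(run_protocol(scenario, [0.0, 60.0], anterior_protocol()))
        second = results_to_records(run_protocol(scenario, [0.0, 60.0], anterior_protocol()))
        assert first == second


class TestPercentDifference:
    @pytest.mark.parametrize("value, reference, expected", [
        (5.0, 5.0, 0.0),
        (2.4, 3.40, -29.411764705882355),
        (7.0, 5.0, 40.0),
    ])
    def test_signed_percent(self, value, reference, expected):
        assert percent_difference(value, reference) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_difference(1.0, 0.0)


class TestLoadCase:
    def test_maximum_must_be_multiple_of_increment(self):
        with pytest.raises(ValidationError):
            LoadCase(force_max_N=130.0, force_increment_N=26.8)

    def test_default_protocol_consistency(self):
        load = LoadCase()
        assert load.force_max_N / load.force_increment_N == pytest.approx(5.0)
        assert load.torque_max_Nm / load.torque_increment_Nm == pytest.approx(5.0)
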