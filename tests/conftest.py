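import numpy as np
import pytest

from kneemech.ligaments import LigamentBundle
from kneemech.knee import KneeGeometry, RestraintSpring


@pytest.fixture
def single_bundle_knee():
    """Minimal knee: one bundle along +X, femur at the origin.

    With k = 10000 N, L0 = 30 mm and DL = 0.03 the linear branch inverts in
    closed form, giving an independent oracle for the equilibrium solver.
    """
    bundle = LigamentBundle(
        name="ACL_single",
        femur_insertion=[0.0, 0.0, 0.0],
        tibia_insertion=[30.0, 0.0, 0.0],
        stiffness_k=10000.0,
        reference_length_L0=30.0,
    )
    return KneeGeometry(
        bundles=(bundle,),
        restraint_springs=(),
        flexion_axis_point=np.zeros(3),
        flexion_axis_direction=np.array([0.0, 0.0, 1.0]),
        acl_footprint_femur=bundle.femur_insertion,
        acl_footprint_tibia=bundle.tibia_insertion,
    )
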