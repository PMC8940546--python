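# kneemech

Reduced-order biomechanics of the knee after anterior cruciate ligament
(ACL) reconstruction, plus the imaging and statistics that accompany a
post-reconstruction MRI follow-up study — all driven by synthetic data.

## Who this is for

Musculoskeletal modelers and methodologists who want a small, fully
scripted, desk-scale stand-in for a knee laxity experiment: rigid femur
and tibia, tension-only ligament bundles, an ACL graft fixed at a chosen
flexion angle, anterior-drawer and tibial-rotation loading protocols, bone
tunnel morphometry on MRI-like phantoms, and a stable-versus-unstable
cohort comparison.

## The model

Each ligament (and the graft) is a functional bundle with engineering
strain `D = (L − L0)/L0` and the piecewise quadratic–linear tension law

```
F(D) = 0                 D < 0          (slack)
     = k·D²/(4·D_L)      0 ≤ D ≤ 2·D_L (toe region)
     = k·(D − D_L)       D > 2·D_L     (linear)
```

with `D_L = 0.03`. The femur is placed at a prescribed flexion angle
(0°–90°); the tibia has two free DOFs — anterior translation and internal
rotation — and a damped Newton solver finds quasi-static equilibrium
under 134 N anterior loads (26.8 N increments) or 10 N·m internal torque
(2 N·m increments). Three scenarios are compared: **intact**,
**deficient** (ACL resected) and **anatomic** (single-bundle graft between
the native footprint centers, pretensioned and fixed at 0° or 30°).
Because the original cadaver calibration data are unavailable, the
packaged default parameters are a regression surface fitted so the model
reproduces the published kinematics and graft tensions; see
`docs/methods.md` for the fitting protocol and its caveats.

## Worked example

```python
from kneemech.calibrate import default_scenario
from kneemech.knee import anterior_protocol, run_protocol

scenario = default_scenario("anatomic", fixation_flexion_deg=0)
results = run_protocol(scenario, [30.0], anterior_protocol())
final = results[-1]
print(f"ATT  {final.anterior_translation_mm:.2f} mm")
print(f"tension {final.acl_or_graft_tension_N:.1f} N")
```

prints

```
ATT  6.13 mm
tension 43.8 N
```

— the anterior tibial translation of the reconstructed knee under the
full 134 N drawer load at 30° flexion with the graft fixed in extension,
and the graft tension carrying part of that load. With the shipped
calibration the model reproduces the six published graft tensions to
within 0.5 N, the anterior translations to within ~0.25 mm, and the
internal rotations to within ~0.5°; `docs/methods.md` explains which of
those gaps are structural limits of a two-DOF straight-line-element
model. The analysis drivers
under `analysis/` run the full study end to end:

```bash
python analysis/01_generate_inputs.py     # synthetic geometry, cohort, phantoms
python analysis/02_calibrate_model.py     # re-fit the defaults (slow, optional)
python analysis/03_simulate_scenarios.py  # kinematics of all scenarios
python analysis/04_tunnel_morphometry.py  # tunnel angles, diameters, enlargement
python analysis/05_cohort_comparison.py   # stable vs unstable t-tests
```

Each writes tidy CSVs (and one figure) under `results/`. A `kneemech`
command-line tool exposes the same stages (`kneemech simulate`,
`calibrate`, `measure`, `cohort`, `generate`, `report`).

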