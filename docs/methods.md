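# Methods

## The model

`kneemech` simulates passive anterior-posterior and axial-rotation laxity
of a knee after anterior cruciate ligament (ACL) injury and single-bundle
reconstruction, at the level of detail of a lumped-parameter rigid-body
model.  The femur and tibia are rigid.  The femur is placed by rotating it
about a fixed mediolateral flexion axis to a prescribed flexion angle
(0/30/60/90 deg in the standard protocols); the tibia keeps two free
degrees of freedom (DOFs): anterior translation along +X and internal
rotation about its long axis (+Y).  The coordinate frame is tibia-fixed,
right-handed, +X anterior, +Y superior, +Z lateral (right knee); lengths
in mm, forces in N, moments in N*mm internally (torques cross the CLI in
N*m).

### Ligament elements

Each ligament is one or more *functional bundles*: straight tension-only
elements between a femoral and a tibial insertion.  With engineering
strain `D = (L - L0)/L0`, tension follows the standard toe-region law

    F = 0                    D < 0
    F = k D^2 / (4 DL)       0 <= D <= 2 DL
    F = k (D - DL)           D > 2 DL

with stiffness `k` (N per unit strain) and transition strain `DL = 0.03`
for every bundle including the graft.  The two branches agree in value and
slope at `D = 2 DL`, so the law is C1.  There is no wrapping, no
viscoelasticity and no strain-rate dependence.  The intact ACL is modeled
as two functional sub-bundles (anteromedial and posterolateral) with
reciprocal mediolateral obliquity; the posterior cruciate and the two
collateral ligaments are one bundle each.

### Restraints

Capsule/meniscus restraint is lumped into two kinds of element:

* four bilinear point-to-point springs (anterior-posterior surrogates at
  two obliquities, medial and lateral).  Their rest lengths are taken at
  the zero-DOF pose of the current flexion angle, so they resist DOF
  excursions without imposing a flexion-dependent neutral shift;
* one torsional restraint about the tibial long axis with stiffness
  `k(phi) = k_90 + (k_0 - k_90) exp(-phi/tau)` (N*mm/deg).  A torsional
  element is used because point springs cannot reproduce the reported
  axial-rotation stiffness (10 N*m producing only a few degrees) without
  also contaminating the anterior-drawer compliance: any spring with an
  anterior direction component `u_x` adds `k u_x^2` of AP stiffness, and
  femoral attachment points far enough from the flexion axis to give a
  useful torque lever swing with flexion.

### Scenarios

* **intact** -- the full bundle set;
* **deficient** -- all ACL sub-bundles removed (simulated rupture);
* **anatomic** -- ACL sub-bundles replaced by a single graft bundle
  spanning the native footprint centers (the centroids of the ACL
  sub-bundle insertions, which are also the tunnel sites).  The graft
  reference length is set in closed form so that at the fixation flexion
  angle (0 or 30 deg) with the free DOFs at zero it carries exactly the
  prescribed pretension.  Fixation hardware (screws, tunnel friction) is
  not modeled.

### Equilibrium

For a load case (anterior force up to 134 N in 26.8 N increments; internal
torque up to 10 N*m in 2 N*m increments) the solver finds the DOF pair
that zeroes the net anterior force and net axial moment on the tibia,
using damped Newton iteration with a central-difference Jacobian,
tolerance 1e-6 N / 1e-6 N*mm, at most 200 iterations, warm-started across
load increments.  Reported translations/rotations are *laxity* values: the
solved pose minus the unloaded equilibrium of the same scenario at the
same flexion, which is how drawer laxity is measured experimentally and
keeps pretensioned-graft scenarios comparable.  The protocol runner emits
one row per (flexion, increment) -- 4 x 5 = 20 rows per protocol -- and is
deterministic: identical configurations give byte-identical result files.

## Calibration

The stiffnesses of the system this package models were originally
identified from a robotic cadaver experiment that is not available.  The
packaged default parameters are therefore a *regression surface*: a
bounded weighted least-squares fit (`scipy.optimize.least_squares`, trf,
fixed committed starting vector, no stochastic restarts) of

* per-bundle stiffness `k` and reference-length scale (bounds [0.8, 1.2]),
* the four spring stiffnesses and three torsional-restraint parameters,
* graft stiffness and one pretension per fixation angle,
* small ACL insertion-placement offsets (femoral in-plane and mediolateral,
  tibial anterior-posterior; bounded by a few mm) that shape how the
  inter-footprint distance varies with flexion,

against the published anatomic-arm values (anterior translation, internal
rotation, graft tension at both fixation angles), intact values recovered
by inverting the uniquely stated percent differences (down-weighted 0.5
because several are stated as "about"), and hinge penalties for the stated
ranges (deficient knees 33-40% above intact at 30-90 deg; the fixed-at-0
reconstruction 8-19% above intact at 30 deg) that are zero anywhere inside
the range.  Residuals are scaled by the reporting tolerances (0.1 mm,
0.1 deg, 0.5 N), so a unit residual equals one tolerance.

Because the defaults are fitted to the published outputs, agreement with
those outputs is a consistency check of the reduced-order representation,
not an independent validation.  Rotation targets are evaluated under the
torque-only protocol; anterior-translation and tension targets under the
force-only protocol.

Calibration self-consistency is tested by parameter recovery: targets
generated by the model at a known vector are re-fitted from a perturbed
start and matched to better than 0.5%.

## Tunnel morphometry

Bone tunnels are measured in image coordinates (mm, origin at the volume
corner, axis order anterior/superior/lateral).  The imaging geometry is a
routine knee MRI protocol: 180 x 180 mm field of view on a 320 x 256
in-plane matrix (0.5625 x 0.703125 mm pixels), 4 mm slices with a
0.5-1 mm gap; axial slices stack along the superior axis.  The tunnel axis
is oriented distal-to-proximal; its angle in the coronal (superior-
lateral) or sagittal (anterior-superior) plane is the angle between the
in-plane projection and the superior long-bone axis, in [0, 90] deg --
the angle convention is fixed by the phantom round-trip, since the source
material does not state one.  Diameters are measured at the centers of the
three equal thirds of the tunnel (fractions 1/6, 1/2, 5/6), each as the
mean of three repeated reads.  The enlargement rate is the signed percent
change of the mean follow-up diameter against the intraoperative 7.0 mm
bore.  (A published mean enlargement of -11.25 +/- 12.46% is *negative*
despite being called an enlargement; the generator and the statistics
support both signs and make no assumption here.)

Voxel phantoms rasterize a cylinder onto the imaging grid; measurement
recovers the axis by per-slice centroids and a least-squares line fit
(end slices are dropped because oblique end cuts bias the centroid), and
the diameter as the mask width along the in-plane direction perpendicular
to the axis projection -- the minor axis of the elliptical cross-section,
which equals the true diameter of a tilted cylinder.  Expected accuracy,
verified by round-trip tests: angles within 1 deg at 4.5 mm slice spacing
and 60 mm tunnel length; diameters within 2 in-plane pixels.  Landmark
phantoms round-trip exactly.

## Cohort statistics

Group summaries are mean +/- sample SD (n-1) for continuous variables and
count (percent, half-up to one decimal) for categorical ones.  The group
comparison is the pooled-variance two-independent-samples t-test
(two-sided; Welch available by flag), with significance at alpha = 0.05.
The published t/P pairs for the angle comparisons are mutually
inconsistent and not reproducible from the printed summaries (e.g.
t = 2.564 printed with P = 0.001 at df = 88, while the printed means/SDs/n
give t = 4.39), so the implementation is validated against textbook closed
forms and the qualitative P < 0.05 claim, not against those printed
statistics.

## Synthetic data

All inputs are generated, seeded and reproducible:

* **geometry** -- a committed idealized template knee (synthetic; no
  cadaver coordinates exist for the source system) whose insertions are
  perturbed by isotropic Gaussian noise of SD 0.2 mm, the stated accuracy
  of the digitizing arm being emulated.  Footprint centers are recomputed
  from the perturbed insertions.
* **cohorts** -- per-group independent normal draws of the four tunnel
  angles with the published means/SDs and group sizes (54 stable, 36
  unstable), plus ages and sexes; no covariance structure is assumed
  because none is reported.
* **phantoms** -- landmark or voxel tunnels at prescribed plane angles.
* **follow-up reads** -- station diameters at a prescribed true change
  plus zero-mean per-read noise, emulating triplicate measurement.

What the generators do *not* emulate: real MRI contrast and segmentation
error, correlated angle variables, non-normal cohorts, digitization bias
(as opposed to noise), and any within-patient correlation between tunnel
geometry and instability.  Passing tests therefore demonstrate the
pipeline's internal correctness and statistical calibration under the
stated generating assumptions, not clinical validity on real images.

## Numerical choices and limitations

* Newton tolerance 1e-6 N / 1e-6 N*mm; central differences with step
  1e-6; backtracking line search halving up to 30 times.
* The graft pretension inverse uses the closed-form branch inversion of
  the force law (quadratic branch for F <= k*DL, linear above).
* Problem sizes: protocols use the full published schedules (5 increments,
  4 flexion angles); the null-calibration simulation uses 2000 seeded
  replicates and the power checks 200 seeds, sizes at which the binomial
  noise is well below the tested margins.
* The 2-DOF reduction cannot represent coupled valgus/varus or
  compartment-wise translation; rotational differences between scenarios
  arise only from the ligament elements' geometry, which is a weaker
  coupling than the contact mechanics of a full finite-element knee.  This
  is the main structural limitation of the reduced model and the reason
  the rotation arm of the calibration is the hardest to satisfy.
* Quantitatively, with the shipped defaults the fit reproduces all six
  graft tensions within 0.5 N and the six anterior translations within
  0.25 mm (three of them within the 0.1 mm reporting precision), but the
  four rotation values only within about 0.5 deg.
  The rotation residual is structural, not numerical: the published
  values imply that rotational stiffness differs between fixation angles
  and scenarios (e.g. 7.3 deg with the graft fixed at 0 deg versus
  6.6 deg fixed at 30 deg, both at 90 deg flexion), but a straight-line
  graft inserting near the tibial axis has a torque lever of only a few
  mm, so its elastic rotational stiffness is two orders of magnitude
  below what those differences require; in this model class the two
  fixation arms necessarily rotate almost identically.  Likewise the
  deficient-versus-intact translation excess spans 32.9-40.1% across
  30-90 deg flexion against the stated 33-40% band: the model's excess
  profile is marginally wider (by ~0.1 percentage point at each end) than
  the band, and narrowing it further is blocked by the translation and
  tension targets.
* The graft's printed "stiffness of 10 mm" in the source material is
  dimensionally unusable; graft stiffness is a calibration parameter and
  10 mm is recorded as the tunnel diameter only.
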