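# Methods

## The calibration problem

A 3D model-based gaze tracker reconstructs, per eye, the 3D corneal
center `C` (mm, camera frame) and the optical-axis direction `Voa` (the
line through eyeball, corneal, iris and pupil centers).  The actual
gaze is the visual axis `Vva` through the fovea and the corneal center;
it is offset from the optical axis by the kappa angle, which differs
between individuals and between a person's two eyes.  Classical
calibration asks the user to fixate known on-screen points; this
package calibrates kappa *implicitly* from binocular observations
gathered during ordinary screen viewing.

## Angular model

The eyeball coordinate frame sits at the corneal center with x/y
parallel to the screen's horizontal/vertical edges and z normal to the
screen, pointing toward the eye.  A unit direction is parameterised by
a horizontal angle ω and vertical angle φ:

    v(ω, φ) = (cos φ sin ω,  sin φ,  −cos φ cos ω),

so ω = φ = 0 looks straight at the screen.  The inverse is
φ = arcsin(y), ω = atan2(x, −z); atan2 covers all quadrants, and
directions within 1e−12 of straight up/down are rejected (ω is
undefined there).  Kappa is the per-eye pair (α, β) added to the
optical-axis angles:

    Vva = h(Voa, C; α, β):  (ω, φ) → (ω + α, φ + β).

Directions transform between frames with the rotation only; the
translation applies to points.  Degrees at every public interface,
radians internally.

## The binocular coplanarity objective

When both eyes fixate one point, the two visual axes span a *gaze
plane*, and because each corneal center lies on its eye's visual axis,
the corneal baseline `C_L − C_R` lies in that plane.  With
n = (VvaL × VvaR)/‖VvaL × VvaR‖, the calibration minimises

    f(αL, βL, αR, βR) = Σ_i ( n_i · (C_iL − C_iR) )²        [mm²]

over N samples.  Four unknowns require N ≥ 4 (the solver warns below
that); f = 0 exactly at the true kappa on exact data.  Cross and dot
products are rotation-invariant, so `CoplanarityObjective` precomputes
the per-sample optical-axis angles and baselines in the eyeball frame
once and evaluates whole candidate batches with vectorised
trigonometry.  Candidates that make some sample's axes (near-)parallel
(cross-product norm < 1e−12) or push φ past ±90° receive a fixed
penalty of 1e6 so the population remains iterable; a final result is
never accepted at the penalty value.

### What the constraint can and cannot determine

A *common* rotation of both visual axes (the same δω or δφ added to
both eyes) moves the binocular fixation point but keeps the axes
(nearly) intersecting — hence still (nearly) coplanar with the
baseline.  For a common elevation change with both eyes at the same
height the configuration rotates rigidly about the baseline and f is
unchanged *exactly*.  Numerically, the objective's Hessian at the truth
has two weak eigenmodes (common-α and common-β, curvature
~0.1–1.5 mm²/deg² in the remote scene) against stiff differential
modes (~10²–10³).  Consequences:

* on exact data the minimum is still exactly at the truth, and driving
  f below 1e−9 pins every component to ≲1e−4 deg;
* under measurement noise the *differential* (binocular) combinations
  h = (αL − αR)/2 and, to a lesser degree, v-differences remain sharply
  determined, while the per-eye components drift along the common modes
  until the box bounds stop them.  Noise reports therefore include both
  the per-eye component RMSE and the binocular-component RMSE
  (`binocular_horizontal`, `binocular_vertical`).

This asymmetry is a property of the coplanarity constraint itself, not
of the solver: a brute-force grid minimiser and an independent DE
implementation land on the same displaced minimum under noise.

## Differential-evolution solver

Population of W candidate vectors x = (αL, βL, αR, βR), initialised
component-uniform inside per-component bounds.  Per generation and per
candidate k: mutation v = x_r1 + K (x_r2 − x_r3) with r1, r2, r3
mutually distinct and ≠ k, clamped to the bounds; a *whole-vector*
crossover gate (one uniform draw per candidate: take v if rand ≤ c,
else keep x_k — a per-component binomial variant exists behind
`binomial_crossover` but is not the default); greedy selection with
ties keeping the parent; survivors replace the population synchronously
and the elitist best (x_op, ε_op) is updated.  Termination when
ε_op < δ (the reported iteration count is that generation) or after T
generations.  One seeded generator drives initialisation, partner
selection and crossover gates in a fixed order, so runs reproduce
bit-for-bit.

Defaults: the *theoretical* preset W=35, K=0.5, c=1, δ=1e−9,
bounds 4..8 / 0..3 / −8..−4 / 0..3 deg (the anatomical kappa range with
the right eye mirrored); the *practical* preset K=0.01, c=0.1 with
symmetric ±5° bounds for noisy real-scene data.  T defaults to 1000:
noiseless runs converge in ~60–110 generations and the slack covers
noisy objectives.  With vector-level crossover the population
occasionally (~2% of runs) collapses onto a non-optimal point and
stagnates; the noiseless experiment drivers therefore retry a stagnated
run with a fresh solver seed (reported calibrations are converged
ones), while noise sweeps keep whatever the search returns after T
generations.

## Scene simulator

The generator emulates two setups.  *Remote*: a 400×300 mm screen
tilted ~40° about the camera x-axis (corners at x ±200 mm), left
corneal center uniform in x ∈ [−45, −15], y ∈ [−90, −50],
z ∈ [350, 650] mm.  *Head-mounted*: a 300×210 mm display plane at
z = −400 mm with the left corneal center in x ∈ [5, 10], y ∈ [20, 30],
z ∈ [25, 35] mm.  The right corneal center sits exactly 60 mm from the
left along a random direction within a 30° half-angle cone about the
screen-horizontal axis — the baseline length is anatomical, and the
cone keeps the eyes side by side while allowing the small head tilts
seen in the fixed worked pair (whose offset is ~13.5° off the
horizontal).  Gaze points are uniform on the screen rectangle (bilinear
in the corners), optionally restricted to one of four quadrants
numbered row-major from the top-left.  Ground-truth kappa defaults to
(5, 1.5, −5, 1.5)°, the population average with the right eye's
horizontal component mirrored.

Given corneal centers, gaze point and true kappa, the visual axis per
eye is unit(gaze − C) and the optical axis is built *in reverse* by
subtracting (α, β) from the visual-axis angles; every noiseless sample
therefore satisfies the coplanarity identity to machine precision, and
`visual_axis_from_optical` at the true kappa returns the original
visual axis exactly.

Noise models §-style measurement error: independent zero-mean Gaussian
noise per coordinate of both corneal centers (SD in mm; independent
realizations per eye — a shared realization would leave the baseline,
and hence the objective, unchanged) and independent Gaussian noise on
each eye's optical-axis angles ω and φ (SD in degrees; the direction is
rebuilt afterwards).  SD 0 returns the sample unchanged.

What the simulator does *not* model: schematic-eye optics (corneal
refraction, pupil imaging — only the resulting corneal centers and
axes are needed), head roll, eye torsion, fixation disparity between
the eyes, or temporally correlated tracker error.  Passing tests
therefore demonstrate correctness of the estimator under the stated
geometric and noise assumptions, not end-to-end accuracy on real
video-based reconstructions.

## Evaluation

The point of regard is the ray-plane intersection
S = C + ((Q − C)·n / (Vva·n)) Vva, binocularly the midpoint of the two
per-eye intersections (a flag substitutes the raw optical axes — the
kappa-free POA baseline).  Gaze accuracy is θ = arctan(RMSE/D) in
degrees with D the point-to-plane distance of the corneal-center
midpoint (chosen over per-gaze-point distances for determinism);
per-axis X/Y accuracies project residuals on the screen-frame edges.
Kappa recovery is reported as per-component RMSE against the truth
plus the binocular-component RMSE described above.

Experiment drivers (all pure functions of their seed): repeated
noiseless calibrations (fresh dataset and solver seed each),
ground-truth variation over six kappa settings (bounds recentred to
truth ± 2° horizontally so every truth is interior), fixed-head gaze
regions (one fixed corneal pair, 30 points per quadrant), the
data-amount sweep {1, 2, 4, 6, 9, 16, 25, 50, 100} × 10 calibrations,
and the two noise sweeps (corneal SD 0–4 mm step 0.5; axis-angle SD
0–1° step 0.1°), each re-noising one fixed 9-sample base dataset per
repeat so the noise level is the only variable.  The default repeat
count for the sweeps is 100; the test suite runs 30 to keep the suite
fast, and the sizes used are printed with every report.

## Baselines

* matrix method: ordinary least squares for M in Vva ≈ M Voa over
  N ≥ 3 stacked axis pairs (no orthogonality constraint — the estimator
  is unconstrained by design and recovers a generating rotation exactly
  on rotation-generated data).  Note the kappa angle-offset map is not
  exactly linear, so on kappa-generated data the best M leaves a small
  residual.
* angular method: per eye, α = ω_va − ω_oa and β = φ_va − φ_oa from a
  single sample with a known gaze point; differences wrapped to
  (−180°, 180°].  Exact on noiseless synthetic samples.
* constant method: fixed (5, 1.5, −5, 1.5)°.

## Numerical choices and edge cases

* Unit-norm validation at 1e−9; frame orthonormality at 1e−9;
  screen-plane coplanarity at 1e−6 mm.
* Screen corners accepted as a rectangle cycle whose first edge is the
  horizontal direction; the vertical edge is re-oriented upward by its
  dot product with camera +y (kept as given when exactly perpendicular,
  e.g. a 90°-rolled screen); crossed orderings are re-cycled keeping
  corner 0 first.  The frame's x-axis flips, preserving handedness, if
  the initial z-axis points away from the eye.
* Ties in DE selection keep the parent (strict improvement required);
  bounds are enforced by clamping at mutation time, so no candidate is
  ever outside them.
* Cone sampling is uniform over the spherical cap (cos θ uniform on
  [cos θmax, 1]); a zero half-angle degenerates to an exact
  screen-horizontal offset.
* `grid_search_kappa` evaluates the objective on a regular grid in
  chunks of 2·10⁵ candidates to bound memory; it exists as a
  brute-force cross-check, not a production solver.

## Known limitations

* Per-eye kappa components are only bound-constrained under realistic
  noise (see the common-mode analysis above); applications needing
  accurate per-eye components should combine this method with at least
  one explicit calibration point or a vergence-breaking protocol.
* Strabismus/amblyopia violate the coplanarity premise (the visual
  axes need not co-fixate); the method does not apply.
* Head roll changes the optical-to-visual-axis relation in ways the
  screen-fixed eyeball frame cannot represent; the simulator does not
  generate it and the estimator does not compensate for it.
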