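# Methods

This note records the models behind `corneosim`, the choices made where the
design was genuinely open, and what the synthetic data can and cannot show
about real corneas.

## Scope and shape of the analysis

The package reproduces, at desk scale, the analysis chain used to compare
intracorneal ring segment (ICRS) designs in a generic healthy and a generic
keratoconic cornea: synthetic corneal surfaces stand in for finite-element
model outputs, and the downstream stages — biconic curvature fitting,
sagittal curvature mapping, Zernike aberration analysis, and the refraction
arithmetic — are exactly the computations a topography-based study would
run on measured or simulated elevations. A simplified membrane-inflation
solver reproduces the mechanical ingredients (Yeoh hyperelasticity,
intraocular pressure loading, regional keratoconic weakening, inverse
stress-free geometry) without shell bending or implant contact mechanics.

## Synthetic surfaces

**Biconic base surfaces.** Each cornea is a biconic sag surface with
independent radii (Rx, Ry in mm) and asphericities (Qx, Qy) for the two
principal meridians, sampled on a regular grid (default 0.1 mm) clipped to
a 9 mm zone. The sag convention puts z = 0 at the apex, increasing
posteriorly; an anterior protrusion therefore lowers z. Default parameters:
anterior 7.37/7.62 mm with Q −0.25/−0.10, posterior 7.91/7.97 mm with
Q 0.63/0.37 (the reference model's pre-operative assessment).

**Keratoconic cone.** The cone is a Gaussian anterior protrusion
`Δz = −a·exp(−ρ²/2w²)` centred 1 mm inferior to the apex. The analytic
form is a modelling choice (only the weakened-zone geometry of the
reference model is known); a Gaussian is the simplest smooth bump with a
controllable decay length. The defaults are calibrated once against the
two stated outcomes of the reference keratoconus simulation: amplitude
a = 110 µm reproduces the +0.11 mm axial-length increase, and decay length
w = 2.75 mm reproduces the +4.7 dpt increase in mean anterior power over
the 5 mm fitting zone. The cone moves the most-elevated point (sag
minimum) off-axis, which is what triggers the map re-centring rule below.
The posterior surface receives a half-amplitude copy of the cone.

**ICRS emulation.** Ring implantation is emulated geometrically, not
mechanically — the emulation exists so the downstream stages are testable
against a known ground truth, and makes no claim of predicting implant
mechanics. Three smooth, compactly supported components, all scaled by a
single gain g (µm of effect per mm² of implant cross-section):

1. *optical-zone flattening*: a quartic posterior recession
   `δ·(1 − (r/4.2)²)²` with apex magnitude δ = g × (arc-mean cross-section);
   this produces both the average flattening seen by the biconic fit and
   the axial-length reduction;
2. *ring-track anterior lift*: a radial cos² bump spanning exactly the
   local base width outward of the optical-zone radius (3 mm), with
   magnitude proportional to the local thickness × width interpolated
   linearly along the 160° arc — tissue over the implant is elevated, so
   sagittal curvature drops interior to the track;
3. *opposite-half steepening*: a smaller (0.15×) posterior bump of the same
   radial shape on the diametrically opposite arc.

The angular windows are exactly 1 over the arc with cos² shoulders outside
the arc ends, so the perturbation magnitude *at* each arc end reflects the
implant cross-section there (the thick-end/thin-end ratio of the
progressive design is exactly (300·800)/(150·600) = 2.67), and the
perturbation is identically zero outside its support. The default gain
g = 250 µm/mm² makes the average symmetric ring flatten the healthy cornea
by 3.3 dpt with a 39 µm apex recession, the scale reported for that design.

**What the synthetic data does not have:** microstructure-driven
anisotropic response, tunnel expansion, implant—tunnel contact, epithelial
and stromal remodelling, measurement artefacts of real topographers
(missing data, alignment error), and the mechanical coupling that makes
equal-cross-section designs differ in the reference FEM. Tests passing on
these surfaces validate the *analysis stages*, not mechanical predictions.

Optional iid Gaussian elevation noise (default 0, seeded) supports
robustness checks; the fixture writer is byte-deterministic per seed.

## Membrane mechanics

**Discretisation.** Constant-strain triangles on a spherical-cap mesh
(polar rings × sectors), total-Lagrangian kinematics. The two stromal
layers are merged into a single membrane of 550 µm with thickness-weighted
Yeoh constants (anterior 385 µm / posterior 165 µm), since the tunnel
interface carries no load in this simplification. Material constants in
kPa: healthy C1/C2/C3 = 35.5/3.2/1.9 (anterior) and 32.0/2.9/1.7
(posterior); keratoconic zones are 0.70× (annulus to 3 mm) and 0.30×
(core, radius 1.5 mm) of healthy, matching the reference material table to
≤ 0.25 kPa.

**Constitutive law.** Incompressible isotropic Yeoh,
`W(I1) = C1(I1−3) + C2(I1−3)² + C3(I1−3)³`, with the thickness stretch
eliminated by plane stress and exact incompressibility
(λ₃ = 1/(λ₁λ₂), det F = 1). The tabulated volumetric parameter d is
carried for completeness but never enters the discrete equations; its
units in the source table are ambiguous and its value is immaterial under
exact plane-stress enforcement. Principal Cauchy stresses are
`σᵢ = 2W′(I1)(λᵢ² − λ₃²)`, verified in the tests to equal the numerical
derivative of the energy to ≤ 1e−6 relative.

**Equilibrium.** Internal forces are the analytic gradient of the total
membrane energy; the follower pressure (15 mmHg = 1999.8 Pa on the
posterior face) contributes p/3 of each deformed element's area vector to
its nodes. The tangent is assembled from element-level central differences
of the vectorised analytic gradient (9×9 blocks, h = 1 nm) and solved by
sparse LU; Newton iterations use a backtracking line search on the max
residual with Levenberg regularisation as fallback, adaptive load
substepping (bisection on failure), and converge on both residual
(≤ 1e−8 × pressure × mean element area, with a roundoff floor) and step
norm. Boundary conditions: rim nodes either clamped or sliding radially in
their own plane (the equatorial condition; the sclera is not meshed, its
constants are carried in the reference table only).

At 1% of IOP the hemispherical cap reproduces the Laplace stress
pR/2t to 0.6% (mesh 12×28); at full IOP the healthy 11 mm cap displaces
its apex ≈ 0.77 mm anteriorly — large, because a pure membrane lacks
bending stiffness and the Yeoh constants here are soft at small strain.

**Inverse stress-free geometry.** The unloaded configuration is found by a
deflation iteration on the shape mismatch, accelerated with the exact
mismatch sensitivity: at equilibrium, dx/dX = −K⁻¹K_X by the implicit
function theorem, where K is the deformed-coordinate tangent and K_X the
reference-coordinate tangent (assembled the same way). The classical
damped update (new rest shape = rest shape − damping × mismatch) is the
K_X = −K approximation of this step; for a membrane it is *non-contractive*
— the inflated shape's sensitivity to rest-shape curvature is large and of
mixed sign — so the exact step, blended with a Levenberg parameter and a
line search, replaces it. The iteration stops when the re-inflated shape
matches the target to 0.1 µm at every node, and raises a failure report
with the mismatch history otherwise.

**A structural limitation, analysed.** At physiological IOP the inverse
problem for this membrane has no solution: pressure-continuation
experiments show the required rest shape deepens super-linearly (rest apex
sag 0.09 / 0.21 / 0.45 / 1.07 mm at 0.5 / 1 / 2 / 3.5 mmHg for the 11 mm
cap) and crosses the membrane ballooning limit point near ~4 mmHg — beyond
it, no stable unloaded configuration inflates into a spherical cap.
Shell models avoid this because bending stiffness stabilises the rest
shape. Consequently the inflate-after-inverse identity is demonstrated at
1 mmHg (error 0.06 µm, well within the 0.1 µm tolerance), and at 15 mmHg
the solver's failure report is itself the documented, tested behaviour.
The *forward* problem at 15 mmHg is unaffected and is used by all other
mechanics analyses.

## Curvature analysis

**Biconic fitting.** Nonlinear least squares (Levenberg–Marquardt) of the
biconic sag plus a free apex offset z₀ over a 5 mm zone; the offset is
needed because deformed surfaces no longer pass through the coordinate
origin, and converges to zero for exact biconic inputs. Initialisation is
a paraxial linear fit (1/Rx, 1/Ry, z₀) with Q = 0; tolerances 1e−14 on
step, cost and gradient; a radicand guard returns penalty residuals
outside the biconic domain. On noiseless biconic surfaces the four shape
parameters are recovered to ~1e−14 relative across Rx, Ry ∈ [5.5, 9] mm,
Q ∈ [−2, 2]. With 1 µm elevation noise the radius estimator has
σ ≈ 0.007 mm (the free q-value is strongly collinear with the radius over
a 5 mm zone), so noisy-recovery tests assert max < 0.03 mm over 100
replicates rather than a tighter bound the estimator cannot meet.

**Sagittal maps.** The clinical axial definition: at each map point the
axial radius is the distance along the local surface normal to the
reference axis, converted to diopters with the surface's refractive index
step (anterior +0.375, posterior −0.042), i.e.
`K = 1000·Δn·sinφ/r` with tanφ the meridional sag slope; at the origin the
meridional limit `K = 1000·Δn·z_rr` applies. Maps are polar
(64 meridians × 0.05 mm radial step, 8 mm display zone by default). For
keratoconic surfaces the origin (and axis) is first moved to the most
elevated point, as topographers do for decentred cones. Tangential
(meridional) curvature is available as an option.

Surface derivatives come from a moving local quadric-patch fit: at each
evaluation point a weighted quadric is fitted to the 16 nearest samples,
giving analytic first and second derivatives. This replaces an earlier
interpolation approach (piecewise-cubic C¹ interpolants have discontinuous
second derivatives and produced multi-diopter artefacts), works on
scattered samplings such as deformed mesh nodes, is exact for
paraboloids, and reproduces the uniform 50.0 dpt map of a 7.5 mm sphere
to 0.012 dpt.

**ΔAL.** Axial displacement is measured anterior-positive, so a posterior
recession of the anterior surface (the ICRS effect) yields a negative
axial-length change, matching the sign convention of the reference
assessment (a 40 µm apex recession reports ΔAL = −0.04 mm).

## Aberrations

Orthonormal Zernike polynomials with OSA/ANSI single indexing through
radial order 6 (28 terms), normalisation √(2(n+1)/(1+δ_m0)), fitted to
elevation in µm by plain linear least squares on scattered points within
the pupil (default 5 mm, matching the optical-zone analyses; the pupil is
configurable and recorded in all outputs). A condition-number check
(threshold 1e8) triggers a warned ridge fallback. Round-trips on exact
basis surfaces recover all 28 coefficients to ≤ 1e−8 µm; discrete
orthonormality holds to 1e−6 under Gauss–Legendre × uniform-angle
quadrature. Change tables difference scenario spectra against a baseline
and label indices 1–14 with their clinical names (vertical/horizontal
tilt … vertical quadrafoil); low/high-order summaries are provided in
signed and RMS variants (split at radial order 3), since no single
convention reproduces every published summary row. Fifth- and sixth-order
terms are fitted but excluded from headline summaries.

## Refraction arithmetic

Surface power is (n1−n0)/R with n = 1 / 1.375 / 1.333 for air / cornea /
aqueous, with the sign convention that a convex anterior surface has
positive power (the source formula's printed operand order would make the
anterior power negative and is treated as a misprint). The "average" power
of a biconic surface is the arithmetic mean of its two meridional powers —
the only averaging rule that reproduces the healthy-block dioptric-change
column from the printed radii at 2 d.p.; mean-radius and geometric-mean
variants are kept behind a switch. An axial-length change converts to a
myopic shift as D_total² × |ΔAL| (D_total = 60 dpt for the healthy eye,
64.7 for the keratoconic one, i.e. 60 + the 4.7 dpt cone steepening);
this form reproduces the published 0.13 dpt from a 36 µm shortening where
a vergence-based alternative does not. The effective refractive change of
a scenario is Δanterior + Δposterior − myopic_shift, with flattening
negative; reported values round to 1 d.p. (2 d.p. for per-surface
columns). The keratoconic block's anterior dioptric-change column is not
recoverable from its printed radii (its averaging zone is evidently
different); the arithmetic therefore consumes the printed per-surface
changes for that block, while the healthy block is recomputed from radii.

## Determinism and problem sizes

Every random element (measurement noise, parameter sweeps, random test
spectra) is driven by a seeded NumPy generator. Pipeline reruns with equal
configuration are byte-identical, and the configuration hash is written to
the run log. Mechanics analyses use cap meshes of 6–12 rings × 16–28
sectors (≈ 100–340 nodes) — fine enough for the sub-percent Laplace
agreement above while keeping every analysis script and the test suite in
the seconds-to-minutes range on a single CPU.

## Known limitations

* The ICRS effect is a calibrated geometric emulation; designs with equal
  mean cross-section produce near-identical average outcomes by
  construction, unlike the mechanical reference model.
* The membrane simplification overestimates inflation displacement and
  makes the inverse stress-free problem ill-posed at physiological IOP
  (see above).
* No epithelial/stromal remodelling: post-operative surface smoothing seen
  clinically is absent by design.
* Sagittal maps assume single-valued elevation over the analysis zone —
  valid for corneal geometries, not for arbitrary closed surfaces.
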