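# Methods

`qma` measures the morphology of an intact (articulated) two-bone joint
from a segmented 3D microCT volume: cartilage morphometry, direct bone
morphometry, and a set of whole-joint measures built on surface
landmarks and virtual loading.  This note records the conventions,
estimators and numerical choices behind each quantity, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Grid and anatomical conventions

Volumes are arrays indexed `(x, y, z)` with isotropic spacing in mm:
`x` medial–lateral, `y` antero–posterior, `z` distal→proximal (z grows
toward the femoral shaft).  Coordinates are voxel-centre based and
0-based; index `i` maps to `origin + i·spacing`.  Label codes are fixed
(0 background, 1 femur, 2 tibia, 3 femoral cartilage, 4 tibial
cartilage); richer segmentations must be mapped by the caller.  A
laterality flag resolves the mirror ambiguity: for a *right* knee the
lateral compartment occupies the low-x half, for a *left* knee the
high-x half.

## Pre-processing

* **Constrained Gauss filter.**  The separable Gaussian kernel is
  truncated at ±`s` voxels and renormalised to sum exactly 1 — the
  `(σ, s)` parameterisation of scanner-vendor pipelines.  Default
  `σ = 1.2, s = 1` (a 3×3×3 kernel).  The filter is applied to the
  attenuation volume only, never to label maps.
* **Threshold segmentation** assigns a label to voxels ≥ threshold and
  removes 26-connected components below a minimum size.  It exists to
  make phantom pipelines reproducible; segmentation of real scans is an
  input, not something this package attempts.
* **Rigid resampling** supports nearest, trilinear and cubic-B-spline
  interpolation; label volumes must use nearest.  Transforms are
  `x_out = R·x_in + t` in physical mm; out-of-field voxels become
  background.

## Local thickness (Cg.Th, Tb.Th, Tb.Sp, Ct.Th)

Thickness is model-independent: the local thickness at a point is the
diameter of the largest sphere that contains the point and fits inside
the structure.  Implementation: Euclidean distance transform → distance
ridge (balls provably contained in a neighbour's ball are pruned; only
provable containment is used, so the reduction is exact) → descending
ball-painting, with the standard shortcut of not repainting a centre
already strictly covered by a larger ball (sub-voxel effect confined to
surface voxels).

The inscribed-ball radius is the distance to the nearest *background
voxel centre*.  Consequences, all deliberate: a full-width plate of
`t` voxels reports exactly `t`; a digitised ball of radius `r` reports
a maximum of `2r + O(lattice)`; an isolated voxel reports 2 voxels, the
minimum resolvable structure size under this convention.  Where a mask
touches the array boundary the structure is treated as continuing, so
full-extent slabs behave as infinite plates.  2D section thickness
(largest inscribed disc) uses the same engine on 2D masks and is
reported in µm.

## Volumes and surfaces

`Cg.V`/`BV`/`TV` are exact voxel counts scaled by `spacing³`.  Surface
areas (`Cg.S`, `BS`) are triangulated iso-surface areas: the binary
mask is padded (closing boundary faces), smoothed with a 0.5-voxel
Gaussian, and meshed by marching cubes at the 0.5 level.  The light
smoothing removes the ~9% staircase overestimate of binary marching
cubes; residual bias is ≤ ~4% for spheres (high) and ≤ ~3% for boxes
(low) at ≥ 10 voxels per side.  Objects too small to survive smoothing
fall back to the raw binary mesh and carry a documented low bias (a
single voxel meshes to an octahedron at ~29% of its voxel-face area).
The full closed boundary is measured — for cartilage this includes the
bone–cartilage interface, not only the articular face.

## Connectivity (Conn.D)

`Conn.D = max(0, 1 − χ)/TV` with the Euler characteristic χ computed by
2×2×2 configuration counting using the (26, 6) foreground/background
connectivity pair.  For a single connected component without cavities,
`1 − χ` is the number of independent connections (first Betti number).
Negative `1 − χ` (several components) is clamped to zero with a
warning.  The TV used for normalisation is the caller-supplied total
volume mask; inside the pipeline it is the hole-filled envelope of the
compartment's bone mask.

## Degree of anisotropy (DA)

Mean intercept length (MIL): along each test direction a stratified
grid of parallel secant lines (default 24×24 lines, 0.5-voxel stepping,
trilinear sampling thresholded at 0.5) is marched through the volume;
`MIL(u)` = total intercept length in bone / number of
background-to-bone crossings.  The direction set (default 128) is a
spherical Fibonacci spiral replicated under quarter-turns about z, so
an in-plane 90° rotation of the specimen maps the set onto itself;
this keeps DA stable (≈1%) under such rotations.  A second-order
fabric tensor is fitted to `1/MIL²` by least squares; DA is the ratio
of the longest to shortest ellipsoid semi-axis (≥ 1, 1 = isotropic),
and the principal axis is the longest-MIL eigenvector.  A seed jitters
each secant origin within its grid cell; results are bit-reproducible
per seed.

## Trabecular number (Tb.N)

Primary (direct) definition: the inverse mean distance between
trabecular mid-axes.  The bone phase is skeletonised, the skeleton is
removed from the total volume, and the largest-inscribed-sphere
transform of the remainder measures mid-axis spacing; `Tb.N` is the
inverse of its mean.  A plate-model fallback `1/(Tb.Th + Tb.Sp)` is
available behind a switch and is also used automatically when the
skeleton degenerates.

## Cortical metrics

`Ct.Th` is the mean local thickness of the cortex mask.  `Ct.Po` is the
pore fraction of the cortical shell: pores are the shell-envelope
voxels not occupied by cortex, so `Ct.Po = 100·pores/shell`.
Cortex/shell separation masks are inputs; automatic cortical
segmentation is out of scope.

## Reference alignment and twist (τ)

Bones are aligned by principal axes of their voxel-coordinate
covariance: the long axis maps to z, the medial–lateral (second) axis
to x.  Among the four proper-rotation sign choices, the pose closest to
the identity is selected — appropriate for scans acquired near the
reference orientation, which is the use case.  `align_to_reference`
returns the *pose* (canonical → observed); applying its inverse aligns
the bone.  τ = yaw(femur pose) − yaw(tibia pose) in intrinsic Z-Y-X
Euler angles, wrapped to (−180°, 180°].  Both the Euler order and the
femur-minus-tibia sign are recorded in the output metadata because τ is
meaningless without them.  Whole-joint metrics are computed in the
tibial reference frame; the volume is re-oriented only when the tibial
pose deviates from identity by more than 0.1°, avoiding gratuitous
nearest-neighbour resampling of already-aligned data.

## Landmarks, σ and ρ

A surface height map records, per XY column, the most distal (femur) or
most proximal (tibia) surface z; unoccupied columns are flagged, never
zero-filled.  Columns are split at a seed x (the averaged centre of
geometry of the 100 most distal femoral slices; fewer slices are used
with a warning on short stacks).  Per half, the landmark is the
centroid of all surface points within one voxel of that half's extreme
z; the notch (femur) or eminence (tibia) landmark is the centroid of
the points within one voxel of the maximum over the strip strictly
between the two minima.  If no interior maximum rises above the minima
the notch is reported missing ("notch not found").

σ for a compartment is the coronal-projection (XZ) angle between the +z
axis and the chord from the notch maximum to the compartment minimum,
in (0°, 90°].  This chord convention stands in for "average
inclination"; a surface-slope average is a conceivable alternative and
is deliberately *not* silently substituted.  Marginal osteophytes
displace the minima distally/peripherally and therefore reduce
(sharpen) σ.  ρ is the signed angle of the lateral→medial minima line
against the transverse plane, positive when the medial minimum is more
proximal; the sign is a package convention and is documented rather
than derivable.

## Joint space width (JSW)

Per compartment, JSW is the vertical (−z) distance from the condylar
bone-surface landmark to the highest tibial bone voxel in the same XY
column (nearest occupied column within one voxel if the exact column is
empty), bone surface to bone surface.  A switch allows including
cartilage surfaces instead.  JSW is translation-equivariant by
construction: shifting the femur by Δz changes both JSW values by
exactly Δz.

## Centre-of-mass vector (λ, α, β, γ)

`v = COM(femur) − COM(tibia)` with uniform-density voxel centroids;
λ = ‖v‖ and α, β, γ are the direction angles (arccos of direction
cosines against +x, +y, +z, each in [0°, 180°]).  The identity
`cos²α + cos²β + cos²γ = 1` holds to numerical precision and is used
as an output invariant.

## Virtual loading (χ, m)

The femur union (bone + cartilage, per the in-situ contact definition;
bone-only behind a switch) is translated down one voxel per step.  At
each step the per-compartment contact area is the number of XY columns
in which the displaced femur interval overlaps the tibia interval,
times `spacing²` — a projected-column area with a voxel-exact oracle.
Compartment membership of a column follows the tibial side of the
sagittal split plane.  χ is the displacement at first non-zero contact
area; m is the least-squares slope of area vs displacement over
[χ, χ + 10 steps] (window size recorded in the output; there is no
canonical window, 10 steps spans the near-linear onset for
condyle-scale curvatures).  A compartment that never contacts is
reported missing, not an error.  χ is emitted in both mm and µm to
remove unit ambiguity.

## Compartment split

The grid is partitioned at the sagittal plane through the notch x
(fallback: centre-of-mass x, with a warning).  A voxel column lying on
the plane within half a voxel is divided by its y-half as a tie-break
so that a mirror-symmetric joint splits into equal compartments.

## Reliability statistics

* **ICC(A,1)** — two-way mixed model, absolute agreement, single
  measures: `(MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`
  from the subjects × repeats ANOVA.  The 95% CI uses the F-based
  interval with a Satterthwaite denominator df.  Other ICC forms are
  rejected rather than silently substituted; a zero-variance table
  raises (the coefficient is undefined there, not 1).
* **Precision errors** — short-term precision in the densitometry
  convention: `PE(SD) = sqrt(Σ SD_i²/n)` with per-subject SD
  (denominator k−1), and `PE(%CV)` the RMS of per-subject %CV using
  each subject's own mean (undefined, not imputed, when a subject mean
  is ≤ 0).
* **Bland–Altman** — differences against means, limits of agreement
  with the normal quantile (1.96 at α = 0.05, not a t-quantile —
  documented choice), and a proportional-bias t-test on the regression
  of differences on means.
* **Pearson/linear regression** — R, R², least-squares coefficients and
  the two-sided p from the t-transform with n−2 df.
* Missing repeats are dropped listwise with a logged count, never
  imputed.

## Bone morphometry and contrast agents

Ionic contrast (Hexabrix-class) perfuses cortical pores and peripheral
trabeculae and corrupts Ct.Th, BS/BV and Tb.Th.  The pipeline and CLI
therefore refuse bone morphometry on volumes flagged
`contrast=hexabrix` unless explicitly forced; bone parameters should
come from non-contrast or inert-contrast scans.

## Phantoms and what passing tests mean

The phantoms provide analytic or exhaustively-counted ground truth,
never computed by the modules under test:

* plate (thickness/volume/box-surface in closed form), ball
  (4πr²/ 4πr³/3, χ = 1), trabecular block (thresholded smoothed
  Gaussian field; the threshold is an order statistic, so BV/TV is
  exact by construction; anisotropy truth is the correlation-length
  ordering — Tb.Th/Tb.Sp of a random field have no closed form and
  carry no truth claims);
* the joint phantom: two spherical condyles joined by a proximal bridge
  (forming the intercondylar notch) plus a long shaft; a tibial plateau
  with eminence ridge and long shaft; hemispherical cartilage shells
  and a cartilage slab of stated thickness; a constructed bone-to-bone
  gap; optionally a marginal hemispherical osteophyte bump whose
  protrusion lowers the condylar landmark.  Landmark positions, chord
  angles, JSW, χ, τ, the COM vector and the sphere-on-plane
  contact-area slope are all known in closed form.
* repeated-measures tables `x_ij = μ + b_i + e_ij` with known
  between/within variances (expected ICC = σ_b²/(σ_b² + σ_w²)).

Default phantom spacing is 0.05 mm — coarser than a small-animal
microCT acquisition (tens of µm) but fine enough that every structure
spans ≥ 6 voxels; a full joint phantom then builds and measures in
seconds.  The pipeline-determinism check runs at 0.1 mm for the same
reason.  Solid-geometry membership tests use a 1e-9 tolerance on
boundaries so nominally symmetric solids stay symmetric on the grid.

What the phantoms do **not** emulate: X-ray physics (beam hardening,
partial-volume blur, contrast diffusion), realistic trabecular
architecture (plates/rods), anatomical curvature of plateaus and
condyles, segmentation error, or scan–rescan repositioning.  Passing
the suite therefore demonstrates that the estimators recover known
geometry and statistics under the stated conventions — not that
segmentation or acquisition effects on real scans are small.

## Known limitations

* Landmark positions are voxel-quantised; angle errors grow with voxel
  size (≈1° per voxel of landmark error at the default geometry).
* The chord-based σ is one reading of "average inclination"; comparing
  absolute σ values across implementations requires matching the
  convention.
* Principal-axes alignment assumes a dominant long axis and a
  near-reference starting pose; strongly rotated or truncated bones
  need an external registration.
* Contact areas are projected column counts, not iso-surface patch
  areas; the two differ for steep contact faces (an iso-surface option
  is noted in the configuration).
* Conn.D clamps negative `1 − χ`; disconnected masks should be cleaned
  upstream.
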