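# Methods

## Scope and data model

All measurements operate on `LabeledVolume`: a 3D grid of non-negative
integer labels with strictly positive per-axis physical spacing (μm) and
an origin, under the voxel-centre convention — the physical position of
index `(i, j, k)` is `origin + (i, j, k) · spacing`. Every derived
quantity (length, volume, centre of mass, distance, transform) lives in
physical μm coordinates, so anisotropic voxels are handled throughout;
the one exception is topological thinning, which runs on the voxel grid
(a grid-topological operation) and is therefore an approximation for
strongly anisotropic data. The validation phantoms are isotropic.

## Synthetic phantoms

The package's validation data is generated, not deposited. The cochlear
duct is a tapering circular tube swept along a conical helico-spiral
with plan-view radius interpolating linearly in turn angle from
`base_radius` to `apex_radius`, height rising linearly (`pitch` per
turn), and lumen radius tapering linearly along arc length. The analytic
centerline length is the quadrature of the speed function

  |dP/dθ| = sqrt(r′² + r(θ)² + (pitch/2π)²),

evaluated with adaptive quadrature; for constant plan radius it reduces
to the closed-form helix arc length (agreement < 0.01%, tested).

**Voxelization.** A voxel belongs to the duct iff the distance from its
centre to the centerline is at most the local tube radius. This is
realised by stamping balls along a densely sampled centerline; the
sampling step is chosen so the sagitta error is below 5% of the voxel
size, making the stamped set indistinguishable from the exact distance
rule (checked against an independent KD-tree nearest-distance oracle).

**Blind ends.** An open curve's distance rule produces hemispherical
caps at the curve ends. The swept tube is therefore trimmed by one local
radius at each end so that the cap apexes coincide with the analytic
curve endpoints: the solid spans exactly the analytic arc length (the
scala media likewise ends blind), and the stored ground-truth volume is
the exact trimmed-tube-plus-caps volume

  V = π(s₂−s₁)(r₁² + r₁r₂ + r₂²)/3 + (2π/3)(r₁³ + r₂³).

The straight-cylinder helper instead clips flat ends, keeping the
classic `πr²L` closed form exact.

**Defaults as study conditions.** The default phantom is a 2.5-turn duct
with plan radius 2000 → 500 μm, 400 μm rise per turn, lumen radius
150 → 70 μm, at 10 μm isotropic voxels — a mid-gestation-scale geometry
(≈ 20 mm arc length, ≈ 0.04 μl/mm ratio; real specimens at comparable
stages are in the tens of millimetres and a few μl). Voxel spacing is
validated against a configurable range defaulting to 4.67–14.50 μm, the
resolution regime of fetal-temporal-bone micro-CT. The five vestibular
organs are spheres (radii 170–250 μm) in an anatomically plausible
compact cluster; sphere layouts and radii are free parameters. Tube
self-intersection (turn spacing < 2 × tube radius) and overlapping or
duct-touching blobs are rejected with explicit errors. Optional seeded
surface-voxel jitter emulates manual-segmentation roughness (default
off). Phantom generation is bit-reproducible given spec and seed.

What the phantoms do **not** emulate: scanner physics (noise, beam
hardening, partial volume), osmium contrast, real duct cross-section
shape (elliptic, locally irregular), or inter-rater segmentation
variability beyond uniform surface jitter. Passing tests therefore
demonstrate correctness of the measurement pipeline on ideal
segmentations, not robustness to acquisition artefacts.

## Mask conditioning

The conditioning recipe — resample ×2 (majority vote ≥ 0.5), grow 5,
smooth 3, shrink 5 — exists to heal thin breaks and smooth the surface
so thinning yields a branch-poor skeleton; volumes are always measured
on the raw label. Implementation choices:

- **Connectivity.** Grow/shrink use the 26-neighbour structuring element
  by default (the most isotropic unit ball); 6-connectivity is a config
  option.
- **Dilation pads the grid.** `grow` extends the array by n voxels per
  side (shifting the origin) so growth is never clipped by the array
  boundary; clipping was observed to leave flat faces that later stages
  turn into gross artefacts.
- **Contour smoothing** is a 3×3×3 mean filter re-thresholded at ≥ 0.5
  with replicated (nearest) borders, so an all-true grid is a fixed
  point. A step that empties the mask raises (structure too thin for the
  recipe).
- **Resampling origin bookkeeping.** Downsampling by f multiplies the
  spacing by f and shifts the origin by `spacing·(f−1)/2`, keeping
  voxel-centre physical coordinates consistent (round-trip centre-of-
  mass shift under one coarse voxel, tested).

The adjunction contracts (dilation extensive, erosion anti-extensive,
closing ⊇ identity, opening ⊆ identity) are verified property-style on
randomized masks for both connectivities, using physical-space
containment so grids of different extents compare correctly.

## Centerline extraction and length

Thinning uses scikit-image's 3D medial-axis thinning (Lee-style
6-subiteration). The contract is stated via properties — skeleton ⊆
mask, unit width on tubes, per-component connectivity preserved — rather
than exact voxel patterns, since any topology-preserving thinning is
acceptable. The skeleton becomes an undirected spatial graph (one node
per skeleton voxel at its physical centre, edges between 26-adjacent
voxels weighted by physical distance). "One centerline for one duct" is
interpreted as: restrict to the component with the largest total edge
length, then take the maximum-length simple path between degree-1 nodes
(weighted diameter, exact Dijkstra over all endpoint pairs with
deterministic sorted-node tie-breaks); side branches are pruned. A
component with no endpoints (pure cycle) is opened at its smallest node
with a warning.

**Line smoothing.** The extracted polyline is relaxed with simultaneous
(Jacobi) updates, endpoints fixed:

  xᵢ ← xᵢ + s·(midpoint(xᵢ₋₁, xᵢ₊₁) − xᵢ) + a·(xᵢ⁰ − xᵢ),

with defaults s = 0.85, a = 0.05, 200 iterations; xᵢ⁰ anchors to the
original input. The update is a convex combination for s + a ≤ 1, hence
stable; collinear input is an exact fixed point, and with a = 0 the
length decreases monotonically toward (but never below) the endpoint
chord — both tested. Smoothing runs after branch pruning; running it
before would differ only through the pruned side branches' influence on
junction neighbourhoods, a small systematic effect on absolute lengths.

**End extension.** Thinning retracts a tube's skeleton by roughly one
tube radius at each open end. After smoothing, each end is extended
along its local tangent (estimated ~2.5 voxels into the curve) in
quarter-voxel steps until it exits the conditioned mask (capped at 30
voxels). With the blind-end phantom convention above, this makes the
measured length converge to the analytic arc length: 0.56% error at
10 μm voxels falling to 0.02% at 5 μm on the standard spiral.

## Morphometry

Volume is exact integer counting times voxel volume — no smoothing, no
interpolation — and is invariant under relabeling and axis permutation.
Centres of mass are unweighted voxel-centre means (segmentations carry
no meaningful intensity weighting). Distances use full-resolution
volumes. Unit conventions: 1 μl = 10⁹ μm³, 1 mm = 10³ μm.

Trend fitting is closed-form OLS (normal equations); r² is defined as 0
when the response has zero total variance, keeping the decomposition
consistent for flat lines. Stage labels like `"GW19"` are parsed to
numeric weeks for the regression. The validation criterion for trend
recovery draws noisy linear schedules (8 stages, GW 11–25, σ = 10 μm)
and checks that the fitted slope falls within ±2 standard errors of the
scheduled slope in ≥ 95% of 100 replicates; the standard error uses the
schedule's **known** σ (`σ/√Sxx`, an exact normal pivot with 95.45%
nominal coverage). Using the regression-estimated standard error would
make the nominal coverage t₆-distributed (≈ 90.8%), i.e. the criterion
would be unattainable by construction at n = 8.

## Section-to-volume registration

The transform maps section pixel coordinates `(u·s, v·s, 0)` into
volume physical space; rotation is stored as a unit quaternion
(scalar-last) and parameterised as a rotation vector during
optimization, applied about the section centre so rotation and
translation stay decoupled. Labels are categorical, so the virtual
section uses nearest-neighbour sampling; out-of-volume pixels are
background. The objective is the mean Dice over the section's labels
(configurable); a label empty in both images scores 1.

The optimizer is local and derivative-free by design — the caller's
initial transform plays the role of the manual pre-alignment, and an
init with zero label overlap is rejected with instructions to pre-align
better. Because Dice is piecewise constant, a single Nelder–Mead run
stalls on plateaus; the search therefore restarts Nelder–Mead through a
fixed schedule of shrinking initial simplexes (6° / 6 voxels down to
0.12° / 0.12 voxels, 600 iterations per stage), which is deterministic
given init and options. If nothing improves on the init, the init is
returned with a warning; the best-so-far trace is non-decreasing.

The registration phantom uses three ellipsoids with distinct semi-axes
(stand-ins for the scala media / vestibuli / tympani masks) and a
ground-truth plane passing near all three centres but offset 130 μm
along the plane normal. The offset matters: a plane through the centres
makes out-of-plane tilt a second-order direction of the Dice objective
(tilt + compensating translation changes central cross-sections only
quadratically) and local search stalls; cutting each compartment
off-centre makes all six degrees of freedom first-order identifiable.
Under perturbations up to 10° and 10 voxels from the truth, ≥ 90% of
seeded runs recover the pose to < 1 voxel and < 1° with mean Dice
≥ 0.95 (typically Dice 1.000 and ~0.01°).

## I/O and configuration

NIfTI-1 is the canonical interchange format (spacing on the affine
diagonal, origin in the translation, values interpreted as μm with the
header unit set to micron). MetaImage round-trips anisotropic spacing;
TIFF stacks carry no reliable spacing and require an explicit override
(fail-fast rather than assuming 1 μm); DICOM series are read-only, with
mm-based spatial attributes scaled to μm. Non-integer voxel data is
rejected with a pointer to the labels-vs-grayscale mix-up. Centerlines
export as legacy-VTK polydata (one polyline cell) and CSV
(`x_um,y_um,z_um`); transforms as JSON (quaternion + translation). The
pipeline configuration round-trips losslessly through YAML; each
default parameter is defined in exactly one dataclass.

## Problem sizes and determinism

The validation suite uses the standard 2.5-turn phantom at 10 μm voxels
(~23M-voxel grid) plus a halved-spacing run at 5 μm for the convergence
check, 100 randomized vestibular phantoms for distance recovery, 100
randomized masks for the morphology contracts, 20 seeded perturbations
for registration recovery and 100 replicates for trend coverage — sizes
chosen so the whole validation runs in a few minutes on one CPU while
every recovery margin stays an order of magnitude clear of its bound.
Everything downstream of phantom generation is deterministic: repeated
runs on identical inputs produce byte-identical outputs (tested at the
file level), and phantom generation itself is bit-reproducible given
spec and seed.

## Known limitations

- Absolute specimen values from real fetal material (e.g. duct lengths
  of ~31–34 mm and volumes of ~3.5–5.6 μl at late stages) are not
  reproduced here: no specimen scans ship with the package, and the
  phantom defaults are a scaled, idealised geometry.
- Thinning on strongly anisotropic grids is approximate (see above);
  resample to near-isotropic voxels first.
- The duct cross-section is circular with a linear taper by
  construction; real ducts are elliptic and locally irregular, which
  perturbs the volume/length-ratio interpretation more than the length.
- Registration is rigid-only (no scaling, no deformation) and local:
  it refines a manual pre-alignment and will not recover from
  initialisations outside the overlap basin.
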