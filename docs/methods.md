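# Methods

`cochlect` re-implements, as a tested library, the analysis chain used for
contrast-enhanced microCT (CECT) of human cochleae: tomographic simulation
with projection-completion metal-artifact reduction, reference-material
grey-value normalization, a cylindrical cochlear coordinate system, 3D
morphometry, and pre/post electrode-insertion trauma quantification.  No
cadaveric scan data are distributed, so every stage is exercised on a
synthetic cochlear phantom whose ground truth is known analytically.  This
note records the models, the parameters that matter, and the design choices
made where the underlying procedures were originally manual or proprietary.

## The synthetic cochlea

The phantom is a spiral of `turns` revolutions (default 2.8, within the
human range of 2.2–2.9).  The centerline radius decays linearly with
unwrapped angle θ, `r(θ) = r₀(1 − d·θ/360°)` with basal radius `r₀`
(default 2.2 mm) and per-turn decay `d` (default 0.26, giving a realistic
basal-to-apical radius ratio of ~3.7:1 at 2.8 turns), and rises at a
constant axial pitch (default 1.0 mm/turn).  An optional `cos²θ` in-plane
elongation of the radius lets dimension-targeted phantoms reproduce the
clinical observation that cochlear length exceeds width by ~2 mm; the
modulation leaves the ground-truth azimuth equal to the spiral parameter,
so angular measurements are unaffected.  Left and right ears are mirror
images via a handedness flag.

The scalae are circular tubes around the centerline — scala tympani below
the partition plane, scala vestibuli above, scala media as a small duct in
between — and the membranes (round window membrane, basilar membrane,
Reissner's membrane), bony laminae (osseous spiral lamina, secondary spiral
lamina, round window arch), spiral ligament, and Rosenthal's canal are
schematic regions in the local tube cross-section `(u, w)` (radial and
axial offsets from the centerline).  Cross-section placements are
schematic: they preserve the topology and the measurable quantities (turn
count, angular ranges, centerline lengths, volumes, membrane thicknesses),
not cellular microanatomy.  The RWM is a cap across the scala tympani
entrance, centered on the 0° reference angle; the round window arch is a
dense bony shell along its upper rim (ending well before 90°); the
secondary spiral lamina is a porous ridge on the outer wall ending at a
configurable angle (default 572°, the published extent).  The default
basilar membrane is 50 µm so that it spans at least one voxel at the
35 µm desk resolution; sub-resolution membranes (the real BM is ~25 µm)
are exercised at 18.9 µm voxels where the trauma report must flag their
volumes as unreliable.

Rasterization assigns each voxel to the nearest turn's cross-section and
then classifies it by precedence (membranes and laminae before fluid,
fluid before capsule).  Generation fails loudly, naming the structure, if
any configured structure would be thinner than one voxel.  The ground-truth
table (turn count, angular extents, centerline arc length, tube volumes,
outer dimensions) is computed from the spec's closed forms, never from the
raster.  Two reference materials are included: the cortical bone of the
capsule and a parafilm-analog block in a grid corner.

Attenuation defaults (1/mm): fluid 0.02, parafilm 0.05, stained soft
tissue 0.12, porous SSL bone 0.18, cortical bone/capsule 0.30, electrode
metal 3.0.  The ordering mirrors the contrast relations of a stained scan;
the absolute values are arbitrary.  A small Gaussian texture
(σ = 0.005/mm, seeded) makes contrast-to-noise finite.

**Staining front.**  Soft-tissue contrast uptake advances from base to apex
at `rate` turns/day (default 1.0, the observed diffusion speed).  Uptake is
a logistic front in unwrapped angle, `σ((rate·t·360° − θ)/w)` with softness
`w` = 30°, and the RWM — in direct contact with the bath — is fully stained
from 3 h onward.  A voxel counts as stained at uptake ≥ 0.5 (front passed).
At this rate a 2.8-turn cochlea is fully stained on day 3 and not on day 2.
The model reproduces the qualitative time-course (fronts, full staining
after three days); it does not model diffusion physics, concentration
gradients, or precipitation.

**Electrode and lesions.**  The electrode is a tube (default radius 90 µm)
traced along the scala tympani centerline from just past the RWM to a
requested angular depth; it only overwrites open fluid, so an atraumatic
insertion changes no anatomy label.  Lesions are declared per structure and
angular range: `fracture`/`tear` remove the voxels (they become scala
tympani fluid); `elevation`/`deformation` displace them axially by two
voxels into fluid or loose filler; `scala-vestibuli translocation` reroutes
the electrode into the scala vestibuli through a basilar-membrane rupture.
The generator books the exact affected voxel sets, giving the trauma module
an exact round-trip target.

## Tomography and metal-artifact reduction

Acquisition is modeled slice-wise in parallel-beam 2D geometry — a
deliberate specialization of the cone-beam scanner, since projection
completion is geometry-agnostic and parallel-beam keeps the simulation
exactly testable at desk scale.  The projector integrates each ray by
Joseph-style bilinear sampling at voxel-size steps; the backprojector is
its exact algebraic adjoint (⟨Ax, y⟩ = ⟨x, Aᵀy⟩ to machine precision),
verified against scikit-image's `radon` as an independent oracle.
Reconstruction is filtered backprojection with a Hann-apodized ramp filter
(cutoff configurable); 360 views over 360° by default.  Reconstruction
RMSE on smooth phantoms is under 2% of the dynamic range at that sampling,
and decreases monotonically with view count.

Metal-artifact reduction follows the projection-completion scheme: an
initial reconstruction; metal segmentation by thresholding (the threshold
must exceed the volume median — refusing to call half the anatomy metal);
forward projection of the binary metal image to find every sinogram pixel
with nonzero metal path length (ε = 1e-9 kills numerical dust); replacement
of those pixels by 1D linear interpolation between the nearest unaffected
pixels along each detector row; and a final reconstruction.  Shadows
touching a detector edge are extended as a constant from the nearest clean
pixel; a fully occluded row raises an error rather than guessing (possible
only with a truncating detector).  Unshadowed pixels are bit-identical, so
the chain is exactly the identity on metal-free data.  Metal voxels are
re-inserted from the initial reconstruction by default so the electrode
remains visible; a flag disables this.  On the seeded electrode slice
phantom the streak metric (grey SD in a 5–15 voxel annulus around metal)
drops to ~0.12× the uncorrected value, well below the required 0.5×.

## Grey-value conditioning and visibility grading

Windowing maps the [0.1, 99.9] percentile range (hot-pixel resistant) to
8 bits, monotonically.  Cross-day normalization is the unique two-point
affine map sending the mean grey of the capsule bone and the parafilm
analog to fixed targets (defaults 200 and 40 on the 8-bit scale); it is
idempotent to one grey level and closes over scan-to-scan gain changes.
Downsampling is block-mean binning (6.3 µm × 3 → 18.9 µm, the segmentation
resolution).  Reference contrast is the CNR |mean(A) − mean(B)| / pooled SD.

Visibility grading (0 = not visible, 1 = partially visible on some slices,
2 = partially on all, 3 = entirely on all) is an automated proxy for a
human grader, not a claim of equivalence: a structure voxel is visible when
its grey exceeds the local fluid mean by a contrast threshold (3× the
texture σ by default); "slices" are 10° transmodiolar sectors; a sector is
"entire" at ≥95% visible voxels and "partial" at ≥5% (the floor keeps
isolated noise voxels from counting as visibility).  Grades are
re-derivable from the stored per-sector fractions and are non-decreasing
in submersion time on the staining simulation.

## Cochlear coordinate frame

The frame follows the clinical consensus convention: rotation axis through
the modiolus, rotation plane through the basal turn, 0° at the center of
the round window, angles increasing base→apex for both ears and unwrapping
beyond 360° across turns.  Because the original reorientation was manual,
the automated fit is this package's own procedure, validated on phantoms:

1. a 3D thinning skeleton of the lumen complex is marched from the RWM
   outward (longest geodesic path);
2. the modiolar axis direction comes from a helix fit to that centerline —
   linear axial rise and linearly decaying radius about a tiltable axis —
   which stays well conditioned from sub-turn arcs to full spirals (a plain
   plane-normal fit is biased by the helical rise);
3. the in-plane axis position is refined twice: a decaying-spiral model
   with optional in-plane elongation on the centerline, then per-10°-bin
   medians/centroids of the fluid voxels (symmetric around the true
   centerline, pinning the center to a fraction of a voxel — sub-degree
   angular accuracy at the small apical radius requires this);
4. the 0° direction points to the RWM centroid; handedness is the rotation
   sense of the marched centerline.

Unwrapping assigns each point the turn whose cross-section centroid —
tabulated as per-bin medians of height and radius along the centerline,
linearly extrapolated past the skeleton's eroded ends — is nearest in
(Δz, Δρ); per-voxel azimuth alone cannot separate turns.  A continuity
filter drops reference bins that sit about one pitch off the global axial
rise (they arise from turn-misassigned voxels and otherwise act as
attractors).  Structures are assumed to begin within the first turn (true
for all measured structures here).  On the default phantom the recovered
axis is within 0.1° of truth, the zero direction within 0.1°, and unwrapped
angles within ~2° for all structures (capsule voxels midway between turns
are intrinsically ambiguous and excluded from angular measurements).

Turn count is the maximal unwrapped angle over the lumen voxels divided by
360, reported to 0.1 turns (voxels rather than the bare skeleton, whose
endpoints erode by about one tube radius).  Cochlear length is the largest
basal-plane extent along the axis→RWM line, width the in-plane
perpendicular extent, height the extent along the axis; extents are
inclusive (max − min + one voxel).  These are fixed operational conventions
standing in for the original two-click measurements.

## Morphometry

Structure volume is voxel count × voxel volume (an empty structure is an
error, not zero); volumes are additive over the label partition by
construction.  Centerline length skeletonizes the mask, finds the longest
geodesic with 26-neighbour steps, and reports the polyline length of the
ordered path after a 5-point moving-average smoothing — the raw chamfer
metric overestimates digitized smooth curves by several percent, and
smoothing is the standard debias; accuracy on helices of known arc length
is ~1%.  Disconnected masks are measured per component with the longest
reported alongside the component count.

Local thickness uses the maximal-inscribed-sphere formulation: thickness
at a voxel is the diameter of the largest sphere inside the mask containing
it.  Sphere radii are quantized upward to multiples of `step/2` voxels
(default step 2, the conventional setting at segmentation resolution), and
a sphere of quantized radius R spans the odd diameter 2R−1 voxels.
Representable diameters are therefore spaced `step` voxels apart, a slab of
t voxels reads exactly t (the 2·EDT − 1 identity), and thickness is bounded
below by 2·EDT − 1 everywhere.  The map is computed by painting spheres
from the largest radius class down (one distance transform per class); an
exhaustive per-center oracle in the test suite confirms exact agreement up
to the shared quantization.  Thickness histograms report the percentage of
mask voxels per bin — voxel-weighted, a documented choice since
area-weighting is a plausible alternative — with exact midpoints
((lo+hi)/2); at 18.9 µm and step 2 the bin width is 0.0378 mm, matching
published bin edges such as 0.057–0.095 mm (midpoint 0.076 mm).

## Trauma quantification

Pre- and post-insertion label volumes on the same grid (guaranteed by the
phantom; registration of independently acquired scans is out of scope) are
differenced per structure.  Electrode-occupied voxels in an open scala are
not trauma — intrascalar position is not damage — and a fluid compartment
occupied by a displaced neighbouring structure is likewise not counted.
For solid structures the trauma mask is the symmetric label difference, so
removals and displacements both register; whether a structure was removed
or displaced is decided by whether it reappears near where it vanished
(gained ≥ 0.3 × lost).  The per-structure report gives trauma volume, the
percentage of the pre-insertion structure volume (voxel-weighted), the
unwrapped angular range, bounding dimensions, centerline length, an
Eshraghi grade via the descriptor vocabulary (0 none; 1 BM elevation; 2 BM
rupture; 3 electrode in scala vestibuli; 4 OSL/modiolus fracture or
SL/stria tear), and a volume-unreliable flag when the structure's true
thickness is below two segmentation voxels.  The composite grade is the
maximum over structures (the scale is ordinal).  Insertion depth is the
maximal unwrapped angle over electrode voxels.  Round-trip accuracy against
the generator's bookkeeping: volumes within 2%, fractions within 0.2
percentage points, angular ranges within 3°, grades exact.

## Problem sizes and reproducibility

Desk-scale analyses run on a 192³ grid at 35 µm (whole cochlea) with a
high-resolution 6.3 µm mode for membrane-thickness work on cropped
patches — the package's standard working sizes; the dimension-cohort
phantoms use 256×256×128 at 48 µm.  All randomness flows from a single
seed (phantom texture, projection noise); regenerating with the same spec
and seed is bit-identical, and an end-to-end run writes a manifest whose
hash is stable across reruns.

## Known limitations

- Parallel-beam 2D geometry, monochromatic rays, no scatter, beam
  hardening, or detector response; the published cone-beam preprocessing
  (vendor filters) is out of scope.
- The phantom's cross-sections are schematic; passing recovery tests shows
  the measurement chain is correct on geometry with known truth, not that
  it handles segmentation noise, anisotropic voxels, or real anatomical
  variability.
- The visibility grading automates a human judgement; its thresholds are
  configuration, not a validated observer model.
- Unwrapping assumes a single spiral whose structures start in the first
  turn; frames for malformed cochleae are out of scope.
- Deformation trauma is counted by symmetric difference, which double-counts
  tissue that moved rather than vanished relative to a pure-removal reading;
  the convention is stated in the report header.
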