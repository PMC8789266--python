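# Methods

`dentmark` implements a fully automated landmark-recognition pipeline for
3D dental arch scans, plus modified Huddart–Bodenham (MHB) occlusal
scoring of an occlusion-registered maxillary/mandibular pair. This note
documents the models, the parameters that matter, the synthetic data the
package is validated on, and the numerical choices made where the design
was genuinely open.

## Recognition pipeline

An arch arrives as a triangle mesh (STL, mm). The stages run in a fixed
order; each consumes only the outputs of earlier stages.

**Orientation.** The anatomical frame comes from PCA of the vertex cloud:
an arch is wider (transverse) than long (antero-posterior) and longer than
tall (occlusal), so the eigenvalue order fixes the axes up to sign. Signs
are resolved by two shape heuristics: the crowns taper, so the decile
height slab with the smaller convex-hull footprint is "up" (ratios within
5% of 1 leave the provisional sign and emit a warning); and the arch
parabola opens posteriorly, so the sign of the quadratic coefficient of an
AP-on-T fit to the crown-level vertices fixes anterior. The transverse
axis then restores right-handedness (T × AP = O). The vertical direction
matters most, so after a coarse peak pass the occlusal axis is refined to
the total-least-squares plane normal through the tooth tips and the
horizontal axes are re-orthogonalized — exactly one refinement iteration.

**Peak points.** Candidate cusp tips are local maxima of occlusal height
within 6 mm of the global maximum (deep enough for worn or partially
erupted teeth, shallow enough to exclude the base). The neighbourhood is
the 2-ring of the vertex: 1-ring maxima are noise-sensitive and
radius-based neighbourhoods vary with mesh density. A vertex is a peak
when it is ≥ all ring neighbours and > at least one; flat plateaus keep
the lowest-index representative. Duplicate and non-tooth peaks are allowed
here — later stages filter them.

**Tooth partition.** Signed curvature is the dihedral angle across each
interior edge, positive for convex folds, negative in creases; boundary
and non-manifold edges get 0. The tooth–gingiva junction is a pronounced
concave crease, so a breadth-first face flood from each peak refuses to
cross edges at or below `stop_curvature` (default −0.6 rad). Crossing is
also refused when *both endpoints* of an edge lie on crease edges: on
scan-density triangulations a fold running diagonally to the sampling
splits into alternating edge rows, and without this closure the flood
slips through one-edge gaps (we confirmed this by tracing escape paths on
synthetic arches — every leak threaded between two flagged edges that
shared only vertices). The closure makes the flagged crease an edge cut
without touching the curvature values or the threshold.

A flood that never meets a crease would swallow the whole model, so any
flood that tries to enter a face more than `max_travel` (12 mm permanent,
9 mm deciduous — "a tooth's width") horizontally from its seed is capped
and the blob is flagged *spilled*; spilled blobs are discarded. The
jawline — a quadratic AP = aT² + bT + c — is fitted to the horizontal
positions of the non-spilled peaks. Blobs sharing faces are merged
(several cusps of one tooth), and disjoint blobs closer than
`merge_distance` (half of `max_travel`) along the jawline are merged
(buccal/lingual halves of a molar). A blob's arch position is the arc
length along the jawline of the *projection* of its highest peak:
projection, rather than the peak's own transverse coordinate, keeps the
position of a buccally or lingually displaced tooth (crossbite) stable.

**Tooth assignment.** Each merged blob gets five features: surface area,
mesiodistal width (extent along the local jawline tangent), buccolingual
width (horizontal extent across it), crown height (occlusal extent) and
distinct peak count (peaks closer than 2.5 mm to a higher kept peak are
duplicates of the same cusp and count once). Features are compared with a
training set of labelled examples, side-collapsed (left/right share
statistics, the features are mirror-invariant), as a sum of squared
z-scores with a diagonal covariance. Standard deviations are floored at
max(1e-3, 5% of the mean; 0.75 for peak count) so a single discrete
feature can never dominate.

Labelling is a dynamic program over monotone alignments of the ordered
blobs onto the arch template (MMMPPCIIIICPPMMM permanent, mmciiiicmm
deciduous): match a blob to a slot (its mismatch cost), skip a slot
(missing tooth, `gap_penalty` = 6), discard a blob (non-tooth residue,
`discard_penalty` = 9), or spend two consecutive blobs on one molar slot
via its mesial/distal half-types (e.g. UR6.0/UR6.1). The penalties are in
squared-z units: a gap beats any worse-than-2.4σ fit. Ties break toward
fewer discards, then toward matching as early as possible. Blob order is
anatomical (patient-right → patient-left): patient-right is
anterior × body-up, where body-up is the occlusal axis for a mandibular
arch and its opposite for a maxillary arch, whose occlusal surface faces
down — this is what lets one template serve both jaws.

**Landmarks.** Incisors and canines take their highest peak; premolars and
molars take the peak with the largest buccal offset from the jawline
(falling back to the highest peak), because MHB measures at the buccal
cusp. Ties break toward the lowest vertex index.

## MHB scoring

Both arches must share one coordinate frame (intra-oral scanners register
occlusion at acquisition). A natural cubic spline, parameterized by chord
length, interpolates the ordered mandibular landmarks; a total-least-
squares plane through the same landmarks is the horizontal reference. For
each scored maxillary tooth (positions 1–6 per quadrant permanent — at
most 12; all 10 deciduous), the closest spline point to the landmark is
found by dense sampling at 0.05 mm plus bounded local refinement (robust
against multiple local minima on a curved arch); the landmark-to-curve
vector is projected into the reference plane and signed along the local
buccal direction (perpendicular to the curve tangent in the plane,
positive away from the arch centroid).

The ordinal mapping is a configurable monotone step function; defaults:
buccal segment d ≥ +1 → 0, −1 ≤ d < 1 → −1, else −2; labial segment
d ≥ +6 → +1, +1 ≤ d < 6 → 0, −1 ≤ d < 1 → −1, −3 ≤ d < −1 → −2, else −3.
Canines use the labial mapping (configurable). The arch total is the sum
of per-tooth scores; teeth missing from either arch are reported unscored
with a reason.

## Synthetic arches

Clinical scans cannot ship, so validation runs on generated arches with
exact ground truth. An implicit field — the union of a gingival base slab
following the quadratic jawline (y = −kx², k = 0.045) and per-tooth
crown primitives — is surfaced by marching cubes (default cell 0.4 mm,
chosen so a full arch stays near 200k faces and a twenty-arch evaluation
runs in minutes). A crown is a rounded box with a uniform 1.7 mm absolute
overhang above its neck (the anatomical "height of contour"; an absolute
inset gives small incisors as sharp a junction crease as molars) carrying
1 (incisor/canine), 2 (premolar) or 4 (molar) spherical-cap cusps, buccal
cusps slightly higher than lingual and mesial higher than distal so the
highest peak is deterministic. Mesiodistal widths: permanent
I1 8.5, I2 6.5, C 7.5, P 7.0, M 10.5 mm; deciduous scaled ×0.8; the full
dimension table is chosen so mean surface areas order
molar > premolar > canine ≥ incisor.

Teeth are placed sequentially round the jawline by collision: the rotated
crown footprint advances until it clears its neighbour by 0.9 mm (plain
arc spacing would make anterior crowns, which rotate tens of degrees
between neighbours on the tightly curved front, collide lingually). The
central incisors are separated by a 1.8 mm diastema. Surface noise is
*spatially correlated*: iid per-vertex amplitudes are diffused over the
vertex graph (3 averaging passes, correlation ≈ 1 mm), rescaled to σ
(default 0.05 mm) and applied along vertex normals. This emulates scanner
waviness; iid noise at 0.4 mm vertex spacing is not a realistic scanner
error model — it randomizes every dihedral angle and no curvature-based
segmentation (ours or any other) survives it.

Ground truth records per tooth: the Palmer label, the face mask of the
exposed crown (faces near the tooth field above the gingiva), analytic
cusp apex positions with buccal/lingual labels, and — for occluded pairs —
the intended transverse displacement of each maxillary tooth, realized as
an offset along the local buccal normal relative to the shared jawline.
The maxillary member of a pair is mirrored crown-down above the mandibular
arch with a 2 mm tip gap. Everything is deterministic given the seed.

The default training set ships as a CSV derived from 24 generated arches
(12 permanent + 12 deciduous, global size jitter σ = 6%) using the truth
masks as blobs and splitting molars at the crown centre into
mesial/distal halves so half-molar types are trainable. `dentmark train`
regenerates it.

**What passing on synthetic arches does and does not show.** The
generator reproduces the geometric premises the pipeline relies on —
taller-than-wide proportions, per-tooth creases, cusp-count and size
separation between types, scanner-scale smooth noise, missing teeth and
transverse displacements. It does not reproduce occlusal fissure
patterns, gingival recession, crowding with overlapping contacts, cleft
palate morphology, scan holes, or the inter-patient variability of a real
cohort; the published per-tooth error rates on clinical scans (~80% OK)
should therefore not be expected to match the near-perfect synthetic
rates, which bound the method's behaviour only under its own assumptions.

## Numerical choices and degenerate inputs

* Vertex merge tolerance 1e-6 mm at load; degenerate faces dropped.
* Non-manifold edges tolerated; traversals treat them as boundaries.
* PCA requires rank-3 covariance, otherwise a degeneracy error; occlusal
  refinement with <3 or collinear peaks is skipped, keeping the prior
  frame.
* The spline closest-point search samples at 0.05 mm and refines to
  1e-7 mm; displacement of a landmark exactly on the curve is 0 to 1e-6.
* Geometric-mean confidence intervals come from a normal fit to log
  distances (CI = exp(mean ± 1.96·SE)); zero distances are floored at
  1e-6 mm before the log. This lognormal construction is the standard
  treatment for positive error magnitudes.
* A predicted blob "finds" a truth tooth when it contains faces within
  1 mm of the truth apex or overlaps the truth mask with Jaccard ≥ 0.3.

## Problem sizes used in the shipped evaluations

The test suite and `scripts/acceptance.py` evaluate: 20 single arches
(seeds alternating jaws) for the per-tooth OK rate and landmark error; 5
occluded pairs (≈60 scored teeth) for MHB ordinal agreement; 200
lognormal replicates of n = 400 for CI coverage; 200 random ≤6-blob
instances for DP-vs-enumeration equality. These sizes keep a full run in
a few minutes while leaving the binomial margins of the 95% criteria
meaningful.

## Known limitations

* Mixed dentition is unsupported (the template constraint is per
  dentition).
* First-vs-second premolar discrimination rests entirely on the training
  spread; with the synthetic training set they are near-identical classes
  and are separated mostly by arch position.
* The spill rule assumes a roughly convex arch; a severely rotated tooth
  whose crease is broken (heavy wear) will partition into its neighbour
  or spill.
* MHB breakpoints in the literature vary by author; the defaults here are
  a configuration, not a claim about any one clinical protocol.
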