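# Methods

`flymuscle` quantifies the remodelling of persistent larval abdominal
muscles (DIOMs — dorsal internal oblique muscles) during *Drosophila*
metamorphosis from two-channel time-lapse stacks: the green channel labels
the muscle cytoplasm, the red channel the nuclei.  This note documents the
models, parameters and numerical choices behind each stage, what the
synthetic phantoms do and do not emulate, and the known limitations.

## Reference frames

Animals are compared in a common frame.  Spatially, the experimenter
annotates the left–right symmetry midline and the anterior end; the stack
is rotated so the anterior→posterior axis runs horizontally, left to
right.  Temporally, the onset of head eversion (HE, the prepupal→pupal
transition ~12 h after puparium formation) defines t = 0; frame *i* maps to
`(i − he_frame) · frame_interval / 60` hours AHE (after head eversion).
Frames recorded before head eversion carry negative hours; the inverse
mapping rounds to the nearest frame, ties toward the later frame.  Neither
the midline nor the HE frame is auto-detected — both are annotation
records, mirroring how they are determined in practice (visually, from the
pupa's anatomy and the eversion event).

Images are resampled bilinearly on an enlarged canvas (no cropping; the
offset is part of the exposed affine).  All geometry — seed polygons, ROI
boundaries, the midline — is transformed with the exact affine instead,
so measurements are never biased by grey-value interpolation.  Right-angle
rotations land on the pixel grid and are exact.  Coordinates everywhere
are 0-based pixel-centre, x rightward, y downward; angles are CCW-positive
against +x in that convention.

## Seeded level-set segmentation

Automatic fiber detection is unreliable in early pupae: histolysis of the
obsolete muscles fills the field with bright debris.  Segmentation is
therefore seeded — a polygon drawn around one fiber — and the contour
evolves **inward only** from the seed boundary.  The front moves with a
morphological scheme driven by the geodesic edge-stopping function

    g = 1 / (1 + grey_weight · |∇(G_σ ∗ I)|)

with one erosion per iteration wherever `g > 0.15` (no edge underfoot), a
gradient-advection step that pins the front to the gradient ridge, and
`curvature_weight` passes of the morphological curvature operator
(alternating sup-inf/inf-sup over four line elements).  Monotonicity is
enforced: a pixel once removed is never re-added, which guarantees
containment in the seed and makes convergence well defined (the update is
a shrinking sequence).  The loop stops when two consecutive iterations
each change less than `convergence_tol` of the seed area, or at
`max_iterations`.  A contour that vanishes (nothing to stop on) raises a
failure signal and the caller falls back to the manually drawn polygon.

Defaults: `edge_sigma` 2 px, `grey_weight` 1.0, `curvature_weight` 1.0
(one smoothing pass), `max_iterations` 500, `convergence_tol` 1e-4, edge
stop threshold 0.15.  With 8-bit images and fiber/background contrast of
~190 grey levels these place the stopping band within ~4 px of the edge
and let advection close the remainder; on synthetic fibers the converged
contour overlaps truth with Jaccard ≥ 0.99.

Rasterisation is even-odd at pixel centres, boundary-inclusive;
8-connectivity for components.  Nuclear clusters are found by Otsu
thresholding of the red-channel histogram *restricted to each muscle ROI*
(threshold maximising between-class variance; lowest maximiser on ties;
pixels ≥ threshold are foreground), followed by 8-connected labelling with
a 4-px minimum area to suppress shot noise.  Individual nuclei are not
separated — at 10× they are not resolvable — so regions represent nuclear
clusters.

## Morphometry

Ten features per ROI; µm-valued ones use the acquisition pixel size
(1.25 µm at the reference magnification).

The skeleton is a thinned medial axis with spur branches pruned up to the
local maximum half-width + 2 px — on a blunt-ended fiber this removes the
cap/corner artefacts while leaving the main axis intact.  **Average
diameter** is the mean, over every pixel of the skeleton's longest path,
of the chord perpendicular to the local tangent, marched in 0.5-px steps
to the first background sample on each side, minus 1 px (the sample grid
overshoots the true contour by ~half a pixel per side).  This is a denser,
deterministic version of the manual protocol of measuring widths
perpendicular to the medial axis at a handful of points.  Near-round masks
with no usable tangent fall back to `2·EDT − 1` at the skeleton.

**Length** is the geodesic length of the longest skeleton path with two
numerical corrections: the path is chord-subsampled every 4 pixels (a
per-pixel 8-connected sum overestimates oblique straight fibers by up to
+7%), and each end is extended along its tangent while the distance
transform stays at the endpoint's value (thinning stops a few pixels short
of the medial axis's true endpoints on rounded fiber ends).  Length is
thus the medial-axis length — for a capsule of tip-to-tip extent L and
width w, that is L − w.

The remaining features follow regionprops-style definitions: **area** =
pixel count · px²; **circularity** = 4πA/P² with the perimeter taken from
the marching-squares boundary polygon smoothed by a 5-point circular
moving average (the raw sub-pixel contour overestimates smooth perimeters
by several percent); moment-equivalent ellipse axes (4·√eigenvalue of the
second central moments) give **elongation** = (major−minor)/major,
**orientation** ∈ (−90°, 90°], **roundness** = 4A/(π·major²) and **aspect
ratio** = major/minor (∞ sentinel for collinear masks); **extent** =
A / bounding-box area; **solidity** = A divided by the number of pixel
centres inside the convex hull of the mask's pixel centres — a discrete
hull area commensurate with the pixel-count numerator, so convex digital
shapes score ~1 rather than the systematic deficit a filled hull image
produces.  Dimensionless features are scale-free; scaling the pixel size
by k scales diameter and length by k and area by k².

## Tracking and annotation

Fibers move little between 30-minute frames.  Correspondences between
adjacent frames are nearest-neighbour matches on ROI centroids, gated by a
maximum displacement D estimated empirically as twice the largest
per-frame movement observed (in phantoms, read off the ground truth).
Candidate pairs are taken greedily in ascending distance — deterministic
and near-optimal at these fiber densities; ties break on the lower ROI id.
Links chain into tracks; a broken link starts a new track.  Splits and
merges are not modelled (pupal muscles neither divide nor fuse in this
window), and gaps longer than one frame are not closed.

Annotations follow the four-criterion nomenclature (cell type DEOM/DIOM,
body part, abdominal segment 1–8, lateral side) and propagate along a
track; conflicting existing annotations are reported, never overwritten.
The lateral side comes from the sign of the cross product of the midline
direction with the centroid offset — in a registered dorsal view
(anterior left, y down) the animal's left side is at smaller y; points on
the midline are assigned "right".

## Storage

A single-file SQLite database holds two table groups: metadata (stacks
with the identity quadruple `stack_name` + (`stock_id`,
`acquisition_date`, `sample_location`), reference frames, environment
readings) and segmentation (ROIs, nuclear regions, features, tracks).
Polygons are JSON vertex arrays and masks JSON run-length encodings —
queryable and diffable rather than opaque blobs.  Pixel data never enter
the database; only file paths relative to a root folder.  Foreign keys are
enforced; deleting a stack with dependants is refused unless cascading is
requested; a schema version tag guards against opening stores written by
newer versions.  Features are stored as SQL REALs (IEEE doubles), so a
save/reload round-trips feature tables bit-for-bit.

## Population statistics

Protocol: ~10 animals per genotype, fibers sampled on a 5-hour grid, one
muscle per hemisegment, giving 10–20 muscles per genotype and time point.
Per grid point each animal contributes its nearest frame within half the
grid step; pooled values are summarised by the median and the 25th/75th
percentiles (linear-interpolation definition — definitions differ between
tools, so this is fixed and documented).  Left/right muscles of one
animal are pooled as independent samples, as the protocol's counts imply;
this is a known pseudo-replication caveat.

Genotypes are compared per time point with the two-sided Mann-Whitney U
test (U = min(U₁, U₂) from midrank sums): populations are small and their
distributions unknown, so a rank test is appropriate.  For tie-free
samples with min(n₁, n₂) ≤ 8 the p-value is exact by full enumeration of
all C(n₁+n₂, n₁) labelings; otherwise the normal approximation with tie
and continuity corrections is used.  Significance is displayed as
−log₁₀(p) against a dotted 0.01 line.  p-values are *not* corrected across
time points — the per-timepoint raw-p display is the intended analysis —
but a Bonferroni flag exists (default off).  Grid points with fewer than
two values on either side are flagged missing rather than tested.

## Synthetic phantoms

The generator renders what every stage needs to be testable without real
data: anti-aliased capsules (a rectangle with semicircular caps) for
fibers, Gaussian blobs riding inside each fiber for nuclei, random small
blobs before HE + ~5 h for histolysis debris, and additive Gaussian noise
(default sd 3 grey levels on 8-bit frames).  Capsules are the deliberate
choice because a constant-width body makes skeleton-based diameter and
medial-axis length analytic.  All randomness flows from a single spec
seed.  Fibers must stay disjoint; overlapping specs are rejected.

Default study conditions: 1.25 µm pixels, 30-minute frame interval, 240
frames with head eversion at frame 24, fiber orientations within ±12° of
the AP axis, 4 nuclei per fiber, slow sinusoidal drift plus a small random
walk (per-frame displacement well under D/2).  Genotype scenarios encode
the qualitative time profiles of the atrophy phenotypes: *control* — 90 µm
at head eversion, linear atrophy to 30 µm at 50 h AHE, then plateau;
*enhanced* (Tor-silencing-like) — thinner throughout, atrophy prolonged to
45 h down to 20 µm; *suppressed* (Atg9-silencing-like) — identical to
control until 30 h AHE, then recovering at 0.6 µm/h toward 80 µm.
Cohorts draw a per-animal size factor (CV 5%) and a per-muscle factor
(CV 2%) from the seed.  Validation and statistics runs use scaled problem
sizes — 10 fibers for the measurement-deviation band, cohorts of 10
animals × 2 fibers sampled directly on the 5-hour grid over 0–60 h —
chosen so every check runs comfortably on one CPU while preserving the
protocol's population sizes (20 muscles per genotype and time point).

What the phantoms do **not** emulate: photorealistic textures, uneven
illumination, out-of-focus light, the centre-thickened fiber profile of
suppressed-atrophy muscles (diameter is constant along each phantom
fiber), muscle–muscle contact, and z-resolution effects (the pipeline is
2-D by design, operating on maximum-intensity projections).  Passing
phantom tests therefore demonstrates the correctness of the geometry,
measurement, tracking, storage and statistics machinery under realistic
noise — not robustness to every optical artefact of live imaging.

## Known limitations

* The level-set formulation is a reproducible stand-in for the method
  family named in interactive tools; exact equivalence to any particular
  plugin is not claimed and is asserted against geometric phantoms only.
* Inward-only evolution means a seed drawn *through* a fiber erodes across
  the cut without an edge to stop on; seeds must enclose their fiber.
* Greedy matching can be suboptimal in adversarial geometries where a
  slightly longer pair blocks two shorter ones; at observed fiber spacing
  (inter-cell distance ≫ D) this does not occur.
* Skeleton-based measures are re-derived per grid orientation; under 90°
  rotation they agree to ~1–2% rather than exactly (thinning is not
  D4-equivariant), while moment- and count-based features are exact.
* Whether orientation should be reported in (−90°, 90°] or [0°, 180°) is a
  convention; (−90°, 90°] is fixed here.
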