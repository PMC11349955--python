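# Methods

This note records the models, conventions and design choices behind
`svpath`, in the spirit of the methods documentation of packages like
scanpy or statsmodels: what is computed, under which assumptions, and where
the genuinely open choices were made.

## Coordinate model

All rasters are `(H, W, 3)` uint8 in (row, col) order, 0-based, with
half-open bounding boxes (`row_max`/`col_max` one past the last pixel).
Every raster lives in a named *frame*; a frame stores `scale_to_full`
(multiply coordinates by it to obtain full-resolution distances) and
`global_offset` (the frame origin in full-resolution coordinates). Mapping
a box between frames is therefore an affine scale-and-translate, rounded
to the nearest integer and clamped to raster bounds. Rounding is the only
lossy step: a compressed→full→compressed round trip moves each coordinate
by at most 1 px per hop, and the cascade's patch offsets are within 1 px
of planted centers (enforced by test).

Padding to a square appends blank (white, configurable) pixels on the
bottom and right only. Histology slides have near-white background, and
one-sided padding keeps the original origin fixed so the pad offset is
identically (0, 0) and never enters the coordinate algebra.

Downscaling uses area averaging (a box filter, via Pillow's `BOX`
resampling), the appropriate anti-aliased choice when compressing a slide
by factors of ~9. Upscaling — not used in the standard flow — is bilinear.

Centered crops near an image edge are **shifted, not shrunk**: the window
slides inward until it fits, so every patch is exactly the configured size
and every patch pixel is genuine image data. The recorded global offset
reflects the shifted window.

## Detection cascade

The cascade is detector-agnostic. A detector is a callable receiving the
(compressed) frame and returning scored boxes in that frame; boxes under
`min_score` (default 0.25, configurable — detection thresholds are
model-specific) are dropped by the contract wrapper, and malformed boxes
(outside the raster, inverted) are rejected as contract violations.

Stage 1 detects the cochlea on the compressed square slide. Slides contain
one cochlea, so when a detector fires more than once the highest-scoring
box is used and the rest logged. Stage 2 detects the SV on a compressed
copy of the full-resolution region cropped around the cochlea center, and
one patch is emitted per SV detection, centered on the detected box center
(boxes carry no anatomical landmark, so the box center is the natural
patch center). Patches are always cropped from the full-resolution
raster — compression is used only to make detection tractable, never for
pixel extraction — and this is enforced bit-for-bit in tests.

The classical baseline detector thresholds mean intensity, labels
8-connected components, filters by an area range, and scores each box
`min(1, area / area_max)`. It has no non-maximum suppression because
connected components cannot overlap. It is a usable stand-in on
high-contrast material (it drives the deterministic end-to-end tests), not
a competitor to a trained detector.

## Segmentation

A segmenter maps an RGB patch to two binary masks (SV, capillary bed) of
the same shape. Empty masks are legal; shape mismatches are rejected.
Capillary pixels outside the SV mask are tolerated with a logged warning —
anatomically the lumina lie inside the SV, but the contract does not force
a segmenter to agree. Postprocessing reduces the SV mask to its largest
8-connected component (patches are SV-centered, so one SV per patch is the
operating assumption) and removes capillary components below a minimum
area (default 5 px², suppressing single-pixel noise). Postprocessing never
adds pixels. 8-connectivity is used everywhere components are labeled,
consistent with thin diagonal capillary walls.

The classical baseline segmenter works in HSV: eosin-stained tissue is
saturated against the near-white background, so the tissue region is
`saturation ≥ 0.12` (dark hematoxylin pixels are also admitted), closed
with a 2 px disk and hole-filled — which pulls pale lumina and dark nuclei
into the SV body — and the largest component is the SV. Capillary lumina
are the bright (`value ≥ 0.82`), weakly saturated (`≤ 0.25`) components
inside the SV mask, area-filtered. On the synthetic fixtures it reaches
Dice 1.0 for both structures; on real H&E material these thresholds would
need tuning per stain batch, which is why the stage is a plug-in.

## Morphometry (SVAT)

* **Area** is the count of set pixels.
* **w₁ (minimum Feret diameter)** is computed exactly by rotating calipers
  on the convex hull of the set pixels' *outer corners* (each pixel
  contributes its four lattice corners, so an n-pixel-wide run measures
  exactly n). The minimum width of a convex polygon is attained flush
  against a hull edge, so it suffices to minimize, over hull edges, the
  maximum vertex distance to the edge line. The test suite checks this
  against an independent brute-force minimum over 3,600 projection angles
  (agreement within 0.5 px on random convex and concave masks; the
  brute-force value can only exceed the exact one, by at most
  O(width·(π/3600)²)).
* **w₂ (midline width)** takes the line crossing the axis-aligned bounding
  box at the midpoint of its longer side, perpendicular to it, and counts
  set pixels on that line. When a curved SV crosses the midline more than
  once the runs are **summed** by default (the literal reading of an
  intersection with the mask); the longest single run is available via
  `per_run_max=True`. Ties between box sides resolve to the row direction.
* **w₃ (average width)** is area / h with **h the longer side of the
  axis-aligned bounding box**. Patches are detector-centered and the SV
  roughly axis-aligned at patch scale; for strongly curved SVs w₃
  underestimates the true width (the planted-band tests budget 10% for
  this bias, and observe ~1% at the default near-straight curvature).
* **Capillary statistics** are the count, total area and mean area of
  8-connected components of the capillary mask at or above the minimum
  area.
* **Nuclei count**: K-means (k = 3 by default: background/tissue,
  cytoplasm, dark nuclei) on the raw RGB values of pixels under the SV
  mask, no spatial features. The cluster with the darkest mean luminance
  (Rec. 601 weights) is the hematoxylin cluster, unless its mean luminance
  exceeds a guard (default 140/255), which prevents fabricating nuclei on
  nucleus-free tissue. k is reduced with a warning if the mask holds fewer
  distinct colors. The count is total nuclei area divided by the median
  area of "singleton" components (area within (10, 200) px² at 512-px
  patch scale, configurable); division by the singleton area resolves
  clumps of fused nuclei without instance segmentation and cancels overall
  scale (doubling every nucleus area leaves the count within 5%). The
  K-means seed defaults to 0 and is recorded in the result; identical
  seeds give identical masks.
* **Units**: everything is measured in pixels and converted to µm by
  dividing lengths by `px_per_um` and areas by its square. There is
  deliberately no default calibration — the scale depends on scanner
  magnification and export downsampling and must be measured; µm columns
  appear in output only when a calibration is supplied, so pixel and µm
  values can never silently mix.
* **Group comparison** is a two-sided test on one metric across two groups
  of SVs; Welch's t-test by default (robust to unequal variances), with
  Mann-Whitney selectable for heavy-tailed metrics. The method used is
  part of the printed output.

Defining identities — `w₃ · h = area` and `mean · count = total` — are
enforced at record construction, and an empty SV mask yields an all-zero
row rather than an error.

## Evaluation metrics

Dice = 2|A∩B|/(|A|+|B|) and IoU = |A∩B|/|A∪B|, related by
IoU = Dice/(2 − Dice). Two empty masks score 1 (perfect agreement, logged);
empty vs nonempty scores 0. Segmentation reports carry per-item values,
means, min/max and the fraction of items with Dice above a threshold
(default 0.7, the conventional cut for acceptable segmentation).

Detection evaluation matches predictions to truth greedily in descending
score order (each truth box matches at most once, match requires box IoU ≥
threshold, default 0.5) and reports precision, recall, and **two** mAP
figures side by side: `map_standard`, the all-point-interpolated area
under the precision-recall curve — the definition detection benchmarks
use — and `map_paper_style`, the plain mean of precision and recall, which
some validation reports quote as "mAP". Reporting both keeps the package
comparable with either convention without ambiguity. With greedy
best-IoU matching, both precision and recall are monotone non-increasing
in the matching threshold (each prediction's preferred truth is
independent of the threshold while feasible), and this is property-tested.

## Synthetic fixtures

The generator emulates what the pipeline sees in an H&E patch, not
histology itself: a near-white background, an eosin-pink SV-like band,
off-white elliptical capillary lumina, and dark blue-purple nucleus disks,
plus per-channel Gaussian noise (default sd 3 on 8-bit values). The exact
palette is configuration, not science.

The band is a constant-width sweep of a quadratic Bézier centerline,
rasterized as the set of pixel centers within width/2 of a dense centerline
sample (0.1 px spacing, nearest-neighbor distance via a KD-tree). Its
analytic area is `width · arc_length + π (width/2)²` (the capsule end
caps), and the rasterized mask agrees within 0.1%. Curvature is
parameterized as the sagitta — the perpendicular bow of the centerline
midpoint off the chord — defaulting to 1 px, close enough to straight that
the minimum Feret diameter tracks the planted width within ~1 px while
still exercising the non-axis-aligned code paths.

Default geometry (512 px patch, 40 px band, 3 capillaries with semi-axes
3–6 px, 40 nuclei of radius 4 px) reflects an SV band at the scale the
pipeline's patches are extracted: wide enough that dozens of
non-overlapping nuclei fit, which is also a geometric requirement —
packing feasibility is estimated up front and infeasible requests are
rejected with the computed capacity. Capillary lumina are planted
disjointly along the centerline (major axis along the local tangent, minor
axis bounded by the band half-width), and each lumen's *rasterized* pixel
count is recorded as truth, so capillary accounting can be checked
exactly. Nuclei are equal-radius disks at integer centers (identical
rasterization, hence exactly equal areas) with pairwise center distance
> 2r + 2, avoiding the lumina.

The miniature whole slide (default 4,096 px, all cascade sides scaled
proportionally) places a dark annulus as a cochlea stand-in and straight
SV bands near its rim, with truth boxes padded to even extents so planted
centers are integers and cascade rounding stays within 1 px. Everything is
reproducible bit-for-bit from the spec (which includes the seed).

What the fixtures do **not** model: staining variability, out-of-focus
regions, touching anatomical structures, texture within tissue, and
irregular nucleus shapes. Passing tests therefore validate the geometry,
bookkeeping and estimators of the pipeline — not the performance of the
classical baselines on real slides, which is precisely why the detector
and segmenter stages accept trained plug-ins.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 64 px random masks for
metric oracles (200 masks × 3,600 projection angles), 512 px patches, and
4,096 px miniature slides (10 slides for the cascade-geometry check) —
sizes chosen so the full validation completes in about a minute on one
core while exercising every code path of the full-scale flow; all cascade
side lengths scale together through `CascadeConfig`. Notable numerical
conventions: nearest-integer rounding (banker's) in coordinate mapping;
convex-hull degeneracies avoided by the corner representation (a
single-pixel mask short-circuits to Feret 1); the AP oracle integrates the
precision envelope on a 200,001-point recall grid (agreement to 1e-3);
Welch's test refuses groups of fewer than two observations.

## Known limitations

* Pyramidal WSI containers (SVS/NDPI/OME-TIFF pyramids) are out of scope;
  input is flat TIFF/PNG.
* h (and hence w₃) uses the axis-aligned bounding box; a strongly curved
  or diagonal SV biases w₃ low. An oriented-box variant would remove this
  but is not needed for detector-centered patches.
* The nuclei counter assumes hematoxylin is the darkest color mode inside
  the SV; heavy pigment or artifacts would violate this.
* The classical baselines are contrast/color thresholds; on real stained
  material they are starting points, not replacements for trained
  detectors and segmenters.
* Turn-specific (basal/apical) grouping of SVs and 3D reconstruction
  across serial sections are out of scope.
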