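# Methods

## Vegetation segmentation

The clipping pipeline computes the excess green index
ExG = (2g − r − b)/(r + g + b) on raw digital numbers, so it is invariant to
bit depth (8- and 16-bit PNGs are handled natively, with a built-in 16-bit
codec because Pillow truncates 16-bit colour PNGs to 8 bits on read). Pixels
with r + g + b = 0 are defined as ExG = 0: pure black behaves like
bareground and the division never degenerates. The index is algebraically
bounded in [−1, 2].

Thresholding is per image by Otsu's method over a 256-bin histogram spanning
the observed ExG range (delegated to scikit-image). A constant map — an
all-gray or vegetation-free frame — has no class structure and raises a
degenerate-input error rather than returning an arbitrary cut. When modes
are separated by empty histogram bins, several splits attain exactly the
maximal between-class variance; any of them is a correct Otsu threshold and
the tests assert optimality of the achieved variance, not the identity of
the tied bin.

Connected components use 8-connectivity by default (diagonal leaf contacts
stay one plant); the speck filter defaults to 100 px at full 2048-px frame
scale and is configurable. Plants that touch or occlude one another merge
into a single component — a known limitation, accepted rather than patched
with watershed heuristics. Class labels are never inferred from pixels; they
come from the declared content of the source image.

## Random modifier

Each paste draws independently: rotation angle U(0°, 180°), scale factor
U(0.6, 1.2), hue shift magnitude and saturation shift U(0%, 10%). The
"0–10%" colour jitter is interpreted as an additive hue rotation of up to
10% of the hue circle with a random sign (sign randomization avoids a
systematic colour drift while respecting the stated magnitude) and a
multiplicative saturation increase of up to 10%, clamped at full scale. The
value channel and the alpha channel are untouched.

The order is fixed: rotate → scale → hue/saturation, so colour jitter is
never resampled and compound blur is minimized. Geometric resampling is
bilinear on alpha-premultiplied colour (prevents dark fringing at the
silhouette edge); the binary footprint is alpha > half scale. Exact
multiples of 90° are grid permutations via `np.rot90`, preserving the
footprint area bit-exactly. Every draw is logged as a `ModificationRecord`
whose replay reproduces the output raster exactly; pools subset by taking
the first k per class, so instance-pool sweeps (1, 5, …, 50) built from one
master pool are nested. Sampling is with replacement — necessary for pools
of a single instance per class.

## Paste operator

Scenes composite in ascending z-order (paste order). Each annotation records
the *visible* mask — its own opaque footprint minus the union of later
pastes — because the evaluator must compare against what a detector can
actually see; amodal footprints would create unlearnable ground truth.
Annotations whose visible area falls below max(`min_visible_px`,
10% of the instance footprint) are dropped; the floor defaults to 50 px at
full 2048-px scale and should be scaled with the scene (the test suite and
acceptance runs use 256-px scenes with 48-px plants — one eighth the linear
scale — and a floor of 2 px).

Row-oriented placement lines n cotton plants along a user-chosen row at
spacing width/(n+1) with uniform perpendicular jitter; weeds are uniform
everywhere under *both* strategies — only the crop's placement
distinguishes row-oriented from random scenes. Random placement confines
the whole silhouette inside the frame; an instance that outgrows the frame
after modification is downscaled to fit and the event logged. Backgrounds
rotate round-robin from a random starting offset. Category ids are fixed:
cotton = 1, MG = 2, grass = 3. Reduced-resolution (512-px) variants are
produced by synthesizing at 2048 px and block-reducing by 4 — area-weighted
means for the image, majority vote per block for masks (which legitimately
erases blades thinner than the block) — rather than re-synthesizing.

## COCO containers

Annotations follow COCO conventions: 0-based coordinates, bbox
[x, y, w, h] with half-open pixel extents, masks as uncompressed
column-major run-length encodings (the codec is self-contained and
round-trips bit-exactly; polygons are rasterized on read). Merging
re-indexes the second set's ids after the first's maxima and keeps the
originals in `orig_id` provenance fields; categories are matched by name
and a name mismatch is an error. Splitting partitions by image, never by
annotation, under a seeded permutation. Both operations conserve counts
exactly. Serialization uses sorted keys and fixed separators, so a fixed
seed yields byte-identical files.

## Evaluator

Matching is the community-standard greedy protocol per image and class:
detections ranked by descending score (ties keep input order), each matched
to the unmatched ground truth with the highest IoU (IoU ties go to the
lowest ground-truth id), a true positive iff IoU ≥ 0.5, and a second
detection on a claimed ground truth is a false positive. AP is the 11-point
interpolation — mean over recall levels {0, 0.1, …, 1} of the maximum
precision at any operating point with recall ≥ that level, 0 where no such
point exists. mAP averages classes that have at least one ground truth;
absent classes are excluded rather than scored 0, which would be an
undefined recall. A single IoU threshold (0.5) is used; no 0.5:0.95
averaging and no 101-point variant. PR curves are computed per dataset,
not pooled across test sets.

## Biomass regression

Ordinary least squares with intercept (statsmodels), fitted separately per
species, never pooled; a straight line is the minimal model consistent with
a monotone area-mass relation at seedling scale. R² = 1 − SS_res/SS_tot is
invariant to affine predictor rescaling, so fits in px² and cm² (via
GSD: cm² = px · (gsd_mm/10)², default GSD 0.0274 mm/px) agree. Plants are
associated to detections by an explicit id mapping supplied by the user; no
automatic spatial matching is attempted.

## The fixture test bed

The generators emulate the *structure* of field survey data, not its
appearance. Soil backgrounds are brown with an anti-correlated red/blue
swap texture that leaves both 2g − r − b and r + g + b unchanged, so every
soil pixel carries the identical negative ExG; plant silhouettes are
green-dominant with luminance-only noise, keeping plant ExG above 0.5.
Segmentation on composed fixtures is therefore exact by construction, and a
plant-free background raises the degenerate-threshold condition. This
isolates the geometry and bookkeeping of downstream stages from
segmentation noise — and it means passing tests certify the pipeline's
logic, not segmentation quality on real imagery, where soil ExG varies
continuously and shadows, specular leaves and mixed pixels blur the modes.

Broadleaf silhouettes (overlapping elliptical lobes) fill ≥ 40% of their
tight bbox; grass blades (thin tapered curves) fill ≤ 25% — the contrast
that makes bbox area a systematically worse biomass predictor in the
constructed data, mirroring (by construction, not as evidence about real
plants) the qualitative field finding that canopy masks predict biomass
better than boxes.

The biomass generator draws areas U(500, 5000) px², sets
biomass = β·area + N(0, σ²) truncated at 0 with β = 0.01 g/px², and chooses
σ² = Var(β·area)·(1 − R²)/R² so the fit's design R² is controlled (0.66
for the MG-sized sample of 99, 0.48 for the Grass-sized sample of 104).
Truncation affects ≲ 2% of draws at these settings and shifts the recovered
moments by well under the test tolerances. Fake detections for evaluator
checks drop exactly round(rate·n) ground truths per class and give
survivors scores in (0.75, 0.95) and spurious boxes scores in (0.05, 0.25),
so with zero jitter the 11-point AP is an exact function of the drop rate.

## Problem sizes and determinism

Tests and the acceptance script run scenes at 256 px with 48-px plants
(one eighth of the 2048-px full scale, with the visible-area floor scaled
alike), 100-scene generation runs, 500-case evaluator oracle sweeps, and
100-rep biomass Monte-Carlo at the per-species field sample sizes. All
randomness flows through `numpy.random.Generator` objects seeded from a
single master seed; fixed-seed reruns reproduce annotation JSON and
evaluation reports byte for byte.

## Known limitations

No shadow rendering, lighting harmonization or boundary blending beyond
alpha compositing; no watershed splitting of merged plants; no automatic
species labelling of clipped instances; no multi-threshold COCO AP; no
nonlinear allometric biomass models. The fixture imagery is deliberately
unrealistic in colour statistics, and conclusions from it transfer to real
imagery only for the pipeline's bookkeeping, not its segmentation accuracy.
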