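# Methods

## Problem setting

After immunomagnetic depletion of a blood sample, the cells left on the
imaging surface are overwhelmingly white blood cells (WBCs) plus a handful
of circulating tumor cells (CTCs). Both appear in 20× bright-field imaging
as round, defocused objects ~11.5 µm across — a dark rim around a brighter
interior on a noisy gray background — and size alone does not separate the
classes. The package classifies each detected cell from its bright-field
crop, with fluorescence used only to label training data.

## Synthetic scene model

No public paired bright-field/fluorescence dataset exists for this
workflow, so the package generates its own with known ground truth. The
generator is a study-conditions definition, not a physics simulation.

**Geometry.** Frames are 480×640 at 0.46 µm/px (chosen so an 11.5 µm cell
spans ≈25 px ≈ 500 px² of area). WBC diameters ~ Normal(11.5, 0.8) µm,
CTC diameters ~ Normal(11.5, 1.8) µm, both truncated at ±3σ: equal means,
wider CTC spread. Cells are placed by rejection sampling with a 34 px
minimum spacing and a 24 px border margin; 10% of cells (by default) are
deliberately placed touching a neighbor at 0.95× the sum of radii to
exercise the watershed, and 5% are flagged "very bright" to exercise the
brightness cap. A frame that cannot hold the requested population raises a
placement error naming the limiting parameters.

**Bright field.** Background 128 (8-bit), multiplied by a radial vignette
(up to ~12% darker at the corners) and a low-frequency "cloud" field,
plus Gaussian pixel noise (σ = 3). Each cell adds a radial profile: a
brighter interior, a dark rim (sinusoidal dip over the rim width), and a
faint outer halo. The classes differ in rim depth (WBC ≈ 40, CTC ≈ 60
intensity units), rim width (2 vs 3 px), interior gain (8 vs 26) and
interior texture amplitude (2 vs 9, a per-cell smooth random field) — this
rendered texture/rim difference, not size, is the learnable signal.
Very-bright cells render with interiors near saturation (250). Twelve
small bright debris specks (σ ≈ 1.2 px Gaussian spots, far below the
minimum cell area) are scattered per frame.

**Fluorescence.** Perfectly registered same-shape channels (an idealization
— real rigs have registration error), background 10 with σ = 2 noise, and
a Gaussian blob (amplitude 170, σ = diameter/4) at each cell center in the
channel matching the class only. This guarantees class-conditional channel
purity, which the label-transfer stage then must reproduce.

What the generator does **not** emulate: optics (PSF defocus stacks),
red blood cells and platelets (samples are post-enrichment), uneven
illumination beyond the smooth vignette/cloud fields, staining variability
and mis-registration. Passing tests therefore demonstrate the pipeline's
mechanics and its statistical hygiene, not clinical performance.

## Segmentation

Composition: brightness cap → gradient Otsu edge mask → hole filling →
opening + area filter → distance-transform watershed → region extraction.

- **Brightness cap** replaces the manual "set a maximum brightness" fix:
  all pixels above the 98th percentile are clipped to it. The default is
  98 rather than a higher percentile because the cap must land *above* the
  brightest normal-cell pixels but *below* the outlier population; with
  ~5% very-bright cells the outlier pixels can exceed 0.5% of the frame,
  and a cap inside that population leaves an intensity step whose gradient
  pulls the edge threshold above normal WBC rims.
- **Edge detection** is Otsu on the Sobel gradient magnitude of the
  Gaussian-smoothed (σ = 1.5) capped image. Applying Otsu to the gradient
  rather than the intensity yields closed rim rings for dark-rim cells,
  which the subsequent flood-fill requires; a plain intensity-Otsu mode is
  available in config. The Otsu primitive uses a 256-bin histogram over
  the sample range, maximizes between-class variance, breaks exact ties
  (plateaus across empty bins) toward the lower threshold, and raises on a
  constant sample rather than inventing a threshold.
- **Gap closing** (disk radius 2) bridges one-to-two-pixel breaks in the
  rim contours before filling: gradient rims dip below threshold in
  vignetted corners, and an unclosed rim leaves an annulus that cannot be
  filled and later shatters under the watershed.
- **Hole filling** marks background components not connected to the image
  border (4- or 8-connectivity, default 8) as foreground. It never removes
  foreground.
- **Opening** uses a disk of radius 2 px with out-of-image pixels treated
  as background for both erosion and dilation, then removes components
  outside [120, 4000] px². The lower bound is ~1/4 of the nominal 500 px²
  cell; the upper bound is deliberately generous (~8 cells' area ≈ a chain
  of 2–3 merged rims) because a merged chain must survive this filter for
  the watershed to split it — filtering merged chains here silently drops
  every cell in them.
- **Watershed** markers are regional maxima of the Gaussian-smoothed
  Euclidean distance transform, with maxima inside one suppression window
  (radius 8 px ≈ 0.6× the nominal cell radius) merged so a single
  irregular blob does not shatter into fragments; flooding runs on the
  negated smoothed distance restricted to the mask, so labels exactly
  partition the foreground. Empty masks return zero regions, not an error.

All parameters live in `SegmentParams` / `BrightFieldSegmenter` and are
config-exposed. Measured on the default generator (ten frames, 50
non-touching cells each): recall ≥ 0.95 at ≤ 3 px centroid error with
≤ 2 false regions per frame.

## Dataset construction

Crops are 30×30, centered at the rounded region centroid, edge-replicated
at frame borders, with the exact float centroid recorded for later count
reports. Label transfer computes, per channel, the mean signal in a disk
of radius side/4 around the centroid minus the frame median, divided by a
robust (MAD-based) noise scale; a class is assigned when its channel's SNR
reaches 3 and exceeds the other channel, otherwise the crop stays
UNLABELED (kept for prediction, excluded from training).

Manual single-cell curation is replaced by explicit rules, applied in
order with the first failure recorded as the rejection reason: area in
[120, 2000] px², solidity ≥ 0.85, eccentricity ≤ 0.8, centroid ≥ 16 px
from the frame border, and pairwise bounding-box overlap ≤ 0.3 (fraction
of the region's own bbox).

Normalization fits a least-squares plane to the crop's outer 3-px border
ring, subtracts it over the whole patch (removing local background tilt
from vignetting), and standardizes to mean 0 / sd 1. The operation is
exactly idempotent after the first application (the second border fit is
the zero plane by least-squares orthogonality). A patch with no residual
variance — constant, or a pure ramp — carries no cell and raises a
degenerate-patch error; the pipeline counts such detections as
unclassified.

Augmentation samples source crops uniformly with replacement (seeded) and
applies a random rotation (±180°), shear (±0.2) and horizontal/vertical
flips about the patch center, bilinear with edge padding; originals are
emitted first and synthesis tops the class up to `target_per_class`
(default 1000 per class). Every crop's `origin_id` resolves to an
unaugmented crop; that provenance is what the cross-validation harness
partitions on. An identity spec returns sources pixel-exactly (the warp is
skipped, not round-tripped through interpolation).

## Classifier

The reference recipe — frozen ImageNet ResNet-50 features with a trainable
head — requires a deep-learning framework and a weight download, so the
package's default backbone is a small scratch CNN written directly on
numpy: three conv blocks (3×3 same-padding conv → ReLU → 2×2 max-pool;
8/16/32 channels), then the identical head used in the reference recipe:
fully connected ReLU layer (default 256 units), inverted dropout at 0.6,
and a 2-way softmax trained with cross-entropy and Adam. Inputs are the
30×30 normalized crops bilinearly resized to 34×34. Defaults follow the
recipe where it states them (dropout 0.6, learning rate 1e-4, batch 16);
epoch budget (50) and early stopping on validation loss (patience 10,
best-epoch weights restored) are package choices. Requesting
`pretrained-resnet50` raises a clear error naming the scratch alternative
unless torch/torchvision plus cached weights are importable.

`freeze_backbone` is honored for either backbone (frozen conv blocks
receive no optimizer updates); the scratch default is `False` because a
random, untrained backbone is not a meaningful feature extractor. Dropout
is active only when a training-mode RNG is supplied, so inference is
bit-deterministic. Probability ties resolve to WBC, the non-rare class,
minimizing false CTC calls. The sklearn-style `CNNClassifier` estimator
wraps the same engine (fit/predict/predict_proba, `get_params`/clone
compatible).

Training is deterministic for a fixed seed and thread count; the engine is
pure numpy, so no framework-level nondeterminism exists.

## Cross-validation and metrics

`make_folds` stratifies by class, shuffles within class, and distributes
each class's remainder to the currently least-loaded folds — so 95
originals at k = 5 give exactly five folds of 19 while every fold's
complement keeps both classes. Only unaugmented crops may enter a plan.

`run_cv`, per fold: augment the complement to the spec target, split the
augmented pool 80/20 into train/validation at the *origin* level
(image-level splitting would leak near-duplicate augmented copies into
validation), train, and predict the held-out fold's originals only. The
harness asserts, for every fold, that the origin sets of train∪validation
and test are disjoint and raises a hard `LeakageError` otherwise — this is
a runtime invariant, not just a test.

F-score is computed for the CTC-positive class directly from the 2×2
confusion matrix ([WBC, CTC] order, rows true), returning 0 with a
degenerate-metric warning when precision + recall = 0. ROC/AUC uses a
threshold sweep over unique scores with ties grouped (trapezoidal area,
equal to the normalized Mann–Whitney U); both the pooled AUC over
concatenated folds and the mean of per-fold AUCs are reported, since both
aggregations are in common use. t-SNE (perplexity 50, learning rate 100,
fixed seed) embeds flattened normalized pixels; its contract is shape and
seeded reproducibility, not geometry.

## Problem sizes used in the shipped checks

The test suite runs the generator at frame scale (480×640) with 50–80
cells per frame; the cross-validation check uses ~150 original crops from
two frames, augmentation to 150 per class, and a 64-unit head trained at
1e-3 for up to 12 epochs — enough for the rendered class difference to be
learned to pooled accuracy ≥ 0.9 in CPU-minutes, while the 1000-per-class
augmentation target and the full training recipe remain the defaults for
real use. The brute-force oracle comparisons (hole filling, opening, Otsu,
AUC, F-score) run on 10⁴ random small masks and hundreds of random
samples per primitive.

## Known limitations

- The synthetic appearance model is parametric and smooth; real
  bright-field cell texture is richer, and the reported synthetic CV
  accuracy says nothing quantitative about clinical data.
- The pretrained transfer-learning path is an interface, not a shipped
  model; results with it depend on the external weights.
- Fluorescence registration error, multi-focal stacks and non-enriched
  samples (RBCs, platelets) are out of scope.
- Quality filtering is rule-based; cells rejected by it (e.g. touching
  pairs with heavily overlapping boxes) are counted as detected but may
  remain unclassified in the count report.
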