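# Methods

`treestump` detects the visible trunks of standing trees ("stumps" in
the loose field usage — eye-level trunks, not cut stumps) in suburban
street-level photographs. Suburban scenes are hard: houses, fences,
lamp posts, cars and bushes provide clutter that is variable in shape,
scale and colour, and some of it (wooden poles, brown fences) is
bark-coloured. The package implements three detection approaches that
trade engineered domain knowledge against learning, the shared
sliding-window machinery that turns patch classifiers into detectors,
the evaluation protocol, street-level data-assembly steps (panorama
stitching, bearing-only triangulation, road-mask sampling), and a
synthetic-scene generator that makes everything testable without
external imagery.

## Approach 1 — engineered colour + contour model

**Colour gate.** Bark colour is modelled as a mixture of `k` = 5
full-covariance Gaussians in RGB (bark palettes span several hue
modes; `n_components` is configurable). Training pixels come from bark
patches expanded by photometric augmentation — brightness gain in
[0.8, 1.2], gamma in [0.8, 1.25], per-channel gains in [0.9, 1.1],
additive Gaussian noise with sigma 0.02, each range configurable —
so a few hundred source patches become >1000 training patches.
Fitting is expectation–maximisation (scikit-learn backend), executed
one warm-started step at a time so the per-iteration log-likelihood
path is recorded; the path must be non-decreasing (checked in tests),
and covariance eigenvalues are floored at `reg_floor` = 1e-4 so
single-colour degenerate inputs converge without NaNs instead of
collapsing.

Pixels are scored by the **minimum Mahalanobis distance** over
components. Distances are on the sigma scale (distance 1 ⇔ one
standard deviation from a component mean), so the default acceptance
threshold `tau` = 3 is the conventional three-sigma region. `tau`,
never stated for this problem, is deliberately exposed as
configuration. The thresholded mask is cleaned by morphological
opening (disc radius 1, removes pixel speckle) then closing (disc
radius 2, fills small holes); radii configurable, 0 disables.

**Contour consistency.** Gabor edges are computed with a bank of 2
frequencies (0.1, 0.2 cycles/px) × 4 orientations (0°, 45°, 90°,
135°); the response is the complex filter's energy with the real
part's DC removed (constant images score 0), the per-pixel magnitude
is the max over the bank, and the stored orientation is the winning
filter's *edge* direction. Trunk *segments* are extracted by tracing
each connected bark-mask region row by row into left/right edge
chains, accepting regions that are ≥ 12 px tall, ≥ 3 px wide
(means), within 30° of vertical, ≥ 60% bark-filled between their
edges, and whose two chains are supported by Gabor edge energy.
Segments are then linked greedily: a pair may join when the facing
segments' directions differ by ≤ 20°, widths by a ratio ≤ 1.5, the
vertical gap is ≤ 0.5× the mean segment length, and the corridor
between them is ≥ 50% bark-likely (distance ≤ `tau`). The
best-scoring pair (equal-weight mean of angle, width and fill
agreement) merges first, ties break on topmost-point order, and the
process repeats to a fixed point. Linking therefore partitions its
input, is idempotent and is independent of input order — all three
are property-tested.

This approach is retained as the engineered baseline. By design it
depends on brittle, hand-set structure and is expected to degrade
fastest as clutter grows; the package documents this rather than
tuning it competitive.

## Approach 2 — BoVW over dense SIFT + linear SVM

Grayscale patches are described by 128-dimensional SIFT descriptors
(4×4 spatial cells × 8 orientation bins) on a dense grid: stride 8 px,
spatial bin sizes 4 and 8 px (scales 1 and 2), keypoints wherever the
full 16s-px support fits. The implementation is local to this package
(no installed library exposes dense SIFT): hard orientation binning,
integral-image box pooling per cell, then L2-normalise → clamp at 0.2
→ re-normalise. Zero-gradient (flat) descriptors stay zero vectors
and are quantised like any other, so sky regions remain in the
histogram instead of being special-cased. Patches too small for any
keypoint yield an empty set (warning, not an error) and encode to a
flagged zero histogram classified negative by convention.

A visual vocabulary of `k` = 200 words — the classification-sized
vocabulary regime, as opposed to the much larger retrieval regime —
is learned by k-means (k-means++ init, 10 restarts, up to 300
iterations, tol 1e-4) over a descriptor pool subsampled to at most
15,000 descriptors; the cap keeps vocabulary learning linear-time at
negligible cost to centroid quality at this `k`. Patches are encoded
as L1-normalised nearest-word histograms (Euclidean assignment, ties
to the lowest index; L1 vs L2 normalisation is configurable, L1 the
default) and classified by a linear SVM (`C` = 1 by default).

## Approach 3 — colour-aware HOG + RBF SVM

Patches are converted from RGB to YUV by the fixed linear transform

    | Y |   |  0.299    0.587    0.114   | | R |
    | U | = | -0.14713 -0.28886  0.436   | | G |
    | V |   |  0.615   -0.51499 -0.10001 | | B |

with no clipping. Histograms of oriented gradients are computed on
each channel independently and concatenated in Y, U, V order. The HOG
geometry is the canonical pedestrian-detection layout: 64×64 window,
8-px cells, 2×2-cell blocks with stride one cell, 9 unsigned
orientation bins, L2-Hys block normalisation (eps 1e-5, clip 0.2).
Gradients are centred [−1, 0, 1] differences with zero borders and no
gamma correction (inputs are already linear floats). Whether U and V
are range-shifted before gradients is immaterial — gradients are
shift-invariant — so no shift is applied.

A numerical subtlety worth recording: for a grey patch (equal
channels) the V transform row sums exactly to zero, so the V channel
is constant and its HOG sub-vector is exactly zero; the U row sums to
1e-5, leaving gradients of order 1e-6 which L2-Hys normalisation can
amplify to order-one block vectors. `hog_channel(block_norm=False)`
exposes the raw cell energies for analyses where this matters; for
classification the effect is irrelevant because real patches have
non-degenerate chroma.

Classification uses an SVM with RBF kernel (`C` = 10, gamma =
1/(d·var(X)) by default), capturing the extra nonlinearity of the
concatenated colour descriptor. Predictions are served by an explicit
kernel expansion over stored support vectors, dual coefficients and
intercept — so trained models serialise to plain arrays — and the
expansion is cross-checked against the training-time estimator's
decision function in tests.

## Sliding-window detection

Scenes are scanned with an image pyramid: levels downscale by a
factor 1.25 from scale 1 to 4, and a fixed window (default 64×64;
48×96 is the tall trunk-shaped variant) slides with stride 16 px over
each level. The final window on each axis snaps to the image edge so
every pixel is covered at each level. Boxes are mapped back to
original coordinates (0-based, half-open, clamped). Any patch
classifier with continuous margins plugs in; windows with score > 0
(the SVM decision boundary; adjustable for precision/recall sweeps)
become detections and are merged by greedy non-maximum suppression at
IoU 0.3.

## Evaluation protocol

Two modes. *Per-tree*: detections are matched to ground-truth boxes
greedily in descending score order, each claiming the highest-IoU
unmatched truth box at IoU ≥ 0.5. *Per-patch*: window label
predictions are scored directly and additionally yield a
row-normalised 2×2 confusion matrix (rows = true class). In both,
precision = TP/(TP+FP), recall = TP/(TP+FN), and **false acceptance =
FP/(TP+FP) = 1 − precision** — the fraction of positive detections
that are wrong. Zero denominators flag the metric undefined instead
of propagating NaN. Note that under heavy class imbalance a small
false-positive *rate* in the confusion matrix (normalised by the
non-tree count) coexists with a large false acceptance (normalised by
the detection count); the two are deliberately reported side by side.

## Street-level data assembly

Capture points are sampled along skeletonised road masks at fixed
arc-length spacing. Views fetched at several headings from one point
(fetching itself is behind a `Fetcher` callable; a disk-backed
fixture fetcher ships, live services do not) are stitched by a pure
horizontal-translation model: pairwise offsets by normalised
cross-correlation search in the expected overlap band (failure below
an NCC floor of 0.2 raises explicitly), composited with a linear
blend ramp so pixels outside any overlap are copied verbatim.
Narrow-baseline same-point views make the translation model adequate;
homography stitching is an extension point, not implemented. Trunk
ground positions come from bearing-only triangulation: a detection's
bearing is heading + (x_centre/width − ½)·hfov under the linear
pinhole approximation, and ≥ 2 bearing rays from known planar poses
(metres east/north; geodetic conversion out of scope) intersect in
least squares, with the RMS perpendicular distance reported as the
residual and near-parallel geometries (< 0.5° spread) rejected.
Defaults: 4 headings at 90° spacing, 90° horizontal field of view,
sources up to 640×640 px.

## Synthetic scenes

The generator emulates the statistics the detectors rely on, not
photorealism. Trunks are near-vertical trapezoids (taper 0.7–1.0,
widths 10–28 px, heights 60–160 px, elongation 1:4–1:12) textured
with column-correlated multiplicative striation around one of five
bark palette hues (browns and greys, spread 0.04), optionally topped
by a green canopy ellipse; clutter comprises grey poles, coloured
boxes and green blobs over gradient or textured backgrounds. Scenes
carry exact half-open bounding boxes plus the generator's own paint
masks, so ground-truth soundness (each box ≥ 80% painted bark) is
checked against construction flags, not colour heuristics. A
`difficulty` knob in [0, 1] adds up to 8 bark-coloured clutter
objects — the axis along which colour-blind and colour-aware
detectors separate. Trunks draw last and so may occlude clutter but
never the reverse, keeping boxes unambiguous. Every generator is a
pure function of its configuration (byte-identical repeats), and one
user seed fans out to all stages by hashing (seed, stage-label).

What the generator does *not* emulate: perspective, shadows and
illumination gradients across objects, foliage texture, occlusion of
trunks (available only as an explicit option), JPEG artefacts, and
the long-tailed variety of real street clutter. Passing tests
therefore demonstrate internal correctness and the expected *relative*
behaviour of the methods under controlled conditions, not absolute
real-world accuracy.

## Headline experiment and problem sizes

`treestump.experiments.run_method_comparison` trains both
learning-based detectors on one synthetic corpus (300 trunk + 300
non-trunk training patches) and evaluates them on held-out windows
from fresh scenes: 1000 trunk and 5000 non-trunk windows drawn from
200 scenes, preserving a realistic 1:5 imbalance; train and
evaluation streams use disjoint derived seeds. The acceptance suite
runs this at three corpus seeds and asserts the qualitative ordering
— colour-aware HOG precision ≥ BoVW precision, both recalls ≥ 0.85
at the easy difficulty — the package's analogue of the published
finding that colour awareness chiefly buys precision. These problem
sizes are the package's study conditions, chosen to give stable
metrics on a single CPU.

## Numerical choices and degenerate inputs

- Boxes are 0-based half-open everywhere; conversion only at file I/O.
- Colour is float in [0, 1] in memory; 8-bit only at file I/O, so the
  YUV transform is never quantised.
- k-means/EM/SVM seeds all derive from user seeds; nothing reads
  global random state.
- Nearest-centroid and NMS ties break on the lowest index; segment
  linking ties break on topmost-point order — all chosen for
  determinism under permutation.
- Empty detection lists, all-false masks, single-image panoramas and
  zero-support confusion rows are all defined results, not errors;
  genuinely contradictory inputs (pool smaller than k, single-class
  training sets, parallel bearings, degenerate boxes) raise
  `ValueError` eagerly.
- Model bundles are deterministic ZIPs (fixed timestamps, sorted
  members, SHA-256 per array): save → load → save is byte-identical,
  tampering fails the checksum, newer format versions fail loudly.

## Known limitations

- The engineered approach's delineation quality has no numeric
  benchmark; its tests are fixture-based (constructed bar geometries).
- The translation-only stitcher assumes same-point captures; wide
  baselines or vertical misalignment need a homography model.
- Dense SIFT uses hard orientation binning (no bilinear vote
  interpolation); adequate for bag-of-words quantisation, slightly
  coarser than interest-point SIFT implementations.
- Absolute precision/recall on real street imagery cannot be inferred
  from the synthetic corpus; only the internal contracts and the
  relative method ordering are validated.
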