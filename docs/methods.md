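# Methods

## Problem setting and model

A micrograph is modeled as a 2D intensity field in which particles appear
as compact dark regions (after contrast enhancement) on a brighter, noisy
background. The pipeline's central assumption is *intensity separability*:
after preprocessing, the particle interiors occupy the darkest portion of
the intensity range, so a partition of intensities alone — no spatial
features — isolates them. Everything downstream (cleaning, Hough voting,
Feret sizing) operates on the binary mask this partition produces.

## Preprocessing chain

Input micrographs are frame-averaged (plain per-pixel mean; the averaging
of n i.i.d.-noise frames reduces noise by 1/√n — no per-frame alignment is
attempted, motion correction being an upstream concern), z-scored over the
whole image, and affinely mapped to [0, 1]. Whether the z-score should use
background-only statistics is unresolvable without a background label;
whole-image statistics are used, which for sparse particles differ
negligibly.

The enhancement steps, in order, each mapping [0, 1] → [0, 1] and each
individually toggleable:

| step | default | notes |
|---|---|---|
| contrast stretch | 2% / 2% pixel-mass limits | limits found by cumulative-mass rule, then linear map with clipping |
| mid-range stretch | — | divide by max |
| histogram equalization | 256 bins | pixel → CDF value |
| adaptive Wiener | 5×5 window | `out = μ + max(0, σ²−ν²)/max(σ², ν²)·(x−μ)`, noise power ν² = mean local variance, reflective boundaries |
| CLAHE | 8×8 tiles, clip 0.01 | delegated to scikit-image's clip-limited adaptive equalization |
| guided filter | 5×5 window, ε = 1e-4 | self-guided local linear model `a_k = cov/(σ²+ε)` |
| grayscale closing | 5×5 square element | dilation then erosion; idempotent |

Sub-step order in the stretch stage follows find-limits → mid-range →
adjust. The Wiener step is the pure-denoising specialization (blur kernel ≡
identity): the frequency-domain deconvolution form needs a known blur
spectrum that real micrographs do not provide. The closing uses the
dilate-then-erode composition (the "closing" semantics); it fills dark
gaps smaller than the element so each particle reads as one connected dark
region.

Two numerical notes. The CLAHE implementation bins internally, so its
single-tile/no-clip limit matches the global equalizer only to within about
two bin widths (asserted in tests at 2/256). The guided filter's ε → ∞
limit is the *twice*-box-filtered mean (per-window intercepts b_k → window
means, then averaged over covering windows), which is the closed form the
tests check.

## Intensity-based clustering

With K = 4 (the default throughout), interval width d = (max − min)/K and
edges at min + k·d, a pixel with value v gets label k iff v lies in the
k-th half-open interval; the top interval is closed so v = max gets label
K. A 1e-9·d nudge before the floor keeps values that lie exactly on an
edge in their own interval despite floating-point round-off. Labels depend
only on values: the assignment is one pass (n operations), seed-free, and
permutation-equivariant. Centers are interval midpoints; an optional
refinement (recompute centers as cluster means, reassign once) exists but
is off by default to keep the default path strictly deterministic.

The baselines run on the same 1-D intensity feature. k-means uses seeded
k-means++ (D²-weighted) initialization — with uniform random starts,
Lloyd's algorithm on well-separated 1-D levels routinely merges two levels
into one cluster, a local optimum that would contaminate any cross-seed
comparison. FCM uses fuzzifier m = 2 and stops when centers move < 1e-5.
Both expose `sort_labels`: raw label order follows the seed (the
instability the deterministic clusterer exists to remove); sorted labels
ascend with center intensity, making "label 1 = darkest = particles" hold
for every method. The particle mask is `labels == 1`; an `invert` flag
covers bright-particle data.

## Mask cleaning and shape filters

Cleaning order: fill interior holes → 3×3 binary opening → drop components
with area < `min_area` → drop components with circularity <
`min_circularity` (default 0.5). `min_area` defaults to 0.3·πr² for the
configured expected particle radius r, with a 4·πr² area cap available,
keeping both filters scale-free. The operation is idempotent and
monotone in both thresholds.

Shape conventions are frozen package-wide: perimeter is the √2-weighted
chain estimate (diagonal steps count √2), circularity is 4πA/P², extent is
area over bounding-box area, and the maximum Feret diameter is the largest
pairwise distance between boundary *pixel centers* (9√2 for a 10×10
square). Digital-perimeter bias matters: a rasterized disk's circularity
sits near 0.92–1.05 depending on radius, and a *small* square's
circularity rises as (π/4)·(s/(s−1))² — above 0.9 for s ≤ 14, i.e. small
squares are indistinguishable from disks by circularity alone.

The square-keeping pass (side-view path) keeps a component iff extent ≥
0.87, bounding-box aspect within 25% of 1, circularity < 0.9, and area
within the cap. Extent carries most of the separation: an ideal disk's
extent is π/4 ≈ 0.785 and measured noisy disks span 0.78–0.83, while noisy
squares span 0.91–0.99. The circularity cut mainly eliminates round-ish
clutter, at the documented cost of also eliminating small squares (see
limitations).

## Circle detection

Boundary pixels — foreground pixels with a background 4-neighbor, image
border counting as background — replace Canny edges as the Hough input.
Each boundary pixel votes, for every radius r in the configured band, for
all centers at rounded Euclidean distance r (the rounded-distance ring is
the rasterization convention; it admits an arithmetic-only independent
oracle). Accumulator cells that are 3×3 spatial maxima in their radius
plane and carry at least `vote_frac_min · 2πr` votes become peaks; peaks
are pooled across radii and greedily suppressed by descending vote
fraction (ties: smaller row, then column, then radius) with centers kept
at least `min_separation` (default r_min) apart. Centers are refined to
sub-pixel precision by the 3×3 vote centroid.

`vote_frac_min` defaults to **0.35**: the inner boundary ring of a digital
disk splits its votes between two adjacent accumulator radii, so even a
noiseless disk's peak carries only ~0.47–0.64 of 2πr (large radii sit at
the low end). 0.35 leaves margin for noise-eaten boundaries while still
demanding more than a third of a circumference of support. The radius band
is derived from the expected particle radius as ±20% unless set
explicitly.

## Square detection and Feret refinement

Components surviving the square-keeping pass with √area within the side
band become rough candidates (center = centroid, halfside = √area/2,
score = extent). Refinement Gaussian-smooths each component patch
(σ = 1 px), re-thresholds at 0.5, and sets halfside = Feret_max/(2√2) —
for a square the Feret maximum is the diagonal. Candidates whose refined
area departs from the cohort median by more than 1.5× (either direction)
are dropped: merged/overlapping particles are area outliers. A single
candidate is its own median and is always kept.

## Evaluation

Detection-level: greedy one-to-one nearest-center matching, a pair
acceptable iff shapes agree and the distance is within the tolerance
(default: that truth particle's radius/half-side). From TP/FP/FN:
recall = TP/(TP+FN), precision = TP/(TP+FP), accuracy = TP/(TP+FN+FP),
misclassification = FN/(TP+FN), Dice = 2TP/(2TP+FP+FN), F1 = harmonic mean
of recall and precision, all as percentages; undefined ratios (zero
denominator) are reported as NaN rather than 0. Across images all metrics
average arithmetically except F1, which is recomputed as the harmonic mean
of the *averaged* recall and precision — the convention that makes the
aggregate table internally consistent. (The TN-based accuracy and
misclassification forms that appear in some treatments are dimensionally
incoherent for detection, where no TN exists; they remain available for
pixel-level mask scoring behind a `literal` flag.) Pixel-level scoring
compares binary masks directly (Dice, accuracy, misclassification).

## Synthetic scenes

The generator renders what the picker assumes and nothing more: a
background plane (default level 0.6) with an optional low-frequency
sinusoidal gradient; dark disks and axis-aligned squares at
background − contrast with a 1-px anti-aliased rim; irregular ice-like
blobs (thresholded smoothed Gaussian fields, largest connected chunk,
softened rim) as realistic negatives for the roundness/extent filters; and
i.i.d. Gaussian pixel noise added last. Placement is rejection-sampled so
shape rims stay `min_separation` apart (capped at 10⁴ attempts, then a
placement error reporting the achieved count); ice blobs are re-drawn up
to 50 times to avoid swallowing particles, so ice rejection is measured
separately from occlusion. Everything derives from one seed;
suites spawn per-scene seeds from it.

Presets (heights×widths are the nominal frame sizes; tests and the
acceptance script run them at 512×512 to keep a full 10-image suite within
seconds — problem sizes chosen as the package's own benchmark scale):

* `easy` — 12 sparse disks, contrast/noise 7.
* `apoferritin_like` — 30 dense disks of radius 10–14, contrast 0.30,
  noise σ 0.15 (contrast/noise 2.0), mild gradient.
* `klh_like` — 12 disks (r 16–22) + 8 squares (side 26–36) + 5 ice blobs,
  contrast/noise 2.5, 2048² nominal.
* `hard` — 25 disks, contrast/noise 1.2, overlaps allowed, ice.

What the generator does **not** model: physical image formation (CTF,
detector MTF, 3D projection), structured/correlated noise, carbon edges,
or particle texture. Passing the synthetic suites therefore demonstrates
the geometry/intensity logic of the pipeline — separability, shape
discrimination, clutter rejection — not performance on real micrographs,
whose contrast transfer and background structure are materially harder.

## Known limitations

* Squares rotated ~45° fail the axis-aligned extent criterion and are
  lost; arbitrary-orientation side views would need a rotated-rectangle
  fit.
* Small side views (s ≲ 14 px) exceed the 0.9 circularity cut because of
  digital-perimeter bias and are eliminated — the same failure mode the
  two-stage square path is known for; on the mixed suite this costs a few
  of the 8 squares per image.
* Rarely (about one pick in two thousand on the mixed suite), a rounded
  edge of an ice blob musters just over the 0.35 vote fraction and yields
  a false circle; true-circle scores bottom out near 0.40, so the margin
  is too thin to raise the threshold without losing real particles.
* Touching particles are not split (no watershed); heavily overlapped
  clusters either merge into one component (rejected by the area cap or
  the Feret outlier rule) or are picked once.
* The MRC reader handles the common modes (0, 1, 2, 6) and rejects
  anything else rather than guessing.
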