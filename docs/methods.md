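# Methods

## Problem and procedure

The package measures *background informativeness*: how much healthy-vs-sick
signal remains in a leukocyte microscopy image after every annotated cell
is removed.  Removal is deliberately crude — each bounding box is filled
with black — so that no cell shape or texture information survives.  The
blacked-out pixels are tracked by a boolean mask and excluded from every
downstream statistic; exclusion is driven by the mask, never by detecting
black pixels, so legitimately dark background pixels are retained.

Each image is then reduced to a single feature vector: the density
distribution of one channel's pixel values over 30 equal-width bins
spanning the channel's full range.  Binning over the fixed range (rather
than each image's own min/max) keeps all images on one grid.  Hue is kept
on the half-degree integer-friendly scale [0, 180) common to 8-bit image
libraries; saturation and value are rescaled to [0, 255].  Histograms are
computed at native image resolution.

Classification quality — accuracy and per-class precision/recall/F1,
averaged over 30 repeated random 2/3-train / 1/3-test splits — is the
informativeness measure.  Splits are regenerated from `base_seed + repeat`
and shared across all grid cells of a repeat, so obfuscated and unmodified
conditions are compared on identical partitions.  Per-repeat metrics are
stored alongside the averages; the standard deviation over repeats
quantifies split-to-split dispersion.

## Classifiers

**Divergence to representatives.**  Class representatives M₀, M₁ are
bin-wise means of the training densities (renormalized to unit sum against
float drift).  Divergences of *all* training samples to each representative
form two pools whose means and population standard deviations (m₀, s₀, m₁,
s₁) z-normalize the test divergences; the smaller normalized divergence
decides the class, with exact ties going to healthy.  Pooling all training
samples (rather than only the matching class) is the procedure implemented;
a `per_class_stats` switch provides the class-restricted variant for
comparison.  Cross-entropy uses the natural log with a guard
`log(q + 1e-12)` because background histograms routinely contain empty
bins; the z-normalization makes predictions invariant to the log base
(asserted in tests).  The MSE divergence is the plain sum of squared bin
differences.  Fitting fails loudly if a class is missing, has fewer than
two samples, or a divergence pool has zero spread.

**Entropy classifier.**  Shannon entropy of the density vector, by default
normalized to [0, 1] by log(n_bins) so values are comparable across bin
counts, feeds a one-feature logistic regression.  Raw nats are available;
the choice of scale only relabels the feature axis and cannot change the
fitted classifier's decisions.

**Baselines.**  XGBoost and logistic regression consume the raw 30-bin
vector with library-default hyperparameters (logistic regression's
iteration cap raised to 1000 for convergence on small n); the exact
parameter map is exportable per seed for results metadata.  Both are
seed-controlled and single-threaded for reproducibility.

## Augmentations

Augmentation is always applied before obfuscation, so the black fill is
exact in the final image.  Gaussian blur uses a normalized truncated
Gaussian kernel of the requested size with σ = 0.3·((k−1)/2 − 1) + 0.8,
the standard kernel-to-σ convention of mainstream image libraries; median
blur takes the window median.  Both use reflective borders, avoiding dark
frame halos that would contaminate background histograms.  Multiplicative
Gaussian noise computes ⌊x·(1+n)⌋ with n ~ N(0, σ) drawn independently per
pixel per channel, clamped to [0, 255]; the configured parameter is the
distribution's standard deviation.  The augmentation study grid uses blur
kernels {3, 9, 21, 51} and noise parameters {0.0001, 0.01, 0.1}.

## Color conversion

The primary RGB→HSV path is the hexcone (max/min sector) formula, chosen
because it reproduces the half-degree hue encoding the pipeline's
histograms are defined on.  An arccos chromatic-plane formulation is
provided as a documented alternative; the two agree to floating-point
precision for chromatic pixels and both map achromatic pixels to hue 0
(tests cross-check them against each other and against scikit-image on
random pixels, within one 8-bit unit).  Hue distances are shortest arcs on
the circle, in [0, 180°].  Histogram binning of hue is linear on [0, 180)
with no circular wrap — the feature is a distribution, not a distance, and
bin 0 / bin 29 adjacency is irrelevant to every classifier used.

## Synthetic data generator

The generator emulates the *structure* of a single-cell smear benchmark,
not its optics: a balanced two-class set of 128×128 RGB images, each with
one roughly central stained-lymphocyte blob (an irregular filled ellipse,
radius 18–30 px, purple at hue 280°, annotated by its tight box), 3–8
pale, low-saturation red distractor disks that are *not* annotated (only
lymphocytes are obfuscated), additive pixel noise (σ = 6), and a background
whose per-pixel hue follows a class-conditional von Mises distribution.

Defaults place the class contrast in the background, where the audit looks
for it: healthy hue mean 330° with concentration κ = 10, sick 270° with
κ = 4 — hue modes 60° apart, the sick background visibly more dispersed
(hence higher Shannon entropy), saturation and value ranges shared between
classes.  The study-scale dataset is 130 images per class.  An optional
per-class `background_hue_jitter` (default 0) shifts each image's hue mode
by a random offset, producing class structures that are non-linear in bin
space (a narrow mode at a random location cannot be separated from a wide
fixed mode by any linear functional of the histogram); it is used to probe
classifier flexibility and off by default.

All randomness flows through one dataset seed; each image draws from a
counter-derived substream, so any single image is reproducible without
generating the rest.

What passing on synthetic data does **not** show: robustness to staining
chemistry, illumination gradients, cell clumping, focus variation, or
realistic erythrocyte texture — none of which are modeled.  The generator
establishes that the *pipeline* recovers a planted background signal and
reports chance when none exists; conclusions about any real dataset
require running the audit on that dataset.

## Numerical choices and degenerate inputs

- Histogram of a fully masked image raises an explicit error; a zero
  vector is never returned.
- Density vectors must sum to 1 within 1e-9 and are validated on
  construction.
- Degenerate hue concentration (κ = ∞) renders an exact-mean background;
  8-bit RGB quantization reintroduces up to ~2° of hue spread.
- Metrics with zero denominators (no predicted or no actual positives)
  report 0 and set a `degenerate` flag rather than raising.
- A failing grid cell (e.g. divergence fitting on zero-spread densities)
  is recorded with its error message; other cells proceed.

## Problem sizes

Study-scale runs use 260 images of 128×128 pixels with 30 repeated splits —
large enough that binomial noise on a 87-image test set (SE ≈ 0.054) is
well below the planted effect sizes, and small enough that the full grid
runs on a laptop core in minutes.  Unit tests use 64×64 images and reduced
repeat counts.

## Known limitations

- Bounding boxes are an input; the package does not detect or segment
  cells.  Real-data audits need user-supplied boxes.
- Only binary classification is supported.
- The divergence classifier's pooled (not per-class) normalization
  statistics are kept for fidelity to the procedure it implements; the
  per-class variant often differs and is exposed but not the default.
- Printed entropy magnitudes depend on the normalization convention;
  only orderings and classification quality are treated as comparable
  across studies.
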