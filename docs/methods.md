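# Methods

This note documents the models and procedures implemented in
`conspicuity`, the defaults they ship with, and what the synthetic ground
truth does and does not establish.

## Conspicuity channels

Channel extraction follows the classic center–surround pyramid
architecture of bottom-up saliency models.

**Pyramid.** Each plane is reduced by repeated Gaussian blur (σ = 1 px,
reflect boundary) followed by bilinear resampling to `ceil(n/2)` on the
pixel-center grid.  This resampling is symmetric, so mirroring an image
mirrors its maps to floating-point precision — a property plain
every-other-pixel decimation does not have.  Depth adapts to the image:
`min(9, floor(log2(min(h, w))) − 1)` reduction steps; center–surround
pairs use centers {2, 3, 4} and surround offsets {3, 4}, skipping pairs
whose surround level does not exist (at least one pair must; images must
be ≥ 64 px per side).

**Center–surround.** For a plane `M`, each pair (c, s = c + δ) yields the
rectified across-scale difference `|M_c − resample(M_s)|`.  Maps whose
dynamic range falls below 1e−9 are treated as exactly zero so that flat
inputs produce identically zero channels rather than amplified rounding
noise.

**Intensity** operates on `(r + g + b)/3`.

**Color** first divides r, g, b by luminance wherever luminance exceeds
2% of its maximum (decoupling hue from intensity; the threshold is set low
enough that a near-black bar of the distractor hue is treated as the same
hue, which is what makes an intensity-only singleton invisible to the
color channel).  Broadly tuned responses R, G, B, Y are formed and opposed
into signed planes RG = R − G and BY = B − Y, and each signed plane is
split into its rectified ON and OFF halves (RG⁺, RG⁻, BY⁺, BY⁻ — the two
polarities of a double-opponent population) before center–surround.  The
split matters for pop-out: a lone green item among many red ones owns a
single-peak RG⁻ map that survives the peak-promotion operator, while the
many-peak RG⁺ map is suppressed.  A single signed map cannot do this —
red↔green opponent contrast is symmetric, so singleton and distractors
score identically there and the global max is decided by resampling noise
(we measured exactly this failure before adopting the split).  The
construction is exactly symmetric under swapping the red and green planes.

**Orientation** applies a complex Gabor bank (wavelength 7 px, bandwidth
1, orientations 0°/45°/90°/135°, labeled by the bar orientation that
maximally excites each kernel) to the intensity pyramid levels and takes
response magnitude; center–surround differences are computed per
orientation and only merged after normalization, which is what lets an
orientation singleton survive among iso-oriented distractors.  Convolution
pads symmetrically (edge replication on levels smaller than the kernel —
`scipy.ndimage.convolve`'s own boundary handling is unreliable when the
kernel exceeds the image, which we hit on coarse pyramid levels).

**Normalization.** `N(M)` rescales to [0, 1] and multiplies by
`(1 − m̄)²`, where `m̄` is the mean of all local maxima above 0.1 except a
single instance of the global maximum (local maxima via a maximum filter
of size `max(3, min(shape)/10)`).  One iteration by default.

**Across-scale sum and output.** Normalized maps are resampled to pyramid
level 2 and summed (orientation: per θ first, then the θ-sums are
normalized and added).  Level 2 keeps one coarse pixel at 4 px on a
900×900 stimulus, so the upsampled argmax localizes targets to a few
pixels; summing at level 4, as some classic descriptions do, quantizes the
argmax to a 16 px grid, which is too coarse for the 10 px localization the
validation suite demands.  The sum is bilinearly upsampled to image
resolution, clipped at zero, and max-normalized to 1 so maps are
comparable across channels (histogram binning, regression targets).

## Density maps

Saccade landing pixels of all subjects are pooled into one binary map
(duplicates collapse; an optional saccade-order cutoff, default 5, keeps
only each subject's first saccades).  The map is blurred with a Gaussian —
σ defaults to 2% of the image diagonal, roughly 1° of visual angle at
typical free-viewing geometries — and max-normalized.  The blur uses a
zero boundary, so mass is conserved for interior fixations (scipy
renormalizes the discretized kernel).  Pooling before smoothing (rather
than averaging per-subject maps) is the documented convention.

## Metrics

* `correlation2d` implements the normalized inner product without mean
  subtraction.  It is **not** Pearson correlation: on nonnegative maps it
  lies in [0, 1], equals 1 for any positive rescaling, and is undefined
  (raises) when an operand is identically zero.
* `histogram_entropy` / `mutual_information` rescale each map to [0, 1] by
  its maximum and bin into 256 (entropy) or 32 (MI, i.e. a 32×32 joint)
  equal-width bins by default.  Marginals are taken from the joint
  histogram, making the estimate symmetric and nonnegative to rounding.
  32 bins keeps the positive bias of the plug-in estimator (≈ bins²/2N ln2)
  near 0.01 bits at typical map sizes.
* `auc_fixation` uses the rank (Mann–Whitney) formulation with ties
  counted ½, which equals the trapezoidal threshold-sweep ROC area.
  Positives default to raw saccade landing pixels; a quantile-binarized
  density map (top 5%) is available as an alternative mode, and the mode
  in force is recorded in the run manifest.
* `winner_tally` splits exact ties fractionally among tied features.
* `significance_label` runs a paired two-sided t-test across images and
  maps p ≥ 0.05 → NS, 1e−5 ≤ p < 0.05 → S, p < 1e−5 → HS.  The S band
  deliberately covers the full gap between the other two thresholds.
  Identical score vectors report NS with p = 1.

## Weight estimation

**Per image (least squares).**  `W_best = (XᵀX)⁻¹ Xᵀ D` is solved
literally from the normal equations, unconstrained — weights may be
negative, and summary tables report both signed and truncated-at-zero
means.  A condition number above 1e12 on `XᵀX` raises an error naming the
most collinear column pair.

**Per dataset (genetic algorithm).**  Fitness of a weight triple is the
mean over images of the fixation AUC of the rectified combined map; since
AUC is rank-based, fitness is invariant to positive rescaling, so only the
direction of the weight vector is identified.  The population holds 60
chromosomes of 3 genes in [0, 2]; each generation keeps the single best
chromosome (elitism, which makes the best-so-far trajectory
non-decreasing), draws children from the 30 best by per-gene blend
crossover, mutates each gene with probability 0.1 by N(0, 0.1) noise
(clipped to bounds), and re-injects 10% fresh uniform chromosomes for
diversity.  Default 100 generations with early stop after 20 generations
without improvement; results are averaged over 10 independently seeded
runs.  Population evaluation is vectorized: one matrix product per image
and a sort + two binary searches per chromosome give exact tie-averaged
rank AUCs at about a tenth of the cost of generic ranking.

## Synthetic ground truth

**Stimuli.**  Search arrays are rendered on a mid-gray 900×900 canvas (the
geometry scales down proportionally for smaller canvases): red horizontal
bars on a jittered 8×8 grid (jitter ≤ 15% of spacing, cells under a target
are vacated, spacing must be ≥ 1.5 bar sides), plus targets deviating in
exactly one feature — green (color), the distractor hue at value 0.1
(intensity), or red rotated by a chosen angle (orientation).  Bar bounding
boxes follow the 7–37 px ladder in steps of 2 (level 10 = 25 px); bars are
1:4 anti-aliased rectangles inscribed in that box; targets land 250–360 px
from the canvas center at a random polar angle.  Competitive two-target
arrays place a green horizontal bar and a red oriented bar antipodally on
a random diameter with a shared radius in the same band; an optional
variant marks each target with 1–3 black dots.  Everything is
deterministic given the seed.

**Observers.**  Fixations are drawn i.i.d. from the probability field
proportional to a planted nonnegative mix `X·w` of the image's own three
channel maps, contaminated with a uniform-outlier fraction (default 0.05)
and Gaussian landing jitter (default 1% of the image diagonal), for 11
subjects × 5 saccades per image by default — the cohort size and
first-5-saccade convention of typical free-viewing corpora.  Dataset
bundles mix bar arrays and smooth random textures (seeded colored noise
with an embedded oriented grating so the three maps are never collinear;
bundles regenerate a texture if the feature Gram matrix conditions above
1e8), and record per scene the exact mix, the fixations, the saccadic and
density maps, and the shared true weights.

**What the synthetic data does not show.**  The generator validates the
machinery, not human vision: real fixations are sequential, center-biased,
and top-down modulated, none of which the i.i.d. planted mixture emulates;
natural-image feature maps are far more correlated than the textures used
here; and the planted-truth AUCs (≈ 0.55–0.6) are much lower than on real
gaze data because the planted mixtures are spatially diffuse.  Passing the
validation suite therefore demonstrates correct implementation and
recoverability of planted structure, not any empirical claim about
observers.

## Numerical and degenerate-case choices

* Constant or empty maps: channels return exactly zero maps; correlation
  with a zero operand and AUC with empty/full positive sets raise typed
  errors; density construction refuses an all-zero saccadic map.
* Winner ties are split fractionally (measure-zero on real data, common on
  tiny fixtures).
* `combine_saliency` clips negative pixels (possible under signed LSE
  weights) before rescaling to max 1; rescaling never affects AUC.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; report bundles contain no timestamps, so a
  rerun with the same configuration and seed is byte-identical.
* Validation problem sizes: metric cross-checks use 100 random 16×16 map
  pairs; weight-recovery and GA studies use 10–20 scene bundles at
  128×128; pop-out localization uses 20 seeded 900×900 arrays per feature
  at bar level 10.
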