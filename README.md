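# conspicuity

How much do the three early visual features — **color**, **intensity**, and
**orientation** — inherently contribute to where people look?

`conspicuity` is a toolkit for answering that question computationally.  It
extracts the classic bottom-up conspicuity maps of each feature from an
image, turns eye-tracking fixations into smoothed human density maps,
scores each feature's agreement with gaze, and estimates how the three maps
should be combined into a saliency map — per image in closed form, and per
dataset with a genetic optimizer.  A synthetic stimulus and observer
generator provides fully labeled ground truth (visual-search pop-out arrays
and planted fixation mixtures), so the entire pipeline can be validated
without any eye-tracking hardware or downloads.

## The model

For an image, three channel maps are computed in the style of the classic
Itti–Koch–Niebur architecture: Gaussian pyramids, rectified center–surround
differences `|M_c − M_s|` between fine and coarse levels (centers
{2, 3, 4}, surround offsets {3, 4}), a peak-promotion normalization
`N(M) = M · (M_max − m̄)²` with `m̄` the mean of the other local maxima, and
an across-scale sum, upsampled back to image resolution.  The color channel
operates on luminance-normalized red–green and blue–yellow opponency
planes, split into rectified ON/OFF polarity pairs; the orientation channel
uses Gabor energy at 0°, 45°, 90° and 135°.

Given the three maps flattened into the columns of `X` (order: color,
intensity, orientation) and a human density map `D` (pooled saccade landing
pixels, Gaussian-blurred, max-normalized), the package estimates
combination weights two ways:

* **per image** — the least-squares solution of `X W = D`:
  `W_best = (XᵀX)⁻¹ Xᵀ D`, signed and unconstrained;
* **per dataset** — a single static weight triple maximizing the mean
  fixation AUC of `X W` across all images, found by a real-coded genetic
  algorithm (60 chromosomes of 3 genes, 30 parents, blend crossover,
  Gaussian mutation, elitism, random re-injection, averaged over seeded
  runs).

Agreement between maps is scored with three metrics:

* 2-D correlation `C(A,B) = Σ a·b / √(Σa² · Σb²)` — deliberately without
  mean subtraction, so nonnegative maps score in [0, 1];
* mutual information `MI(A,B) = H(A) + H(B) − H(A,B)` in bits, from
  (joint) intensity histograms of the maps rescaled to [0, 1];
* fixation AUC — the probability that a fixated pixel outranks a
  non-fixated one in saliency (Mann–Whitney form, ties ½).

## Worked example

```python
import conspicuity as cp

# 8 synthetic scenes whose fixations follow the planted mix
# 0.2*color + 0.1*intensity + 0.7*orientation
bundle = cp.make_synthetic_dataset(8, true_weights=(0.2, 0.1, 0.7),
                                   seed=0, out_dir="demo_ds")

cfg = cp.RunConfig(dataset_dir="demo_ds", output_dir="demo_report", seed=0)
cfg.ga.generations = 40
cfg.ga.n_runs = 3
report = cp.run_evaluation(cfg)
report.write("demo_report")
```

Printing the headline numbers of that run:

```
mean AUC color       0.5040  vs others: NS
mean AUC intensity   0.5255  vs others: NS
mean AUC orientation 0.5632  vs others: S
AUC winner percentages: {'color': 0.0, 'intensity': 25.0, 'orientation': 75.0}
LSE signed mean weights: {'color': 0.0277, 'intensity': 0.0907, 'orientation': 0.1882}
GA static weights: {'color': 0.1148, 'intensity': 0.0955, 'orientation': 1.6530} (mean AUC 0.5634)
```

Orientation — the feature planted with the dominant weight — wins the
per-image AUC comparison in 75% of the scenes, its mean AUC is
significantly larger than the other channels' (`S`: 0.001 < p < 0.05 on a
paired test across images), it receives the largest per-image least-squares
weight on average, and the genetic optimizer assigns it by far the largest
static weight.  The written report bundle contains the per-image score
table, winner tallies, per-image and summary weight tables, the GA report,
and a manifest from which the run is exactly reproducible.

The same pipeline runs from the shell:

```bash
conspicuity synth --n-images 8 --seed 0 --out demo_ds
conspicuity run demo_ds --seed 0 --out demo_report
conspicuity report demo_report
```

Fixation tables are plain CSV (`image_id,subject_id,x,y,order`, 0-based
pixel coordinates, `x` = column, `y` = row, origin top-left); datasets are
a directory with `images/` plus `fixations.csv`.

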