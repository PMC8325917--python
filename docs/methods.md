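# Methods

## Pipeline model

`treefuse` classifies individual tree crowns from three co-registered
airborne data products. Each crown is a rectangular bounding box in map
coordinates joined to a field record (individual id, taxon code, site,
plot). The two-stage design keeps the image model and the tabular model
separate: a convolutional classifier turns the crown's RGB crop into a
K-vector of taxon probabilities, and a small fusion perceptron combines
that vector with the hyperspectral and lidar features to produce the
final prediction. The stages are trained sequentially, not end to end.

### Crown geometry and raster conventions

Map coordinates are meters in a shared projected CRS. Rasters are
row-major from the north-west corner; a point belongs to the cell whose
half-open interval [lo, hi) contains it on both axes, so a coordinate
exactly on a cell edge falls in the cell with the larger index. Crown
clipping takes the cells whose centers fall inside the crown's bounding
box; non-rectangular polygons are replaced by their bounding box with a
warning. The hyperspectral feature is the single centroid-pixel
spectrum (no averaging over the footprint); stored reflectance is
divided by a scale factor (default 10000, the common convention for
uint16 reflectance products).

### Hyperspectral bad bands

The wavelength grid is 380 + 5k nm for k = 0..425. Atmospheric
water-vapour windows carry mostly noise; the default mask removes the
inclusive windows [1340, 1445] and [1790, 1960] nm — 22 + 35 = 57 bands,
leaving 369. The windows are configurable; the default configuration is
validated at load time (369 good bands exactly).

### Lidar pseudo-waveform

Height anomalies (below-ground echoes from timing errors, spuriously
high returns) are removed per point-cloud file by keeping heights
within the 1st–99th percentiles (linear interpolation between order
statistics, inclusive bounds). Points inside the crown box are then
binned by height above ground into `n_bins` equal bins over
[0, `max_height`]; defaults are 39 bins over 0–40 m, i.e. a bin width of
40/39 ≈ 1.026 m. The bin count is the binding constant because it fixes
the lidar feature-block length at 40 (39 proportions + the total point
count); treating the nominal one-meter bin width as binding instead
would give 40 bins, and both `n_bins` and `max_height` are configurable
for that reading. Bins are half-open with the final bin closed; points
outside [0, max] after filtering go to the nearest end bin (logged)
rather than being dropped. An empty crown yields the all-zero waveform
so the pipeline stays total on sparse data.

### RGB stage

Crops are standardized by resizing the short side to the target
(default 224 px, bilinear; slivers are upsampled), center-cropping the
long side, and normalizing each channel with ImageNet-style means and
stds (configurable constants, not hard-coded). The classifier is a
compact convolutional network implemented in numpy: the standardized
chip is average-pooled to `input_side` (default 32 px), passed through a
stack of 3 × 3 conv + rectifier blocks (channel widths 8 → 16 → 32,
spatial pooling after the first two blocks), global average pooling,
and a linear softmax head. The named encoder depths (18, 34, 50, 101,
152) select progressively deeper stacks of this design, and `"small"`
(one block) is the default; weights are randomly initialized, so the
depth-comparison harness exercises the selection procedure (max
validation macro F1, ties to the smaller depth) rather than any
pretrained ranking. Training is minibatch SGD with cross-entropy under
a one-cycle schedule, split by individual 80/20.

### Fusion network and soft F1 loss

Features are concatenated in fixed order rgb | reflectance | lidar
(440 elements when K = 31). Inputs are z-scored with statistics fit on
the training split: the total-point-count feature is O(10²) while
reflectances are O(1), which plain SGD at the reference learning rate
cannot absorb otherwise. The network is input → 64 → 32 → K with
rectifier activations and a softmax output.

The training objective is the per-example soft F1 loss
L(θ) = K⁻¹ Σₖ [1 − 2θₖyₖ/(2θₖyₖ + θₖ(1−yₖ) + (1−θₖ)yₖ + ε)], ε = 1e−7,
averaged within each minibatch. The denominator simplifies
algebraically to θₖ + yₖ + ε, and for one-hot y the loss collapses to
1 − 2θₜ/(K(1 + θₜ + ε)): it depends on θ only through the true-class
probability, is strictly decreasing in θₜ, equals 1 exactly at θₜ = 0
and approaches (K−1)/K as θₜ → 1. Its gradient with respect to θₖ is
−2yₖ(yₖ+ε)/(θₖ+yₖ+ε)²/K, backpropagated through the softmax. A
cross-entropy switch exists for baselines.

Reference optimization settings are batch 64, 20 epochs, one-cycle
schedule peaking at 1e−2 (linear warm-up from max/25 over the first 25%
of iterations, cosine decay to max/100 — the named policy does not fix
these shape constants, so they are configuration). The optimizer is
momentum-free SGD with optional L2 weight decay on weight matrices
(default 1e−3, biases excluded). Two additions matter at small sample
sizes:

- **Step count, not epoch count, governs convergence.** Twenty epochs
  at batch 64 assumes roughly a thousand training crowns. The pipeline
  defaults for synthetic scenes (~10² crowns) therefore run 2000 epochs
  to restore a comparable number of SGD updates; the library default
  keeps the reference 20.
- **Restart ensembling.** `n_restarts` trains several identically
  configured networks from different initializations and averages their
  probabilities (pipeline default 3, library default 1). Single runs
  occasionally settle in optima that fit the training set through
  non-generalising directions of the lidar block or plateau just below
  the open-set confidence threshold; averaging removes this
  initialization variance. The features themselves are linearly
  separable in these scenes (verified against a regularized logistic
  oracle), so this is purely an optimization safeguard.

### Open-set post-processing and evaluation

If the maximum fusion probability is below the threshold (0.5), the
"Other" class receives a fixed mass (0.5) and the original entries are
scaled by (1 − mass)/Σθ; at or above the threshold the vector passes
through with Other = 0. The rule preserves the ranking of the original
classes. Hard labels are the argmax of the augmented vector, ties to
the lowest index. The threshold and mass are configuration values; the
reference values come from inspection of probability histograms and
have no reproducible derivation.

Evaluation reimplements the standard classification-report
aggregation: one-vs-rest precision/recall/F1 with the
zero-denominator-gives-zero convention, macro F1 as the unweighted mean
over all report classes (zero-support classes included), weighted F1 by
support fraction, accuracy, and cross-entropy as the mean −log of the
probability assigned to the true class, clipped to [1e−15, 1] (the clip
is configurable; reported competition-style cross-entropies near 11.6
imply clipping of near-zero probabilities). The reduced confusion
matrix maps any true taxon outside the training classes to "Other".

## Synthetic scenes

The generator emulates the structure of the real products, not their
physics. Each 20 m × 20 m plot holds up to `crowns_per_plot`
non-overlapping rectangular crowns (rejection-sampled, side 2.5–5 m)
whose taxa are drawn from a geometric-decay abundance (0.8ᵏ) so one
class dominates, mimicking real census skew. Per taxon, an archetype
fixes a smooth random 426-band reflectance signature (pairwise distinct
by at least `min_separation` = 0.02 somewhere on the grid), a crown
colour from the hue wheel, and a Gaussian height profile (means spaced
6–34 m, sd 1 m). Rasters get the archetype values plus additive
Gaussian noise (defaults: 0.01 reflectance, 0.02 colour); the point
cloud is Poisson with the reference density 3.15 pts/m², uniform in
x–y, with crown points drawing heights from the taxon profile and open
ground from a 0–1.5 m understory layer. Height-anomaly injection adds
points strictly outside the original height range.

What passing tests on these scenes shows: dimensional and format
contracts, label recoverability through the full stack, loss and
post-processing algebra, and that the training machinery can fit and
generalize when classes are separable. What it does not show:
robustness to shadows, crown-boundary mixing, co-registration error,
phenology, or spectra whose class overlap resembles real congeneric
species — synthetic class separations are far cleaner than field data,
so accuracy numbers on synthetic scenes say nothing about accuracy on
real campaigns.

## Problem sizes and determinism

Tests and the acceptance script use scenes of 4–14 training plots and
2–4 test plots with 3–6 taxa (roughly 20–90 training crowns), the
pipeline defaults above, and fixed seeds; the acceptance script derives
every random stream from its `--seed`. Identical configuration and seed
give bit-identical scenes and training trajectories (pure numpy, no
threading nondeterminism).

## Known limitations

- The RGB backbone is compact and randomly initialized; it stands in
  for large pretrained encoders in structure (configurable depth,
  fine-tuning harness, probability output) but not in capacity, and
  depth comparisons on synthetic chips carry no information about
  which depth would win on real imagery.
- Crowns must fall within a single tile; no mosaicking or CRS
  reprojection.
- The exact band subset behind the published 369-band count is not
  recoverable; the default windows are standard water-vapour regions
  chosen to remove exactly 57 bands and are configurable.
- Percentile interpolation, bin-edge, and cell-membership conventions
  are documented choices where the field has no single standard.
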