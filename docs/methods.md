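# Methods

## Problem and model

The task is two-class semantic segmentation of 3D point clouds of pot-grown
seedlings: every point is either *stem* (label 1) or *other* (label 0 —
leaves, petioles, soil, pot, background planes, outliers). The model is a
hierarchical encoder/decoder over unordered point sets.

**Encoder.** The input cloud (N points, 3 coordinates, normalized to the
unit sphere) is lifted per point to the first feature width, then passes
four set-abstraction stages. Each stage: (1) farthest-point sampling selects
N/4 centroids (greedy max-min, first pick = point 0; point order is
shuffled per epoch during training, so the start is random in training and
deterministic in evaluation); (2) a ball query collects up to K points
within radius r of each centroid, nearest-first, padding short neighborhoods
by repeating the nearest in-ball point; (3) neighbor features concatenated
with neighbor-minus-centroid offsets pass a shared two-layer perceptron and
are max-pooled over the group. Default schedule: points
[4096, 1024, 256, 64, 16], channels [64, 128, 256, 512, 1024], K = 32,
radii [0.1, 0.2, 0.4, 0.8] in normalized units (single-scale grouping).

**Decoder.** Four feature-propagation stages mirror the encoder (widths
reversed: [512, 256, 128, 64]). Each interpolates the coarser features onto
the finer point set with inverse-distance weights over the 3 nearest coarse
points, w_j ∝ 1/(d_j + 1e-8) normalized to sum to one, concatenates the
encoder skip features of that resolution, and applies a pointwise
perceptron. The per-point head is one hidden conv–BN–ReLU block at the
finest decoder width followed by the linear classifier; softmax gives
probabilities.

**CRA-MLP.** Every perceptron in the backbone is a conv–BatchNorm–PReLU
stack (PReLU slope per channel, initialized 0.25) followed by channel
attention and a residual: ω = σ(W₂ relu(W₁ avgpool(FD))) with bias-free
W₁ ∈ R^{C×C/4}, W₂ ∈ R^{C/4×C}, and output = FD·ω + FD. The gate
re-weights channels using global (per-cloud) statistics; the residual
guarantees the block can never lose information relative to its stack.

**PESA.** At the attention site, centroid coordinates P are lifted by a
bias-free conv–BN–ReLU to the feature width (Pi), gated by a feature-
attention layer — sigmoid of a linear map of the row-summed gram matrix
Pi Piᵀ, averaged over points so the gate's pre-activation has unit scale
regardless of stage size — and fused multiplicatively with the features:
F' = Po ⊙ Fi. Offset self-attention follows: Q, K (width C/4) and V
(width C) are bias-free linear maps of F'; E = QᵀK (no scale factor — none
is part of the design); a = softmax over the query axis; A = a row-normalized
over keys (1e-9 guard), so A is row-stochastic; Fsa = A V; and the output is
Fo = CBR(Fsa − F') + F' with CBR = conv–BN–ReLU. Two published readings of
the gate formula (gate inside vs outside the lifting perceptron) collapse to
the same computation once the lift is named Pi; the gate can also be
disabled (`position_gate="none"`).

**PESA placement.** The default places one PESA block at the bottleneck
(the coarsest encoder output, where "global feature integration" happens);
`pesa_placement="all"` instead applies one per encoder stage. The default
was chosen after desk-scale experiments: with a PESA at every stage, the
multiplicative position gating repeatedly zeroes feature entries (ReLU-gated
Po has many zeros) and held-out mIoU dropped by 8–10 points; at the
bottleneck the block is neutral-to-positive. At full scale the per-stage
variant remains available but is not the default.

**Loss.** Cross-entropy is the mean over points of −log p at the true class
(probability floored at 1e-12). Dice is computed per class on soft
probabilities, 1 − (2·Σpy + ε)/(Σp + Σy + ε) with ε = 1e-5, macro-averaged
over classes; for a batch it is computed per cloud and then averaged, so
each cloud's overlap counts equally no matter how few stem points it has.
The hybrid loss is w_ce·CE + w_dice·Dice with both weights 0.5 by default
(the published description leaves the weights open; equal weighting is the
neutral choice and both are exposed in config and CLI).

**Training.** Adam (first-moment coefficient 0.9 — "momentum" in the
optimizer-schedule sense), batch size 6, cosine learning-rate decay from
1e-3 at epoch 0 to 1e-5 at the final epoch, 150 epochs at full scale. Two
published statements of the batch size disagree (6 in the experimental
settings, 8 in the algorithm box); 6 is used. Training is deterministic
given the seed; evaluation mode is deterministic outright.

## Metrics

mIoU, mP, mR and mF1 derive from per-class TP/FP/FN counts accumulated over
the whole evaluation set (micro over points), then averaged over classes and
reported as percentages to one decimal. A class with TP+FP+FN = 0 (possible
in degenerate early-growth clouds with no stem points) is excluded from the
class mean with a warning. Per-cloud-then-average aggregation is *not* used:
the metric definitions contain no per-sample index. Speed is clouds
segmented per second (reciprocal of mean per-cloud inference time),
inference only — preprocessing is excluded.

## Data pipeline

Statistical outlier removal scores each point by its mean distance to its k
nearest neighbors and removes points above mean + std_ratio·std of that
score (defaults k = 16, std_ratio = 2; the published pipeline names the
method but not its parameters). Augmentation expands each specimen fourfold:
the original, a rotation by U[0, 2π) about the vertical axis (gravity
orientation is meaningful for plants; full-3D rotation is configurable), a
per-point Gaussian jitter (σ = 0.01) clipped at 0.05, and unclipped Gaussian
noise (σ = 0.02), all in normalized units. Jitter and noise are deliberately
distinguished as clipped vs unclipped perturbations — the published
pipeline treats them as distinct augmentations without defining the
difference. Splits are grouped by specimen: a "4:1" ratio resolves to train
fraction 0.8 applied with floor to the origin count, which is the only
reading that reproduces a 952/240 entry split from 298 specimens × 4
variants; k-fold cross-validation partitions origins into folds differing
by at most one origin.

## Synthetic scenes

The generator emulates the structure of scanned cucurbit seedlings, not
their appearance. A scene is assembled from parametric surfaces in a z-up
frame with the soil plane at z = 0: a curved stem tube (cubic-polynomial
spine, default length 0.35, radius 0.008 scene units) whose base sits 0.02
below the soil so the stem/soil boundary is genuinely ambiguous; drooping
elliptical leaf patches and petiole tubes (labeled other); a soil disk, pot
shell, optional wall and table planes; and uniform outliers in the 1.5×
inflated bounding box. Surface point budgets are proportional to area
(background planes down-weighted ×0.15 to mimic sparser background
returns), with a largest-remainder allocation making the total exact.
Presets cover the scene families a stem segmenter must handle: simple,
multi-branch, cluttered/noisy, two-plant, and early-growth (stem < 5% of
points — the class-imbalance stressor). Morphology parameters are plausible
stand-ins; no quantitative morphology statistics of real seedlings were
available to fit them.

What passing on synthetic scenes does and does not show: the scenes
reproduce the geometric confusions of real scans (stem/soil adjacency,
petiole-stem similarity, background clutter, outliers, imbalance) but not
sensor noise models, occlusion patterns of a real camera path, leaf venation
or self-intersecting geometry. Results transfer as evidence the pipeline and
optimization work, not as field accuracy estimates.

## Desk-scale benchmark

The reference run (`stemseg.benchmark`) uses 120 scenes of 1024 points from
the default preset sampler, split 4:1 grouped (96 train / 24 held-out
origins), 30 epochs, channels [48, 96, 192, 384, 768] (three-quarters of the
full schedule) with K = 32, batch size 6, hybrid loss; the baseline disables
CRA-MLP and PESA and trains with plain cross-entropy under the identical
data and schedule — the two endpoints of the published ablation structure.
Problem sizes keep the whole two-model run around ten to fifteen minutes on
one CPU. The width was settled by capacity: quarter widths underfit badly
(held-out mIoU in the low 70s) and half widths still left a few points on
the table; K = 32 matches the ~20-point occupancy of the first-stage ball
at the chosen radius. A head-dropout knob and an optional train-time
rotation flag exist but default off — both reduced held-out accuracy under
the 30-epoch schedule.

## Numerical choices

* Coordinates are float64 in I/O and preprocessing; the network runs
  entirely in float32 (features and sampling geometry).
* FPS runs on squared distances (same argmax); ties resolve to the lowest
  index, so results are reproducible across runs.
* Ball-query overflow is nearest-first; underflow pads with the nearest
  in-ball point (the centroid itself for isolated centroids).
* BatchNorm: momentum 0.1 running statistics, eps 1e-5; evaluation uses the
  running estimates.
* Max-pool backward splits gradient equally among ties.
* The degenerate single-point cloud normalizes to the origin with scale 1.
* Checkpoints store every parameter and buffer plus configs and history;
  save→load→evaluate reproduces metrics exactly.

## Known limitations

* The autodiff engine is minimal by design: no GPU, no mixed precision, no
  graph optimization; throughput is a few training steps per second at the
  desk-scale width. Full-scale (4096-point, full-width, 150-epoch) training
  is architecturally supported but not practical on one CPU.
* Parameter counts depend on perceptron depths and decoder widths that the
  published description does not fix; totals here are not comparable to
  published totals.
* The speed metric is reported for completeness; at desk scale it reflects
  this numpy implementation, not an optimized deployment.
* PCD support is the ASCII dialect only; binary PLY is not read.
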