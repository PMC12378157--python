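# Methods

## The model

`meddistill` implements teacher–student knowledge distillation for small
medical-image classification problems in the MedMNIST mould. A large,
frozen feature extractor (the *teacher*) and a compact trainable network
(the *student*) both see the same image `X_i`; each produces a length-`m`
logit vector `Z = (z_1 … z_m)` through a linear head. Logits are softened
by a temperature-`t` softmax

    P_i^soft = exp(z_i / t) / Σ_j exp(z_j / t),

and the student is trained on the convex mixture

    L_total = α · L_ce + (1 − α) · L_distill,
    L_distill = t² · KL( P_T^soft ‖ P_S^soft ),
    KL(p ‖ q) = Σ_i p_i ln(p_i / q_i),

where `L_ce` is the hard-label loss at `t = 1`: cross-entropy for
multi-class and ordinal tasks, mean per-label binary cross-entropy (with
per-logit sigmoids) for binary and multi-label tasks. All losses are
natural-log (nats) and per-sample batch means, so `α` is independent of
batch size and — because the `t²` factor sits inside `L_distill` — of
temperature. A numerical floor of 1e-12 guards every logarithm; the softmax
subtracts the row maximum, so logits up to ±1e4 are safe.

Conventions worth making explicit:

* **KL direction.** The loss is the *forward* KL from teacher to student,
  `t²·Σ P_T ln(P_T/P_S)`, the standard distillation form: it is
  non-negative, zero exactly when the softened distributions coincide, and
  its gradient in the two-class case pushes the student's logit gap toward
  the teacher's.
* **Multi-label soft targets.** A softmax across labels is meaningless when
  labels are independent indicators, so each label contributes the binary
  KL between `Bernoulli(σ(z_T/t))` and `Bernoulli(σ(z_S/t))`, averaged over
  labels and scaled by `t²`. This is this package's construction for the
  multi-label case; it reduces exactly to the two-class softmax form for a
  single label.
* **Binary tasks** use a 2-logit head, BCE against the one-hot target as
  the hard loss, the softmax KL as the soft loss, and the index-1 sigmoid
  as the positive-class score at evaluation time.

## Training procedure

Phase 1 (*linear probing*): the teacher backbone is frozen and only its
linear head is trained on extracted features — the backbone's parameter
bytes are identical before and after, by construction and by test. Phase 2
(*distillation*): teacher logits on the training set are computed once
(they are deterministic because the teacher is frozen) and cached; each
student batch takes an Adam step on the analytic gradient
`α·∂L_ce/∂z + (1−α)·∂L_distill/∂z`.

Optimization defaults follow the reference recipe: Adam (β₁=0.9, β₂=0.999),
base learning rate 1e-3, multiplied by 0.1 at the start of epochs 50 and 75
(0-based), up to 100 epochs, batch size 128 (32 for probing), early
stopping when the monitored validation metric has not improved for
`patience` = 15 consecutive epochs (ties count as no improvement). The
best-validation checkpoint is returned, ties resolving to the earlier
epoch.

One pitfall found while validating the loop: monitoring validation **AUC**
with ties-to-earlier selection returns a barely-trained epoch-1 checkpoint
whenever AUC saturates at 1.0, which it does readily on separable data.
`TrainConfig` keeps AUC as the configurable default, but the package's
desk-scale reference settings monitor validation **ACC**, which does not
saturate into ties and is the quantity the reference comparison reports.

## The NumPy network core

The package carries its own compact neural-network implementation
(`meddistill.nn`): convolution (im2col + BLAS), max/global-average pooling,
batch norm, linear layers and ReLU with hand-written backward passes, Adam,
a layer-for-layer ResNet-50 (bias-free convolutions, affine batch norm —
backbone 23,508,032 parameters, matching the canonical construction), and
forward-only ViT constructors with the DINOv2 dimensions: patch 14, qkv
bias, per-block layer-scale, class token, and position embeddings for the
native 37×37 grid (518 px), bicubically interpolated for other input
sides. The ViTs never need a backward pass: the teacher is frozen by
design and probing trains only the head on extracted features. Parameter
totals, floored to millions, land at 22 / 86 / 304 for S/14 / B/14 / L/14
and 23 for the ResNet-50 student with any MedMNIST-sized head (m ≤ 14) —
a 1000-way stock classifier would not reproduce the 23.

A "tiny" three-block CNN (~53k parameters, widths 24/48/96, global average
pooling) is provided for both roles at desk scale. It is test scaffolding,
not part of the reference method.

## Synthetic data

The generator emits the MedMNIST NPZ dialect (six keys, uint8 `n×28×28` or
`n×28×28×3` images, `n×1` index or `n×m` indicator labels) with known
class-conditional structure: class `k` of `m` is a Gaussian blob
(amplitude 200 over background 20, σ = 2 px by default) at angle `2πk/m`
on a ring of radius 0.32·side; multi-label samples draw each label
independently (p = 0.35) and superimpose one blob per active label;
ordinal grades sit at increasing radius on a fixed bearing so adjacent
grades are the most confusable. I.i.d. Gaussian pixel noise of scale
`noise_sigma` (0–255 units) is added and clipped to 8 bits. Identical
specs (including seed) reproduce identical bits.

What this emulates: the dialect, the task taxonomy (binary / multi-class /
multi-label / ordinal), spatially localized class evidence, and a
difficulty dial. What it does not: the texture statistics, anatomical
variability, label noise, and class imbalance of real medical images — so
green tests certify the pipeline's mechanics and the method's behaviour
under controlled conditions, not clinical performance.

Reference difficulty settings, chosen from the supervised baseline's
difficulty curve and then frozen: `noise_sigma = 25.5` (0.1 of range) is
the "easy" regime where the reference 20-epoch tiny-CNN run reaches ≥ 0.90
test accuracy; `noise_sigma = 180` is the "moderate" regime where the same
baseline lands near 0.85 (at 100 it is ≈ 0.99, at 220 ≈ 0.73).

## The reference comparison

`meddistill.experiments.distillation_benefit` runs the package's headline
measurement on 4-class moderate-noise data (800/200/200 splits). Every
stage uses the full reference protocol — Adam at 1e-3 with 0.1× steps at
epochs 50/75, up to 100 epochs, batch 128, early stopping on validation
ACC with patience 15. A tiny teacher backbone is supervised-pretrained to
convergence (standing in for large-scale pretraining), frozen, and
linear-probed to convergence; the student is then distilled at t = 2.0,
α = 0.2 (the strongest cell of the reference ablation grid), and the
paired α = 1 baseline trains the identically initialized student on the
same data with the same schedule. The comparison is the mean test ACC over
five seeds, distilled vs baseline.

Three details matter and were found the hard way (each is asserted by a
test or visible in the probe diagnostics): the probe head must be trained
to convergence — a head stopped early is underconfident and its softened
targets are nearly uniform, carrying no teacher signal; the teacher
backbone must be trained to convergence, not budget-matched to the
student, or it has nothing to teach; and both arms must get the
full-length schedule, because the distillation objective converges more
slowly than plain cross-entropy and a truncated schedule biases the
comparison against it. Problem sizes are desk-scale choices so the whole
comparison runs in under twenty minutes on one CPU.

## Evaluation

AUC is rank-based with ties counting one half: positive-class score for
binary, unweighted one-vs-rest macro over classes present for
multi-class/ordinal, unweighted mean over labels with both outcomes for
multi-label (classes/labels with a single outcome are skipped and logged;
an entirely single-outcome binary split raises an explicit error). ACC is
argmax accuracy (ties to the lowest index) for single-label tasks and the
per-label 0.5-threshold mean for multi-label. Scores are softmax
probabilities for single-label tasks and per-logit sigmoids otherwise,
always at `t = 1`.

## Visualization

Feature embeddings use t-SNE (perplexity 30 by default, seed mandatory,
`n > 3·perplexity` required). Heatmaps use gradient-weighted
class-activation mapping on the last convolutional block — channel weights
are the spatially averaged gradients of the class score, the weighted sum
is rectified, bilinearly upsampled, and max-normalized; for the
GAP-plus-linear architectures here the gradients are exact. A map that is
identically zero before normalization (the class score has no positive
evidence) is flagged as degenerate rather than rescaled.

A measured limitation: with a 7×7 last conv block (4-px cells, ~18-px
receptive field) and global average pooling, relevance cannot concentrate
into a 2σ (4-px-radius) disc around a blob — a fully converged model puts
only ~8% of mass there (uniform would be 6.4%). Localization is real but
coarse: at the resolvable 4σ scale the converged model places ~46% of mass
in a disc whose area share is 26%, and translating the evidence translates
the map's center of mass accordingly. The regression tests assert exactly
these measured behaviours.

## Preprocessing and IO

Images are scaled to [0, 1], bilinearly resized (half-pixel centers) to the
target side (default 224, matching the reference recipe; desk-scale runs
use 28), grayscale replicated to three identical channels, then
standardized per channel — by default with statistics computed on the train
split of the loaded dataset (the reference recipe does not pin specific
statistics; this default is a package decision and is overridable to fixed
values or none). A standard-deviation floor of 1e-6 keeps constant images
finite. Task kind is inferred from label shape; ordinal regression is
shape-indistinguishable from multi-class and must be declared
(`task_override="ordinal"`), after which it is trained with ordinary
cross-entropy.

## Known limitations

* ResNet-50 training works in principle (all its layers have backward
  passes) but is impractical at NumPy speed; the reference experiments use
  the tiny CNN for both roles.
* ViT teachers support forward only; attention-based saliency for them is
  out of scope.
* The multi-label soft-target construction is this package's extension;
  alternatives (e.g. a softmax over label logits) were not explored.
* Single training runs only: no distributed or mixed-precision execution,
  and no confidence intervals on a single run's metrics.
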