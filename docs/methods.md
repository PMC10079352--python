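# Methods

This note documents the models and procedures implemented in `patchal`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## The active-learning cycle

The loop (`alloop.run_active_learning`) follows the standard pool-based
scheme. The pool is a disjoint partition of patch ids into unlabeled `U`
and labeled `L`; an acquisition moves a batch from `U` to `L` and the
partition invariants (`U ∩ L = ∅`, `|U| + |L|` constant) are re-validated
on every transition. The first batch is drawn uniformly at random — no
trained model exists yet, so no informed selection is possible. Each
iteration then retrains the selector model *from scratch* on `L`
(warm-starting is available but off by default: retraining avoids
order-dependence on the acquisition history), measures AUC on a fixed
held-out test set (never on pool items), checks the stopping rules
(`max_labeled` and/or `auc_threshold`, OR semantics — either rule can be
disabled), and acquires the next batch.

Ensemble members differ only in their initialization seed and share the
same labeled set; MC dropout uses a single model with the dropout head
active at prediction time. Every source of randomness derives from the
config seed through a fixed `SeedSequence` spawn tree with one child per
purpose per iteration (train / MC masks / subpool / clustering). Streams
are spawned unconditionally in the same order whichever selector runs, so
selector variants are exactly comparable under a shared seed and two runs
with identical configs produce identical metrics tables.

## Uncertainty scores

Predictive samples form an F×N×C tensor (F passes or members, N items,
C classes). Scores per item:

* Max Entropy: H[p̄] of the mean predictive distribution;
* BALD: H[p̄] − (1/F)Σ_f H[p_f], the mutual information between the
  prediction and the model posterior; analytically ≥ 0, so float residue
  is clamped at zero;
* variation ratios: 1 − modal-vote-count/F over per-pass argmax votes.

Entropies use natural log; rankings are base-invariant, so the base only
fixes reported magnitudes. Argmax and modal ties resolve to the lowest
class index, and score ties in top-m selection to the lexicographically
smallest id — determinism matters more than the (measure-zero) tie itself.
MC dropout draws one mask per pass, shared by all items in that pass: a
pass is a single sampled network, and scores become independent of item
ordering. Default score is BALD; default F = 20 passes and N = 3 members.

## DADA

Composition per iteration: subpool draw → predictive passes → score →
deep features → PCA → k-means → budgets → per-cluster top picks.

* **Subpool.** A fresh uniform sample without replacement (default 2000)
  from the current `U`; any still-unlabeled item is eligible again in
  later iterations. This bounds scoring cost independently of pool size.
* **Features.** Penultimate activations (post-global-average-pool) of the
  selector model — architecture-independent dimensionality and the
  standard deep-feature choice.
* **PCA.** Default 32 components, clamped by rank; small enough to keep
  k-means fast, large enough to separate the synthetic modes.
* **Clustering.** Seeded Euclidean k-means, default K = 20 (AL quality is
  reported stable for cluster counts roughly 10–80). K is clamped to the
  number of distinct points; empty clusters are dropped and labels
  compacted, so every cluster is non-empty.
* **Budgets.** acqSize(i) = PR(i)·Q with PR(i) = Z(i)/ΣZ, where Z(i) is
  the mean score over *all* subpool members of cluster i (not only
  eventual candidates). Fractional budgets are rounded by
  largest-remainder (Hamilton) apportionment with lowest-index
  tie-breaking — it conserves Q exactly and is deterministic. A cluster
  is never billed beyond its size; capped surplus is redistributed by the
  same rule among uncapped clusters. An all-certain subpool (ΣZ = 0)
  falls back to uniform shares and is logged.

With K = 1 and a subpool covering `U`, the machinery reduces *exactly* to
plain top-Q uncertainty acquisition (verified by set equality under a
shared seed), so DADA is a strict generalization of MC/ENS acquisition.

## NAR

An architecture is a list of blocks (kind, repeats, channels, kernel,
stride) plus a GAP → dropout → dense head. Reduction with multipliers
d = α^(−φ), w = β^(−φ), r = γ^(−φ) (α = 1.2, β = 1.1, γ = 1.15, so
α·β²·γ² = 1.92027 ≈ 2) rewrites each block as:

* repeats′ = max(1, ceil(d·repeats));
* channels′ = the multiple of `channel_divisor` (default 8; set 1 for
  exact-ratio tests) nearest to w·channels, floored at one divisor and
  bumped one step if below 90% of the target — the rounding conventions
  of the compound-scaling lineage, which keep layers non-degenerate;
* input′ = round(r·input). Input channels (RGB) are never scaled.

The published sources do not state rounding rules; the above are package
conventions. Reduction fails loudly (naming the block) when the reduced
resolution underflows a kernel — shallow architectures therefore cap the
usable φ, mirroring the behavior reported for shallow residual nets.

`estimate_flops` counts MACs per layer occurrence (conv:
H·W·C_out·k²·C_in; depthwise: H·W·C_in·k²; dense: C_in·C_out; pool: 0)
with 'same'-padding spatial propagation; a block's stride applies to its
first occurrence. MACs rather than 2×MACs because only ratios matter.
The classifier head is excluded (tiny, and unscaled by reduction). On a
reference architecture (repeats 8, channels 64–512, input 224) measured
ratios track (α·β²·γ²)^(−φ) within ~20%; the discrepancy is integer
rounding, dominated by ceil on repeats.

## The trainable model

`build_trainable` concretizes a spec as a compact numpy CNN: strided
convolutions (im2col) with ReLU, optional max pooling, global average
pooling into the feature vector, and a dropout + dense softmax head
trained with Adam. It supports `conv` and `pool` trunk blocks;
`depthwise_conv` and `dense` blocks are representable and costable but
not buildable — the tested reference family (`tiny_cnn`: three conv
blocks, 32 features) needs neither. Inputs in [0, 1] are resized to the
model's input resolution (bilinear) and standardized per patch per
channel internally. Training is minibatch Adam (paper-faithful defaults:
50 epochs, learning rate 1e−4); inference is dropout-free and batched.
All arithmetic is numpy, so fit/predict are deterministic given the seed.

## Preprocessing

Channel standardization maps each patch channel to mean 0/std 1.
Statistics are per patch (not pool-wide): self-contained at inference and
appropriate for stain variation between samples. A constant channel is
centered to zeros and logged. Training-time augmentation draws, in fixed
order, a rotation uniform in ±22.5° (reflection padding, so no class-
correlated black corners), vertical/horizontal flips at probability ½,
and brightness/contrast/saturation factors uniform in [0.8, 1.2]
(magnitudes are a package choice: mild, symmetric, clipped to [0, 1]).
Augmentation applies only during training, freshly per epoch.

## Synthetic data

`generate_patch_pool` emulates the statistical structure of a TIL patch
pool: 16% positive prevalence (exact by construction), positives carrying
12–30 dark bluish elliptical blobs (eccentricity ≤ 2) versus 0–3 for
negatives, on one of 8 latent background "styles" (pastel base hue plus a
low-frequency sinusoidal texture) with Gaussian pixel noise (σ = 0.05).
Default patch size is 240 px; the test suite and benchmarks use 64 px to
stay desk-scale. All randomness flows from one root seed via named
substreams, and outputs are bit-identical across runs.

What the generator reproduces: class imbalance, a visually local positive
signal, and feature-space cluster structure orthogonal to the label (the
redundancy DADA exploits). What it does not: stain chemistry, nuclear
morphology, slide-level artifacts, annotator disagreement beyond a
symmetric label-noise option. Consequently, passing benchmarks show the
machinery behaves as designed — budgets conserve, diversity increases
mode coverage, reduced selectors preserve final quality — not that the
same AUC values would be attained on real tissue. On this easy synthetic
task both DADA and random acquisition saturate near AUC 1.0 within a few
hundred labels; the label-efficiency comparison is therefore a
non-inferiority check at desk scale rather than a replication of
full-scale gaps.

`generate_feature_pool` (isotropic Gaussian modes with guaranteed center
separation) supports acquisition-logic tests without images or a CNN.

## Benchmark problem sizes

The desk-scale benchmark uses a 4000-patch pool at 64 px with a 600-patch
held-out test set; AL runs use Q = 50 for 5 iterations (250 labels),
F = 20, K = 20, subpool 2000, and a 20-epoch / 1e−3 Adam schedule chosen
once for the small CNN (the compact model converges in a few hundred
steps; the paper-faithful 50-epoch/1e−4 defaults remain in `ALConfig`).
The decoupling benchmark uses Q = 40 for 3 iterations with a φ = 3
selector. The acceptance script scales the pool to 2000 patches and two
paired seeds so a full from-scratch run stays in the minutes range.

## Known limitations

* The trainable model family is intentionally small; faithful replicas of
  large production architectures are representable in `ArchSpec` but out
  of scope, as is the binary layer-selection scheme for sequential
  (non-block) networks — those are rejected with an explicit error.
* α, β, γ are fixed to published values; no grid search is performed.
* The advisory validation split on `PoolState` carries no semantics
  (validation-based early stopping is off by default).
* k-means and PCA run on CPU via scikit-learn; very large subpools would
  want minibatch variants.
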