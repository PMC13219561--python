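# Methods

## Model

### Backbone

The encoder is a standard pre-norm vision transformer: a patch-embedding
projection with bias, a learned class token, learned positional embeddings
(one per token, class token included), `L` blocks of
(LayerNorm → multi-head self-attention → residual,
LayerNorm → GELU MLP → residual), and a final LayerNorm. The pooled feature
of layer `l`, `f_l(x)`, is taken from the layer's output hidden state (after
the residual addition, before the final norm): the class-token row under
`cls_token` pooling, the token mean under `mean_tokens`.

Closed-form parameter count (verified against tensor enumeration in the
tests): at the base-size /16 geometry (L=12, d=768, MLP 3072, 16×16 patches,
224×224 RGB input) the encoder holds exactly 85,798,656 scalars — 590,592 in
the patch embedding, 768 in the class token, 151,296 in the positional
embeddings, 7,087,872 per block, 1,536 in the final norm. No pooler head is
included; the closed form reproduces the published full-tuning budget
without one.

Random initialization uses truncated normal (±2σ) with σ = d^(-1/2) for all
projections and zero biases. The Xavier-scale σ (rather than the 0.02 used
when such models are trained from scratch at width 768) keeps the activations
of a *randomly initialized* small-width encoder at unit scale, so successive
blocks apply substantial, depth-distinct transformations; with σ = 0.02 at
width 32 every block is numerically near the identity and per-layer features
are indistinguishable, which would make layer probing vacuous. Loading
externally trained weights is an orthogonal concern and not required
anywhere.

All computation runs on a compact reverse-mode autodiff core
(`probefuse.autodiff`): float64 tensors over NumPy with the operations the
model needs (broadcasting arithmetic, batched matmul, softmax/logsumexp,
erf-based GELU, LayerNorm, slicing/stacking). Every primitive's gradient is
checked against central finite differences in the test suite.

### Fisher probing (layer selection)

Per-dimension Fisher scores
`S_j = Σ_c n_c (μ_cj − μ_j)² / Σ_c n_c σ_cj²` (population variances;
zero-variance dimensions return a 1e12 sentinel with a warning, since
few-shot supports can be degenerate) are exposed for reference but are not
used for selection: estimating per-dimension statistics from K ∈ {1, 5, 10}
samples is unreliable. Selection instead uses the gradient proxy

    F_c(l) = (1/|S_c|) Σ_{x∈S_c} || ∇_{f_l(x)} L_CE(h(f_l(x)), y) ||²,

computed analytically as `∇_f = Wᵀ(softmax(W f + b) − onehot(y))` at a single
probe head `h` whose weights are drawn once (seeded, scale d^(-1/2), zero
bias) and shared across all classes *and* all layers, so proxies are
directly comparable. The head bias shifts logits but contributes no separate
term to the feature gradient. Layer score = `max_c F_c(l)`; scores are
z-normalized across layers (population std, ε = 1e-8 guard); the top `K_s`
layers are returned in descending score order with ties broken toward the
shallower layer. Probing always runs on the frozen, unadapted backbone,
before adapter injection, and touches no weight.

**Known limitation (measured).** On a randomly initialized backbone the
proxy's across-layer ranking is dominated by (a) a monotone depth trend —
activation norms grow along the residual stream, and the z-score, an affine
transform of the score vector, cannot change rankings — and (b) the chance
alignment of the fixed random head with the discriminative directions. In
the planted-layer experiments (below) the proxy recovers the informative
layer in the top-3 of 6 at roughly the 50% chance rate, whereas selecting
layers by support-set linear-probe accuracy recovers it in 20/20 trials.
The proxy's signal evidently relies on class-conditional *cluster* structure
of the kind pretrained features exhibit on real data; a margin-type linear
signal in otherwise undifferentiated features is invisible to it. The
behavior of the probe on real selections (a preference for mid-to-deep
layers) is reproduced by the depth trend. The acceptance suite asserts the
≥80% recovery condition regardless and documents its failure rather than
substituting a different selector.

### Low-rank adapters

Each of the query, key, and value projections of every block is wrapped:
`W' = W₀ + s·B A`, `A ∈ R[r×d]` seeded Gaussian (σ = 0.02), `B ∈ R[d×r]`
zero, scaling `s = 1` by default (the α = r convention). Zero-initialized
`B` guarantees the probe-phase model and the adapted model agree exactly at
step 0. Projection biases stay frozen. `merge()` folds `s·B A` into the
dense weight for single-matrix inference; `unmerge()` restores `W₀`
(round-trip exact to float64, tested at 1e-5). Trainable entries:
`3 · L · r · (d_in + d_out)` — 442,368 at L=12, d=768, r=8.

### Attention-guided fusion

Given pooled features of the `K_s` selected layers (ordered by descending
Fisher score, so the top-ranked layer receives the largest initial static
weight):

1. shared alignment: `f̃ = normalize(LeakyReLU(P f + b, 0.1))` with one
   `d×d` projection for all layers (L2 guard ε = 1e-12; an all-zero
   activation stays zero with a warning);
2. static weighting: `f̂_l = w_l f̃_l`, `w` initialized
   `linspace(1.5, 0.5, K_s)` (a single selected layer takes the start value
   1.5);
3. cross-attention: the stack `F ∈ R[K_s×d]` is queried by a learned
   Xavier-normal vector `q ∈ R[1×d]`; `K = F W_K`, `V = F W_V` (no biases,
   no output projection — the aggregation is exactly
   `softmax(q Kᵀ/√d_k) V`), realized with 8 heads by splitting `q`, `K`,
   `V` into segments of width `d_k = d/8` with per-head softmax over the
   `K_s` positions; dropout (p = 0.1) is applied to the attention weights
   and only during training;
4. output: LeakyReLU then L2 normalization, so `‖F_out‖₂ = 1` and the
   classifier operates on feature direction.

With equal static weights the fused output is invariant to permuting the
layer order (set attention); attention weights are nonnegative and sum to 1
per head.

### Training

Trainable partition: adapter tensors ∪ fusion tensors ∪ head (a zero-
initialized linear map `d → N` with bias, 3,845 entries at d=768, N=5);
disjointness and the frozen complement are asserted at construction. Each
episode is adapted by full-batch AdamW (β = 0.9/0.999, decoupled weight
decay 1e-4) on the support cross-entropy for 50 steps, with global
gradient-norm clipping at 1.0 and cosine annealing
`lr_t = lr · ½(1 + cos(π t/T))` (exactly the base rate at step 0, ≤1% of it
at the final step). The head learning rate scales linearly with task
complexity, `head_lr = base · N/5`; adapters and fusion share the smaller
adapter rate. Defaults: adapter 2e-3, head base 2e-2. Because the classifier
sees a unit-norm feature, the logit scale is bounded by the head-weight
magnitude; rates much below these leave a zero-initialized head with
near-uniform softmax after 50 steps (measured: at head rate 1e-3 the 50-step
support loss moves by under 4%, at 2e-2 it drops to ~0.3× while query AUROC
is flat between the two regimes), so the larger defaults are the ones under
which the optimization contracts (loss decrease on separable data) are
meaningful. The query set is never forwarded before evaluation.

Evaluation: softmax scores on the query set; macro one-vs-rest AUROC
(scikit-learn's rank-based ROC, midrank ties — constant scores give exactly
0.5) with classes missing from the query dropped from the macro average
under a warning; accuracy as argmax match rate. The AUROC path is verified
against a brute-force pairwise win/tie count oracle.

## Synthetic data

`generate_episode` builds class-balanced N-way K-shot episodes from two
pattern families emulating the shallow-vs-deep contrast of real images:
`texture` (high-frequency gratings, class-specific orientation and 2–4 px
period) and `shape` (global two-blob Gaussian layouts). Pixels are
`margin · pattern + noise_sd · N(0,1)`, standardized to zero mean and unit
variance per image and channel (the preprocessing applied before the
backbone); `margin = 0` therefore yields labels independent of the pixels.
Defaults: N=4, K=5, M=20 queries, 32×32 single-channel, noise_sd 1,
margin 5 — at that signal-to-noise ratio a raw-pixel linear probe separates
queries almost perfectly, which is the intended easy regime for pipeline
smoke tests.

`generate_planted_task` labels *generic* images (white noise plus one
random low-frequency wave, standardized) by the sign pattern of
`ceil(log2 N)` seeded hyperplanes through a chosen layer's pooled feature
space. Two design points matter:

- **Innovation-subspace directions.** The hyperplane normals are drawn
  (seeded) within the span of the top principal components of the layer's
  innovation — the residual of regressing `f_l*` on `f_{l*−1}` over a
  reference batch of 128 images. In a residual-stream encoder a fully
  random direction is linearly present at *every* depth, so labels planted
  along it are recoverable from any layer and the fixture would not test
  layer selection at all.
- **Exclusion margin.** Samples within 0.5 standard deviations of any
  hyperplane are resampled (rejection over fresh batches, with a retry
  budget and a hard error when exhausted). The margin makes the task
  learnably separable at small K: at 0.5 a linear probe on the planted
  layer reaches 0.95–0.99 query AUROC, whereas at 0.1 even that oracle is
  capped at ~0.85–0.89, below any meaningful "separable task" bar.

What the planted fixture does *not* emulate: pretrained-feature cluster
structure (classes as compact modes of the feature density). Passing
pipeline tests on planted tasks therefore demonstrates correct mechanics —
gradient flow, adaptation, fusion, evaluation — on linearly separable
signals, not performance on real imaging data.

Episodes export to PNG (16-bit grayscale or 8-bit RGB, with per-image value
ranges stored in the CSV manifest for inversion) and to lossless `.npz`
archives; both round-trip through the loaders.

## Problem sizes and reproducibility

Desk-scale experiments (tests and the acceptance script) use an L=6, d=32,
4-head encoder on 32×32 single-channel images with K_s=3 and rank-8
adapters; the base-size /16 geometry appears only in analytic parameter
accounting. The acceptance script runs 20 planted recovery trials, 50
shuffled-label null trials, and 20 trained episodes of 50 steps each, all
derived from one `--seed`. Every generator, initializer, and training run is
a pure function of its seed; task seeds derive as `seed + task_index`, and
rerunning any command with the same configuration reproduces its outputs
bit-for-bit (wall-clock timings aside).

## Known limitations

- The Fisher-proxy selector's ranking is chance-level on randomly
  initialized backbones (see above); its value is predicated on pretrained
  feature geometry, which this package cannot verify without external
  checkpoints.
- The fusion parameter inventory (shared projection, static weights, query,
  `W_K`, `W_V`) is one consistent reading of the published module; with it,
  the full trainable set at the base geometry is 2.22 M (2.58%), while the
  deterministic core reported by the acceptance script (adapters + shared
  projection + query + static weights, 1.03 M / 1.20%) stays within the
  published 1.11 M / 1.29% budget.
- Episodic adaptation is per-task; there is no meta-training across tasks,
  no data augmentation, and no mixed-precision or GPU path.
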