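# probefuse

Probe-then-fuse adaptation for few-shot image classification with frozen
vision-transformer backbones.

When only a handful of labeled images per class are available (N-way K-shot
tasks, as in few-shot medical imaging), fully fine-tuning a large ViT
overfits, while a fixed linear readout of the final layer ignores the fact
that different tasks are best served by representations at different depths
— textures and edges live in shallow layers, abstract semantics in deep
ones. `probefuse` adapts a frozen backbone per task in three steps:

1. **Fisher probing.** Each layer's pooled representation `f_l(x)` (the
   class-token row of the layer's hidden state, or the token mean) is scored
   on the support set with a gradient-based Fisher proxy. A single fixed,
   randomly initialized linear head `h` is attached to the features and, for
   each class `c`,

   `F_c(l) = mean over class-c support of || ∇_{f_l(x)} L_CE(h(f_l(x)), y) ||²`

   — the diagonal empirical Fisher information of the representation. The
   layer score is `max_c F_c(l)` (so a layer is kept if it separates at
   least one class well), scores are z-normalized across layers, and the
   top `K_s` layers are selected.
2. **Low-rank adaptation.** Every attention projection (query, key, value)
   of the frozen backbone receives a trainable low-rank branch,
   `W' = W₀ + B A` with rank `r ≪ d`; `B` starts at zero so the adapted
   model initially equals the base model, and `B A` can be merged into `W₀`
   for inference.
3. **Attention-guided fusion.** The selected layers' pooled features are
   aligned by a shared projection (LeakyReLU + L2 normalization), pre-scaled
   by learnable static weights initialized `linspace(1.5, 0.5, K_s)`,
   stacked, and aggregated by multi-head cross-attention in which a learned
   query attends over the `K_s` stack positions:
   `Attention(q, F, F) = softmax(q Kᵀ / √d_k) V` with `K = F W_K`,
   `V = F W_V`. The output is LeakyReLU-activated and L2-normalized, so the
   final classifier operates on a unit direction vector.

Only the adapters, the fusion module and the linear head are trained
(AdamW, cosine-annealed learning rates with the head rate scaled by the
class count, global gradient clipping); every base backbone weight is
bit-identical before and after adaptation. Query performance is reported as
macro one-vs-rest AUROC.

The package is pure NumPy/SciPy (a compact reverse-mode autodiff core drives
the transformer and the training loop), ships a synthetic episode generator
— including *planted tasks* whose labels are constructed from a chosen
layer's features, for testing layer selection — and needs no downloads or
GPUs.

## Worked example

Run the full pipeline on five synthetic 4-way 5-shot texture episodes with a
6-layer, width-32 encoder:

```bash
probefuse run --config demo.yaml --out demo_run
```

with `demo.yaml`:

```yaml
backbone: {n_layers: 6, hidden_dim: 32, n_heads: 4, mlp_dim: 64, patch_size: 8, image_size: 32, n_channels: 1}
lora: {rank: 8}
fusion: {n_selected: 3, feature_dim: 32, n_heads: 4}
training: {steps: 50}
n_selected: 3
n_tasks: 5
seed: 0
```

prints

```
 n_tasks  auroc_mean  auroc_std
       5         1.0        0.0
```

(the default texture episodes have a signal-to-noise ratio of 5, so a
correctly trained pipeline separates the queries perfectly), and writes one
JSONL record per task. The first record begins

```json
{"seed": 0, "selected_layers": [4, 3, 6],
 "layer_scores": [-1.637, -1.161, 0.681, 0.813, 0.649, 0.654], ...}
```

showing the three layers the Fisher probe selected and the z-scored layer
scores it selected them by, followed by the 50-step support loss trace
(1.386 → 0.280 here) and the query metrics.

Parameter accounting at the base-size /16 geometry (12 layers, width 768):

```bash
probefuse params --config vitb.yaml --rank-sweep 8
```

```json
{"backbone": {"patch_embedding": 590592, "class_token": 768,
              "positional_embedding": 151296, "encoder_blocks": 85054464,
              "final_norm": 1536, "total": 85798656},
 "rows": [{"rank": 8, "backbone_frozen": 85798656, "lora": 442368,
           "fusion": 1771011, "head": 3845, "total": 2217224,
           "total_millions": 2.22, "percent_trainable": 2.58}]}
```

The frozen backbone counts 85.80 M parameters; the rank-8 adapters add
0.44 M trainable entries, and the whole trainable set stays below 3% of the
backbone.

Other subcommands: `probefuse probe` (layer-selection frequencies over many
episodes, CSV), `probefuse generate` (export an episode as PNG files plus a
CSV manifest).

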