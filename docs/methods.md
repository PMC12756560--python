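# Methods

## Problem and model

`toxfuse` predicts 12 binary in-vitro toxicity endpoints (7 nuclear-receptor
and 5 stress-response assays, Tox21-style) for small organic molecules from
four complementary representations of the same compound:

1. **Molecular graph** — atoms as nodes (78-dim feature vectors), bonds as
   pairs of directed edges with a 4-way bond-type one-hot;
2. **SMILES sequence** — regex-tokenized, padded/truncated to 202 positions;
3. **2-D depiction** — a 224×224 RGB image rendered from the structure,
   ImageNet-normalized;
4. **¹³C NMR spectrum** — a binary peak-presence vector on a 1 ppm grid over
   [−20, 240) ppm (260 bits).

Each representation is encoded to a fixed-length embedding by a
modality-specific network; the embeddings are projected to a common dimension
`d_e` with per-modality linear maps + ReLU, stacked as M tokens (fixed order:
graph, smiles, image, spectrum), fused by one shared multi-head
self-attention layer

    Z = MultiHead(X, X, X),    fused = (1/M) · Σ_m Z_m,

and classified by a Linear→ReLU→Dropout block followed by an MLP head with
one logit per endpoint.  Compounds without a measured spectrum substitute a
**learnable missing token** — initialized to zeros, with the dimensionality
of the spectrum embedding — before the shared spectrum projection, so
partially observed compounds remain trainable and the projection weights are
shared between the real and missing paths.

The attention block is a plain `MultiHead(X, X, X)` with mean pooling (no
residual or layer norm), matching the fusion equation above; a
`residual_attention` flag enables a standard pre-norm residual block for
users who want it.

## Encoders

* **Graph**: L stacked edge-aware GIN (GINE) layers.  Per layer, node v
  updates as `MLP((1+ε)·h_v + Σ_{u∈N(v)} ReLU(h_u + e_uv))` with a learnable
  per-layer ε (init 0), followed by batch norm → ReLU → dropout; the raw
  4-dim bond one-hot is linearly projected to the current node dimension
  before entering the sum (the update adds edge to node states, so the
  dimensions must be reconciled; a per-layer linear map is the minimal
  choice).  Global sum pooling, then a two-layer projection head.
* **SMILES**: token embedding + fixed sinusoidal positions → pre-norm
  transformer blocks whose attention is restricted to real (non-pad)
  positions → masked mean pooling → linear, dropout, GELU, linear.  Batches
  are trimmed to the longest real prefix; pad positions beyond it are inert
  by construction (verified by a pad-invariance test).
* **Image**: a small residual CNN.  A 4× average-pooling stem reduces
  224→56 before convolution; three conv/BN/ReLU/pool stages, one residual
  3×3 block, a 1×1 conv to the backbone dimension (default 512), global
  average pooling, then the projection head.
* **Spectrum**: a 1-D CNN over the peak bits.  Because global average
  pooling makes a plain conv stack translation-invariant — which would erase
  the chemical-shift position of a peak, the very signal a binned spectrum
  carries — the input has two channels: the raw bits and bits × normalized
  bin position.  Conv/BN/ReLU/pool blocks, global pooling, and a linear map
  to the backbone dimension (default 768) precede the projection head.
  When the backbone is frozen only the head (and probe) receive gradients,
  and the frozen batch-norm layers run in inference mode.

All networks run on a small reverse-mode automatic-differentiation engine
over NumPy written for this package (`toxfuse.nn`): tensors with backward
closures, exact gradients for matmul/conv/pooling/attention/normalization
ops (checked against central finite differences in the test suite), an Adam
optimizer, and explicit `numpy.random.Generator` streams for every source of
randomness.  Training is single-CPU and bitwise reproducible for a fixed
seed on a fixed platform.

## Training protocol

Two phases:

1. **Encoder phase** — each encoder is trained individually, jointly with a
   12-task linear probe, under the masked objective below (defaults: Adam
   lr 1e-3, batch 32, ≤50 epochs, early stopping with patience 10 on
   validation macro ROC-AUC, best-epoch weights restored).  The spectrum
   encoder trains only on the spectrum-available subset.  The probe also
   serves as the single-modality baseline predictor.
2. **Fusion phase** — all encoders are frozen (their embeddings are
   precomputed once in eval mode, which is exactly equivalent and much
   faster); only the fusion network and the missing token are optimized
   (defaults: ≤30 epochs, patience 5) on the full dataset, including
   spectrum-absent compounds.

**Masked loss.**  Labels live in {0, 1, missing}; missing entries are stored
as −1 and masked.  The objective is binary cross-entropy with logits averaged
over observed entries only; a batch with no observed entry has loss exactly 0
and contributes no gradient.  A mean-of-per-task-means variant is available
behind a flag (`per_task_mean`); the flat mean is the default for its
simplicity.  No per-task positive re-weighting is applied by default.

**Hyperparameter search** is a seeded random search over a finite space
(`hyperparameter_search`), returning the best configuration by validation
macro AUC plus all trial records.

## Evaluation

Scaffold split: molecules are grouped by Bemis-Murcko scaffold (acyclic
molecules form one shared empty-scaffold group by default; a flag gives each
its own group), groups are shuffled by the split seed, and whole groups are
assigned greedily — train until its count first reaches 80% of molecules,
then valid to 10%, remainder test.  A deterministic largest-first variant is
available behind `shuffle=False`.  The splitter guarantees non-empty
partitions and zero scaffold overlap; both are asserted in tests.

ROC-AUC uses the rank/trapezoid definition (equal to the pairwise
probability with ½ credit for ties; verified against an O(n²) enumeration
oracle).  Macro AUC is the unweighted mean over endpoints for which both
classes are observed; single-class endpoints are skipped and logged.
Threshold metrics (accuracy, balanced accuracy, Cohen's κ, MCC, sensitivity,
specificity) are computed at sigmoid score ≥ 0.5.  Cross-seed model
comparisons use two-tailed paired t-tests with df = n−1; identical metric
vectors report p = 1.0 and zero-variance nonzero differences report p = 0.0,
both with warnings.

The ablation harness (`benchmark_matrix`) trains and evaluates every
(seed, modality-subset) cell — 4 singles, 6 pairs, the graph+smiles+image
triple, and the full quad under `ablation=full` — and reports per-endpoint
and macro AUCs, cross-seed mean ± sd, and paired p-values against the full
model.  Attention maps are averaged over samples and heads per split and
exported as long-format CSV (query modality × key modality).

## Synthetic benchmark

The generator builds valid molecules from a fragment grammar: a primary ring
(benzene, pyridine, pyrimidine, furan, thiophene, cyclohexane, cyclopentane,
piperidine, oxane, plus fused bicyclics) with up to three substituents, an
optional second ring joined by a short linker (probability 0.8 — this is
what gives synthetic sets hundreds of distinct Bemis-Murcko scaffolds and
realistic scaffold-split geometry), and a configurable fraction (default
0.1) of purely acyclic chains.  Three planted toxicophores — nitroaromatic,
carbonyl, aromatic halide — drive the 12 endpoints through a logistic model
`activity_t = σ(Σ_k w_tk·x_k + b_t)` whose intercepts are calibrated by
bisection so each endpoint's positive rate falls in [5%, 40%] (Tox21-like
imbalance); labels are Bernoulli draws flipped with probability
`label_noise` (default 0.05) and masked missing per endpoint (default 0.15).
In the default *complementary* weighting, endpoints 1–6 are driven by the
aromatic-halide indicator (graph-visible) and endpoints 7–12 by the carbonyl
indicator (spectrum-visible: carbonyl carbons resonate near 180 ppm), which
is what makes four-modality fusion demonstrably better than any single
modality on this benchmark.

Simulated ¹³C spectra place one peak per symmetry-equivalent carbon class
(equivalence from canonical atom ranking) at an environment base shift —
aromatic 128 ppm, carbonyl 180 ppm, sp³ carbon bound to a heteroatom 60 ppm,
plain sp³ 25 ppm — with Gaussian jitter (default sd 1 ppm).  Spectra are
kept for a Bernoulli-sampled 36% of compounds, matching the partial spectral
coverage of public toxicity corpora.

What the generator does **not** emulate: real chemical-shift physics
(coupling, solvent, substituent effects beyond the four-class rule),
realistic Tox21 marginals and endpoint correlations, assay noise structure,
activity cliffs, or large pharmaceutical-like molecules.  Passing the
synthetic experiments therefore shows that the architecture, masking,
missing-modality and evaluation machinery behave correctly and that fusion
exploits planted complementary signal — not that the model reaches any
particular accuracy on real toxicity data.

## Problem sizes and numerical choices

The tested experiments run at deliberately small scale, chosen so the full
suite executes on one CPU core: encoders default to h=128/L=5 (graph),
4×4-head transformers (SMILES), (32, 64, 128)-wide CNN stages (image) and a
3-block 1-D CNN (spectrum), but the scaled experiments use h≈32–48 variants,
600-molecule benchmarks with 3 split seeds, ≤18 encoder epochs and ≤30
fusion epochs.  The capacity (overfit) check uses 64 distinct molecules with
distinct binned spectra, since a memorization test is only meaningful when
the inputs are distinguishable.  All tolerances in tests reflect float32
arithmetic: oracle comparisons at 1e-5, permutation invariance at 1e-4
(summation order differs between batched and permuted evaluation), bitwise
equality where the contract is exactness (masking, frozen parameters,
missing-token substitution, seed determinism).

Degenerate inputs: empty peak lists are rejected (absent spectra go through
the missing-token path, never a zero vector); all-pad token sequences raise;
molecules with no carbon yield no spectrum and are marked spectrum-absent;
single-class validation endpoints are skipped in early stopping; an
all-missing label batch contributes zero loss and gradient.

## Known limitations

* Encoders are trained from scratch at small scale; `load_backbone_weights`
  accepts external checkpoints but is untested against any published weights.
* The NumPy engine is CPU-only and unoptimized for large batches; image
  training dominates runtime.
* The SMILES vocabulary is built from the dataset being processed rather
  than the training split only; token inventory carries no label
  information, and this keeps featurization identical across split seeds.
* Attention is task-agnostic (shared across the 12 endpoints); task-
  conditioned fusion is out of scope.
* Hyperparameter search is random search, not model-based optimization.
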