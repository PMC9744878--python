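# Methods

This note records the modelling assumptions, the defaults and why they
were chosen, the interpretation calls made where the architecture's prose
description is ambiguous, and what the synthetic cohorts do and do not
establish.

## Problem formulation

Each subject contributes a time-ordered sequence of visits. The model
predicts the next visit's total severity score ŷ⟨n+1⟩ from the feature
histories X⟨1..n⟩, the inter-visit gaps Δt⟨1..n⟩, and the past observed
scores y⟨1..n⟩. All three histories are concatenated per time step into
one input vector of width Q + 2 (scaled features, Δt in years, past score
standardized — see *Input encodings*). Every history length 1..N−1 of an
N-visit subject is used as a training sample, matching the evaluation
scheme, which scores predictions at every target visit. Subjects with one
visit contribute no windows (but do contribute rows to feature scaling).

## Architecture

- **Composite block (CB)**: recurrent layer (vanilla tanh cell by
  default; GRU and LSTM available) followed by batch normalization of its
  output activations, `H⟨t⟩ = β + γ ⊙ (h⟨t⟩ − E[ĥ])/√(Var[ĥ] + ε)`.
- **BN placement**: one γ/β pair per CB, shared across time steps; one
  running-statistics accumulator per CB, pooling over batch *and* time
  steps. Per-time-step statistics were the alternative; pooling is the
  simplest reading consistent with a single normalizer per block, and it
  keeps the statistics well-estimated for short sequences. Variance is
  the population variance (ddof 0). Running estimates are exponential
  moving averages with momentum 0.1; train mode normalizes with the
  current mini-batch, inference with the frozen estimates, which makes
  inference predictions independent of batch composition (asserted in
  tests).
- **Dense block (DB)**: K CBs; with dense connections on, CB_j receives
  concat(input, H¹..H^{j−1}) and the block emits concat(input, H¹..H^K) —
  the input passthrough is included, following the DenseNet convention.
  DBs are stacked under the same concatenation rule. With dense
  connections off, blocks are plainly chained.
- **Read-out**: the final DB's output at the *last time step* through a
  single affine unit. A literal flatten over all time steps would tie the
  head's weight count to the sequence length and could not be trained
  across variable visit counts; last-step read-out is the
  variable-length-consistent interpretation and is recorded here as an
  interpretation, not a stated fact.
- **Initialization**: orthogonal recurrent matrices, Glorot-uniform input
  matrices, zero biases (LSTM forget-gate bias 1), γ=1, β=0. Seeded;
  same seed ⇒ identical weights ⇒ identical outputs.

The whole forward pass runs on a small reverse-mode autodiff tape over
numpy arrays (`progrnn.autodiff`). Its operation set is exactly what the
architecture needs, and every op plus the assembled model is checked
against central finite differences (rel. error ≲ 1e−6 across cell types
and flag combinations).

## Training

Mean-squared-error loss plus an L2 penalty restricted to the recurrent
layers' input and recurrent weight matrices (not biases, not γ/β, not the
head), optimized with Nadam (β₁ = 0.9, β₂ = 0.999). Mini-batches of 16
same-length histories: samples are grouped by history length, shuffled
within groups, chunked, and the batch order shuffled per epoch — every
sample appears exactly once per epoch. The learning rate is multiplied by
0.2 at every 10 consecutive epochs without validation improvement.

Defaults chosen where unstated: initial learning rate 1e−2 (the targets
are standardized and the networks small, so a large initial step with the
aggressive /5 decay schedule converges fastest; verified stable across
seeds and cell types), l2 = 1e−4, max 200 epochs, early stop after 30
non-improving epochs. Validation is a 10% *subject-level* hold-out,
stratified by visit count — subject-level because a sample-level split
would put shorter windows of a training subject into validation, leaking
that subject's trajectory. The model state returned is the one with the
best validation loss (never worse than the final epoch's).

### Input encodings

- Gene columns: log2(x+1), then z-scored with train-subject statistics
  (sample sd, ddof 1); the log transform is standard for TPM-scale data.
- Clinical columns: z-scored directly.
- Zero-variance columns: scale 1 pass-through (exact zeros), logged.
- Δt: years.
- Past scores y⟨i⟩ *and* the regression target: standardized by the
  train-split score mean/sd (carried in the scaling state, so the same
  leakage discipline as the features; predictions are mapped back to the
  raw 0–272 scale). An earlier encoding that fed y/272 raw was rejected
  after measurement: its channel variance is ~300× smaller than the
  z-scored features, the compensating weights are exactly the ones the L2
  penalty shrinks, and the optimizer needs most of its epoch budget just
  to rediscover the persistence structure. Standardization removes that
  pathology without changing what information the model sees.

## Evaluation

- **PIE** = unweighted mean over prediction time points (target visit
  indices) of the per-time-point RMSE; full-history predictions only. A
  pooled-over-records RMSE is available behind a flag.
- **PIC** = unweighted mean over time points of the Spearman rank
  correlation (average-rank ties). "Rank order correlation" is read as
  Spearman. Time points with fewer than 3 records, constant truths, or
  constant predictions carry no rank information and are excluded with a
  log line.
- **History ablation**: at depth k, each subject's final visit is
  predicted from only its k most recent prior visits.
- **Cross-validation**: subject-level fold assignment over subjects with
  ≥ 2 visits; scaling, target standardization, and the model are refit per
  fold; fold metrics aggregated as mean ± sd/√n_folds. The baseline arm
  must reuse the identical fold assignment (enforced).

## Statistical comparison

Paired t-test across matched fold metrics (df = n_folds − 1); a
zero-variance difference vector is reported as degenerate (t = 0 or ±∞)
rather than erroring. A summary-statistics variant
t = (m_a − m_b)/√(se_a² + se_b²) reproduces comparisons published only as
mean ± SE tables. The instrument-noise floor aggregates published
per-part error variances as Σᵢ√vᵢ — the sum of per-part standard
deviations. This is an inference: the aggregation formula behind the
published total is not written out, and the quadrature alternative
√(Σvᵢ) is inconsistent with it; the chosen reading reproduces the
published value and is monotone in every argument.

## Synthetic cohorts

The generator emulates the *statistical skeleton* the model assumes:

- 423 subjects by default; visits drawn from the schedule
  (0, 6, 12, 24, 36, 48) months with per-visit dropout probability 0.15
  after a minimum of 2 visits (configurable down to 1).
- Latent severity: baseline ~ N(20, 8²) clipped to [0, 272], progression
  rate ~ N(8, 4²) points/year (a realistic drug-naive progression band),
  latent(t) = clip(baseline + rate·t). Observed score =
  round(clip(latent + N(0, 3²))), an integer in [0, 272], split into four
  parts by fixed proportions 0.10/0.15/0.65/0.10 (motor-exam dominance)
  with largest-remainder rounding so the parts sum exactly.
- Expression: per-gene log2 baseline ~ U(1, 8), log-normal noise
  (sd 0.5); the first `n_signal_genes` genes add
  slope·(latent/272) on the log2 scale, slope ~ N(effect, (effect/4)²) —
  additive on the log scale keeps values non-negative and the effect size
  interpretable as log2-fold change per full traversal of the severity
  scale. Gene count defaults to 200: the generator is exercised at
  hundreds of genes for tractability and is configurable upward.
- Clinical block: 10 ordinal motor subscores tracking the latent
  severity, 3 nominal noise codes, standard-normal noise columns (default
  100 columns total) — giving the baseline arm all three column kinds.

Not emulated: library-size/batch effects, count-level sampling noise,
realistic gene–gene correlation, non-linear trajectories, score
floor/ceiling dynamics beyond clipping. Passing tests therefore show that
the pipeline learns the kind of structure it posits (autoregressive score
dynamics plus severity-linked expression), not that it attains any
particular accuracy on real repository data, whose headline numbers are
not reproducible without restricted access.

## Test problem sizes

The seeded learning checks use 200 subjects × (100 genes + 100 clinical
columns) with a 32-cell, 2-CB, 2-DB model trained ≤ 100 epochs, and the
noise-free recovery check 150 subjects × 50 genes with a 16-cell model —
sizes at which the documented effects (dense+BN beating the persistence
baseline and the plain configuration; held-out Spearman ≥ 0.9 against the
latent trajectory) are stable across seeds while the whole suite stays
lightweight.

## Known limitations

- Dense concatenation with input passthrough duplicates the raw input
  across DB levels; parameter counts grow accordingly (the closed form in
  `count_parameters` is exact and tested against introspection).
- BN with batch size 1 and sequence length 1 degenerates to emitting β;
  training batches that small are legal but uninformative for γ.
- The Nadam implementation is the classic momentum-corrected form without
  the schedule decay some frameworks add; with the external
  plateau-driven decay this difference is immaterial.
- Single-threaded determinism is the tested contract; BLAS-level
  threading may reorder floating-point reductions.
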