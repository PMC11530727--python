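# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `moodfuse`.

## Data model and preprocessing

A record is one EMA prompt: participant id, timestamp, a 60-epoch
(1-minute) ZCM count window, a 60-epoch PIM intensity window, a
fixed-width speech feature vector (any embedding of the voice sample; the
package is agnostic to the extractor), and nine 0–100 mood ratings in the
fixed order vigorous, gloomy, concerned, happy, unpleasant, anxious,
cheerful, depressed, worried.

Preprocessing is deliberately conservative:

- **Cleansing** drops records with any non-finite value, negative
  actigraphy counts, or ratings outside the instrument range; each record
  is counted under the first violated rule, and the report keeps the
  counts per rule.
- **Label normalization** divides the 0–100 ratings by 100.
- **Chronological split**: per participant, the first 70% of records go
  to training, the next 15% to development, the rest to test
  (`floor`/`floor`/remainder; with at least three records every split is
  topped up to one record, so each participant appears in all parts).
  Splitting by time, never at random, prevents future records from
  leaking into training.
- **Standardization**: ZCM and PIM are each z-scored with one scalar
  mean/SD pooled over their 60 epochs (the epochs are exchangeable counts
  of a single channel), speech per feature dimension.  Moments use the
  population convention (divisor n), matching the CCC definition, and are
  fit on the training split only.  Zero-variance channels pass through
  with SD 1 and are flagged rather than aborting a run.

An open choice was whether standardization statistics should be global or
per participant; they are global (fit on the pooled training split), which
keeps the statistics well-estimated for participants with few records and
leaves between-subject level differences visible to the model.

## Model

Widths default to `d = 128` (tests and benchmarks use 32–64; the width is
a capacity/runtime trade-off, not a structural choice).

1. **Encoders.** ZCM, PIM, and speech each pass through their own 2-layer
   feed-forward network (linear → ReLU → dropout 0.1 → linear) to width d.
2. **Physical-activity stream.** The ZCM and PIM embeddings are
   concatenated and projected back to d.  The fusion stage weights exactly
   two modalities — physical activity and speech — because the two
   actigraphy modes are views of the same sensor; a three-way fusion over
   (zcm, pim, speech) is available behind `ModelConfig.three_way_fusion`.
3. **DRUW fusion.** `fused = Σ_m w_m h_m` with `w_m = exp(−s_m)/2` and a
   penalty `Σ_m s_m/2 + λ_f (Σ_m w_m − τ_f)²` added to the objective.
   `τ_f` defaults to M/2 (so the symmetric initialization σ_m = 1,
   i.e. w_m = 1/2, is penalty-free) and `λ_f` to 0.1.  The fused vector is
   not re-normalized after weighting; the downstream layer norms make the
   model robust to the overall scale, so the weights act mostly through
   the modality *ratio*.
4. **Macro space.** An emotional FFNN (2-layer, d → d) maps the fused
   vector; the triple (emotional output, phys stream, speech stream) forms
   a 3-token sequence with learned token-type embeddings, processed by one
   post-norm transformer encoder layer (4 heads, feed-forward 4d) and
   mean-pooled into the macro embedding M.  This is the minimal sequence
   structure that lets attention arbitrate between the fused summary and
   the raw modality streams.
5. **Micro personalization.** `P_i = α M + (1 − α)(M + f_i(M))` where
   `f_i` is a per-participant 1-hidden-layer perturbation whose output
   layer starts at zero — every micro layer is the identity at
   initialization, so personalization grows out of the macro solution.
   α defaults to a fixed 0.5; per-participant learnable α (logistic
   reparameterization) is available.  Unknown participants at inference
   fall back to P = M with a logged warning.
   The micro layer consumes the macro embedding rather than the fused
   features: personalization is then a selection/adjustment in the shared
   emotional space, and the macro path stays the single bottleneck.
6. **Heads.** Nine linear heads with a logistic output keep predictions in
   (0, 1), matching the normalized labels.

## Objectives

Per-task losses default to MSE over the batch (batch size 16 makes
batch-level CCC losses noisy; `1 − CCC` is available by configuration).
The DRUW multitask total is

    Σ_k w_k L_k + Σ_k s_k/2 + λ (Σ_k w_k − τ)²,   w_k = exp(−s_k)/2,

parameterized by `s = log σ²` for unconstrained optimization, with
λ = 0.1 and τ = K/2 by default.  Minimizing over s gives larger σ (smaller
weight) to larger losses — adaptive balancing — while the restraint and
log terms bound the weights away from the trivial zero solution.  Baseline
combiners (equal mean, fixed weights, plain sum for the multi-output
baseline) share the same per-task losses.

## Training

SGD with Nesterov momentum 0.9, initial learning rate 0.001, batch size
16, weight decay 1e-4, up to 100 epochs.  The learning rate decays by 0.9
whenever the development mean CCC fails to improve (strict increase by
more than 1e-6) for 5 consecutive epochs, with the patience counter reset
after each decay.  The checkpoint with the best development mean CCC is
selected.  Weight decay applies to network weights only — decaying the
log-variances s or α would bias the uncertainty weights toward 1/2 —
and dropout is disabled at evaluation time.

**Frequency-compensated personalization rate.**  Each participant's micro
layer (or adapter) is touched only by that participant's records — about
1/P of the batches for P participants — so at the shared learning rate the
personal layers move P times slower than the shared trunk and barely adapt
within a standard schedule.  The trainer therefore places per-participant
parameters in their own optimizer group with the learning rate scaled by
the number of participants (`personal_lr_scale="auto"`, overridable).
This is the usual remedy for sparsely-updated per-user parameters and is
what makes the macro-then-micro narrative work within a fixed epoch
budget.

## Evaluation and validation

CCC is computed with population moments; a constant series yields CCC 0
with a degenerate flag.  Per-emotion CCCs are pooled over all records of a
split part (not averaged per participant), the convention in affect
regression; the table reports the nine values plus their mean (SD).
Single-modality results use a mask that zeroes the excluded encoders'
standardized inputs (zero = the training-set mean level).

The within-individual validation fits, per emotion, a linear mixed model
of observed on predicted ratings with a participant random intercept
(statsmodels MixedLM, REML) and reports intercept, slope, SE, z, p, 95%
CI, group variance, and residual variance.  Singular or non-converged
fits are flagged per emotion rather than failing the run.

## Synthetic EMA generator

The simulator emulates the structure of a two-week office-worker EMA
study: each participant is prompted five times a day — wake (~7:00 ± 30
min), 11:00 / 15:00 / 19:00 each ± 10 min, and bed (~23:00 ± 30 min) —
giving 70 records per participant at the defaults, with optional uniform
record dropout.

The generative model:

- latent affect state `z_t ∈ R³` (valence, arousal, distress) follows a
  per-participant AR(1) with coefficient φ = 0.6 and unit stationary
  variance;
- labels: `100 · logistic(B_i z_t + c + u_i + ε)`, with a fixed read-out
  pattern B mapping positive moods to +valence and anxious/depressive
  moods to +distress/−valence, per-subject loading perturbation
  `B_i = B + δB_i` (entry SD 0.1), subject offset `u_i` (SD τ_u = 0.15),
  and measurement noise ε (SD 0.05), all on the logit scale;
- ZCM windows: 60 Poisson draws with log-rate shifted by arousal
  (base 30 counts/min); PIM windows: 60 log-normal draws with log-mean
  shifted by arousal (base 200, log-SD 0.5), mean-corrected so the neutral
  expectation equals the base level;
- speech: `a·(W z) + v_i + noise`, with a dataset-wide random encoder W,
  a participant voiceprint `v_i` (SD 0.5), and amplitude/noise set by a
  per-modality SNR (`a = √(snr/(1+snr))`); SNR 0 makes a modality
  statistically independent of the labels.  A `speech_latent_mask` can
  silence chosen latent dimensions in the speech channel to create
  complementary modality signals.

B's scale (row norms ≈ 0.35 on the logit scale) was chosen so that
within-person label fluctuation is ~8 VAS points and the between-subject
share of label variance is ~15% — the orders of magnitude EMA mood data
show.  The published study does not report label distributions or
inter-emotion correlations, so these defaults are structural stand-ins,
not estimates of any real population.

What the simulator does *not* emulate: circadian and weekday structure,
missing-not-at-random compliance, label drift/reactivity, raw audio or
raw accelerometry, and real DAMS inter-item covariance.  Passing the
recovery benchmarks therefore shows the pipeline can learn the kinds of
structure it targets (shared affect dynamics, subject-level offsets,
modality-specific information), not that it attains any particular
accuracy on real studies.

## Benchmark experiments (tests and acceptance script)

Problem sizes are desk-scale by design: 24–60 participants, 14 days,
speech width 32–64, embedding width 32–64, 15–30 epochs.  The three
directional benchmarks:

- **Personalization recovery** — with subject offsets (τ_u = 0.15), the
  macro-micro model beats an otherwise identical macro-only model by
  ≥ 0.05 test mean CCC on every seed tried (observed gaps ≈ +0.07).
  Oracle ceilings computed from the generative process put the available
  gap at ≈ +0.17, so the bar is well inside what a correct implementation
  can reach.
- **Multimodal benefit** — with speech silent on arousal (which drives
  the actigraphy), the DRUW-fused model is at least as good as the best
  single-modality model.
- **Noise rejection** — with zero-SNR speech, the learned speech fusion
  weight ends below the physical-activity weight.  Note the restraint
  equilibrium (0.5 = 2λw(Σw − τ), i.e. w ≈ 1.396 at the defaults) attracts
  both weights over long schedules; the separation induced by the data
  gradient is read out after a moderate 15-epoch schedule where it is
  clearly visible.

## Known limitations

- The per-task loss family and the exact restraint expression follow the
  standard uncertainty-weighting construction; other parameterizations
  (e.g. weights 1/σ rather than 1/(2σ²)) would behave similarly but are
  not implemented.
- Fusion weights are global, not per record; contextual weighting is only
  available through the gated/attention baselines.
- The mixed-model validation treats predictions as fixed regressors
  (no measurement-error correction).
- Micro layers require each participant to appear in training; cold-start
  participants receive the macro prediction.
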