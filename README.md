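# moodfuse

Personalized daily mental-health monitoring from everyday wearables:
a macro-micro multimodal multitask learning framework for predicting
momentary mood from wrist actigraphy and speech embeddings.

## The problem

Ecological momentary assessment (EMA) studies prompt participants several
times a day to rate their current mood — here nine emotion intensities
(vigorous, gloomy, concerned, happy, unpleasant, anxious, cheerful,
depressed, worried) on a 0–100 visual-analogue scale.  Alongside each
prompt, a wrist-worn accelerometer provides a 60-minute window of
per-minute activity counts in two modes — zero-crossing mode (ZCM) and
proportional-integration mode (PIM) — and a short voice recording yields a
fixed-width speech embedding.  The modelling task is a 9-output regression:
predict the normalized mood ratings from the actigraphy windows and the
speech features, for many participants at once, while respecting that mood
expression is strongly idiosyncratic.

`moodfuse` implements the full pipeline for this problem:

- **DRUW fusion** — dynamic restrained uncertainty weighting of the two
  modality streams.  Each modality *m* carries a learnable log-variance
  `s_m = log σ_m²`; the fused embedding is `Σ_m w_m h_m` with
  `w_m = exp(−s_m)/2 = 1/(2σ_m²)`, and the objective gains a penalty
  `Σ_m s_m/2 + λ_f (Σ_m w_m − τ_f)²` whose restraint term keeps the total
  weight near `τ_f` so neither modality is silenced or inflated.
- **Macro-micro personalization** — a shared ("macro") emotional space is
  built by an emotional feed-forward network plus a transformer encoder
  layer over the fused and per-modality embeddings; a per-participant
  ("micro") residual layer then adapts it:
  `P_i = α M + (1 − α) FFNN_i(M)`, with blending factor `α ∈ [0, 1]`.
- **DRUW multitask loss** — the nine per-emotion losses are combined as
  `Σ_k w_k L_k + Σ_k s_k/2 + λ (Σ_k w_k − τ)²` with `w_k = exp(−s_k)/2`,
  so harder/noisier emotions are adaptively down-weighted while the
  restraint prevents the trivial all-weights-to-zero solution.
- **Evaluation** — per-emotion concordance correlation coefficient
  (CCC = 2ρσ_xσ_y / (σ_x² + σ_y² + (μ_x − μ_y)²)) on a chronological
  70/15/15 per-participant split, plus a mixed linear model of observed on
  predicted ratings with participant random intercepts.
- **Comparison grid** — the alternative fusion (concatenation, max, gated,
  attention, solo-attention, cross-modal, fixed weights), personalization
  (shared FFNN, transformer-only, adapters), and multitask (equal, fixed,
  multi-output) strategies, selectable per run.
- **Synthetic EMA simulator** — since real EMA mood datasets are private,
  the package ships a generator producing studies with the same structure:
  per-participant latent AR(1) affect states, logistic label read-outs
  with subject-specific offsets, Poisson/log-normal actigraphy windows,
  and SNR-controlled speech encodings, with exported ground truth for
  recovery experiments.

All neural components run on a small numpy reverse-mode autodiff engine
bundled with the package (`moodfuse.nn`); there is no deep-learning
framework dependency.

## Worked example

```python
from moodfuse import (EmotionModel, ModelConfig, TrainConfig,
                      evaluate, preprocess, train)
from moodfuse.simulate import SimulatorConfig, simulate_dataset

# a small synthetic EMA study: 30 office workers, 2 weeks, 5 prompts/day
dataset, truth = simulate_dataset(
    SimulatorConfig(n_participants=30, n_days=14, speech_dim=32, seed=1))
ds, split, stats, report = preprocess(dataset)   # clean, normalize, split, z-score

model = EmotionModel(ds.participants(), ds.speech_dim,
                     config=ModelConfig(embed_dim=32, hidden_dim=32), seed=1)
checkpoint, history = train(model, ds, split, TrainConfig(epochs=20, seed=1))
print(f"best dev mean CCC {checkpoint.best_dev_ccc:.3f} "
      f"at epoch {checkpoint.best_epoch}")
print(evaluate(model, ds, split, part="test"))
```

Output:

```
best dev mean CCC 0.795 at epoch 19
[test/all] vigorous=0.792  gloomy=0.819  concerned=0.824  happy=0.791  unpleasant=0.748  anxious=0.813  cheerful=0.725  depressed=0.816  worried=0.738  mean=0.785 (SD 0.036)
```

The per-emotion numbers are pooled test-set CCCs between predicted and
self-reported normalized ratings; `mean (SD)` summarizes across the nine
emotions.  On this synthetic study roughly 0.8 mean CCC is attainable in
20 epochs; the residual gap is the simulator's label noise plus whatever
per-subject structure the schedule has not yet absorbed.

The same pipeline is available from the shell:

```bash
moodfuse simulate --out data.csv --truth truth.json --seed 1 --n-participants 30
moodfuse train --data data.csv --out run/ --seed 1 --epochs 20 --embed-dim 32
moodfuse evaluate --run run/ --data data.csv --part test --modality all
moodfuse validate --run run/ --data data.csv --out mixed_model.csv
moodfuse ablate --data data.csv --fusion gated --personalization basic_ffnn \
    --mtl equal --out grid.csv
```

YAML configuration files can be passed with `--config`; precedence is
CLI flag > config file > built-in default (`moodfuse show-config` prints
the defaults).  Every command writes a manifest with its config snapshot,
seed, and input digests so runs can be reproduced exactly.

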