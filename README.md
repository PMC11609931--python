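# ildim — multimodal fusion-attention classification of interstitial lung disease

Interstitial lung disease (ILD) is diagnosed from several complementary
information streams at once: chest CT imaging (honeycomb/ground-glass
fibrotic texture), physiological indicators such as arterial oxygen
pressure (PaO₂ runs ≈85 mmHg in cases vs ≈95 mmHg in controls), and the
patient's free-text history. `ildim` implements a multimodal classifier
that encodes each stream separately and learns *how much to trust each
stream* through an attention-based fusion head, plus a synthetic cohort
generator so the whole pipeline — including the modality ablation study —
runs and is tested without any clinical data.

## The model

Per subject, three encoders produce fixed-width features:

- **H_i = CNN(X_image)** — conv → ReLU → 2×2 max-pool blocks (valid
  cross-correlation), global average pooling, linear map;
- **H_n = Bi-LSTM(X_num)** — standard LSTM gate equations run forward and
  backward over the series, hidden states merged by elementwise sum,
  mean-pooled over time;
- **H_t = SelfAttention(X_text)** — embeddings + sinusoidal positions,
  multi-head scaled dot-product attention
  (E_ij = Q_iᵀK_j/√d_k, A = softmax(E), SA_i = Σ_j A_ij V_j).

The fusion head projects each feature (α_m = tanh(W_m H_m)), lets the
three modality tokens attend to each other (β = MHSA([α_i, α_n, α_t])),
scores each fused token with a learned vector, softmaxes the scores into
simplex weights w, and classifies the weighted fusion M = Σ_m w_m β_m
with a softmax affine layer trained by cross-entropy under AdamW.
Everything — convolution, LSTM, attention, backprop, the optimizer — is
implemented on numpy float64 with a small reverse-mode autodiff engine
and verified against brute-force oracles and finite differences.

## Worked example

```python
from ildim import (GeneratorConfig, generate_dataset, split_samples,
                   ModelConfig, TrainConfig, train, evaluate)

gen = GeneratorConfig(n_cases=40, n_controls=20, rng_seed=7)  # default cohort shape
samples, manifest = generate_dataset(gen)
train_set, test_set = split_samples(samples, manifest)

params, history = train(train_set, ModelConfig(), TrainConfig(epochs=25, rng_seed=1))
report = evaluate(params, test_set)
print(f"final training loss {history[-1]:.3f}")
print(f"AUC={report.auc:.3f}  precision={report.precision:.3f}  "
      f"recall={report.recall:.3f}  F1={report.f1:.3f}")
print("confusion [[TN FP] [FN TP]] =", report.confusion.tolist())
```

prints

```
final training loss 0.000
AUC=1.000  precision=0.889  recall=1.000  F1=0.941
confusion [[TN FP] [FN TP]] = [[3, 1], [0, 8]]
```

The 60-subject cohort (40 ILD / 20 non-ILD) is split 80/20 with
stratification; on the 12 held-out subjects the model ranks every case
above every control (AUC 1.0) and misclassifies one control at the 0.5
threshold. Per-sample fusion weights are available via
`ildim.fusion.fusion_state(sample, params).weights`.

## Command line

```
ildim simulate --seed 1 --out data/            # write PNG/CSV/JSONL fixtures
ildim train    --data data/ --seed 1 --out run/
ildim evaluate --data data/ --checkpoint run/checkpoint.zip --out run/
ildim ablate   --data data/ --seed 1 --out runs/   # six modality subsets
ildim inspect  --large-image                        # parameter / FLOP tables
```

`ablate` retrains the model from scratch for each of the six modality
combinations ({image}, {series}, {image, series}, {series, text},
{image, text}, all three) under identical seeds and writes one metrics
JSON + ROC CSV per subset plus a ranked summary.

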