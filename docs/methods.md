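# Methods

## The model

The classifier fuses three modality streams per subject — a 2-D grayscale
image standing in for a chest-CT slice, a T×D physiological time series
whose first channel plays the role of PaO₂ (mmHg), and a token sequence
from free-text history — into a binary ILD / non-ILD decision.

**Image encoder.** A stack of blocks, each a valid (no padding, stride 1)
cross-correlation, ReLU, and non-overlapping 2×2 max pooling; then global
average pooling over the remaining grid and a linear map to the shared
width `d_model`, giving H_i. Cross-correlation (the unflipped kernel) is
the convention implemented; a kernel of height M and width N maps an H×W
input to (H−M+1)×(W−N+1).

**Series encoder.** A bidirectional LSTM with the standard gate equations

    i_t = σ(W_i[h_{t−1}, x_t] + b_i)        f_t = σ(W_f[h_{t−1}, x_t] + b_f)
    c̃_t = tanh(W_c[h_{t−1}, x_t] + b_c)     c_t = f_t∘c_{t−1} + i_t∘c̃_t
    o_t = σ(W_o[h_{t−1}, x_t] + b_o)        h_t = o_t∘tanh(c_t)

The backward pass runs the same recursion on the reversed sequence with a
zero-initialized state. The two directions are merged by **elementwise
sum** at each step (so they share one hidden size), the merged sequence is
pooled over time (mean by default; last-step via config), and a linear map
yields H_n. Inputs are z-scored per channel with training-split statistics
only, to avoid leakage.

**Text encoder.** Embedding lookup plus sinusoidal positional encoding,
one multi-head self-attention block with a residual connection and no
layer norm, then a mean over token positions gives H_t. Scores are
E_ij = Q_i·K_j / √d_k (the `score_scale: dk` flag selects a plain d_k
denominator instead), weights are the row-softmax of E, and each output
row is the A-weighted convex combination of value rows. Head outputs are
concatenated along the feature axis and mixed by W_O. An empty token
sequence encodes to the zero vector.

**Fusion head.** Each modality feature is projected, α_m = E(W_m H_m),
with E(·) elementwise tanh (identity via config). The α vectors form a
3-token sequence fed through a second multi-head self-attention block,
giving fused tokens β_m. A learned scoring vector s produces per-modality
scores E_m = s·β_m, softmaxed into simplex weights w, and the fused
representation is M = Σ_m w_m β_m (config can fuse the α tokens instead of
the β tokens). A softmax affine classifier on M gives class probabilities;
cross-entropy (probabilities clamped at 1e−12 before the log) is the
training loss. Under a modality-subset configuration only the present
branches are instantiated and the fusion softmax runs over the present
modalities.

**Optimization.** All gradients come from a small reverse-mode autodiff
engine written for this package (float64 throughout; validated against
central finite differences in the test suite). AdamW with decoupled weight
decay updates the parameters; decay is applied to matrices and not to bias
vectors. Defaults: learning rate 1e−3, weight decay 1e−2, betas
(0.9, 0.999), ε 1e−8, batch 16, 50 epochs — all in `TrainConfig`.
Initialization is uniform in ±1/√fan_in, fully seeded.

## The synthetic cohort generator

No clinical data ships with the package; the generator emulates the
salient class differences so every stage is testable end to end.

| knob | default | meaning |
| --- | --- | --- |
| n_cases / n_controls | 40 / 20 | cohort shape (2:1 imbalance kept; no reweighting) |
| image_size | 64 | pixels, grayscale |
| series_length / channels | 32 / 4 | steps × channels; channel 0 is PaO₂-like |
| vocab_size | 120 | token ids; ids 0–7 case symptoms, 8–15 control symptoms |
| signal_image/series/text | 1.0 | per-modality class-signal strength in [0, 1] |
| pao2_case_mean / control_mean | 85 / 95 mmHg | stationary means of channel 0 |
| pao2_sd | 5 mmHg | marginal SD of the AR(1) PaO₂ channel (φ = 0.8) |
| train_fraction | 0.8 | stratified split; split seed separate from data seed |

*Images*: smooth Gaussian-filtered background (level 0.4, field SD 0.08)
plus pixel noise (SD 0.04); cases add a periodic sin²·sin² "honeycomb"
texture (period 4 px, amplitude 0.25·strength) in a peripheral annulus
(radius 0.55–0.95 of the half-width), values clipped to [0, 1] and
quantized to 8 bits on disk. *Series*: channel 0 is a stationary AR(1)
process whose mean slides linearly from 95 toward 85 mmHg with strength;
remaining channels are standard-normal nuisance noise. *Text*: each token
is a symptom token with probability 0.4; a symptom token comes from the
case sub-vocabulary with probability 0.5 + strength/2 for cases and
0.5 − strength/2 for controls, so at strength 0 the two classes share one
distribution (and one RNG path — the draw is bit-identical across labels).
Lengths are uniform on [16, 32].

What the generator does **not** emulate: spatial anatomy or DICOM
geometry, irregular sampling or missing values in the series, natural
language beyond bag-of-symptom token statistics, label noise, and
covariate shift between sites. Passing tests therefore demonstrate that
the pipeline recovers a planted, well-specified signal — not clinical
performance.

## Evaluation and the ablation study

Precision, recall and F1 are reported for the ILD class at the argmax
threshold (0.5 for two classes); the 2×2 confusion matrix has truth in
rows and prediction in columns. AUC is the Mann-Whitney probability that a
random case outscores a random control, ties counted 1/2, computed from
ranks; ROC points come from the score sweep. A single-class test split
yields the threshold metrics but no AUC (reported as undefined).

The ablation runner retrains the model **from scratch** for each modality
subset — by default the six study combinations: {image}, {series},
{image, series}, {series, text}, {image, text}, {image, series, text} —
under identical seeds, and ranks subsets by AUC. Multi-seed studies
(`repeat_study`) redraw the cohort and retrain per seed and report the
per-seed spread; band-style checks (e.g. a null experiment's AUC lying
near 0.5) are applied to the mean over seeds, since per-seed AUC at
desk-scale test sizes (n ≈ 120) has an SD near 0.1 even under the null.

## Problem sizes and numerical choices

The multi-seed experiments in the tests and in `scripts/acceptance.py` use
a 600-subject cohort (400/200) at full signal strength, an 80/20
stratified split, five seeds, and a training protocol of 10 epochs at
batch 64 — enough for the loss to plateau on this cohort, chosen as the
package's desk-scale study size. The reference architecture is 64×64
grayscale input, two conv blocks (8 and 16 channels, 3×3 kernels), hidden
size 20, d_model 64, 4 attention heads. The `large_image()` profile (224×224
RGB, one 3→64 block) exists only for parameter-count introspection; note
that with valid padding its first block yields 111×111 after pooling, not
the 112×112 a padded convolution would give — the parameter counts are
unaffected by padding.

Other numerical choices: softmaxes subtract the row max before
exponentiation; the logistic is evaluated on the numerically stable branch
for either sign; ties in `argmax` predictions break toward the lower class
index; 2×2 pooling drops a trailing odd row/column and routes gradients to
one winner per window (earlier element wins ties); the FLOP estimator
counts multiply-accumulates in the matmul-dominated terms (1 MAC = 2
FLOPs) and ignores elementwise gates, softmaxes and pooling.

## Design choices where the design was open

- Bi-LSTM directions merge by sum, not concatenation.
- Temporal pooling and token pooling are means (last-step pooling is a
  config option for the series branch).
- Attention score scaling uses √d_k by default; the plain-d_k variant is
  preserved behind `score_scale: dk`.
- The projection nonlinearity E(·) is tanh; fusion scores are a learned
  vector dotted with each fused token; the fused tokens are the attention
  outputs β (the α reading is available via `fuse_input: alpha`).
- One attention block per encoder, residual connection in the text
  encoder only, no layer norm anywhere.
- The modality subset is part of the model configuration (it determines
  which branches exist), not of the training configuration.

## Known limitations

Training is plain full-batch-shuffled AdamW with no early stopping,
validation split, or class reweighting. The classifier threshold is fixed
at argmax, which under 2:1 imbalance can trade precision for recall on
small test splits. The engine is single-threaded numpy and intended for
desk-scale cohorts, not production imaging volumes.
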