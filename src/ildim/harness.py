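"""Training, evaluation, modality ablation and model introspection.

Training minimizes mean cross-entropy with AdamW (decoupled weight decay;
decay applies to matrices, not to bias vectors).  Evaluation reports
precision/recall/F1 for the ILD class at the argmax threshold, a 2x2
confusion matrix (rows = truth, cols = prediction), ROC points, and AUC
computed as the Mann-Whitney probability that a random case outscores a
random control (ties counted 1/2).

The ablation runner retrains the model from scratch for each modality
subset — the six study combinations by default: the two informative
single streams, the three pairings, and the full tri-modal input — under
identical seeds, then ranks the subsets by AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from . import fusion
from .config import ModelConfig, TrainConfig
from .synthetic import MultimodalSample, split_samples

__all__ = ["MetricReport", "LayerParamRow", "train", "evaluate", "ablate",
           "auc_mann_whitney", "count_parameters", "estimate_flops",
           "ABLATION_SUBSETS", "run_experiment"]

# the six modality combinations of the ablation study
ABLATION_SUBSETS = (
    ("image",),
    ("series",),
    ("image", "series"),
    ("series", "text"),
    ("image", "text"),
    ("image", "series", "text"),
)


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion: np.ndarray               # [[TN, FP], [FN, TP]]
    roc_points: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": np.asarray(self.confusion).astype(int).tolist(),
        }


@dataclass
class LayerParamRow:
    layer: str
    output_shape: tuple
    params: int


# ------------------------------------------------------------ training

class AdamW:
    """Adam with decoupled weight decay; decay skips 1-D (bias) arrays."""

    def __init__(self, leaves, tc: TrainConfig):
        self.leaves = leaves
        self.tc = tc
        self.m = [np.zeros_like(t.data) for t in leaves]
        self.v = [np.zeros_like(t.data) for t in leaves]
        self.t = 0

    def step(self):
        tc = self.tc
        self.t += 1
        b1, b2 = tc.adam_beta1, tc.adam_beta2
        for leaf, m, v in zip(self.leaves, self.m, self.v):
            g = leaf.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            if leaf.data.ndim >= 2:
                leaf.data -= tc.learning_rate * tc.weight_decay * leaf.data
            leaf.data -= tc.learning_rate * mhat / (np.sqrt(vhat) + tc.epsilon)


def _series_norm_stats(samples):
    X = np.concatenate([s.series for s in samples], axis=0)
    return X.mean(axis=0), X.std(axis=0)


def train(samples: list[MultimodalSample], model_config: ModelConfig,
          tc: TrainConfig):
    """Fit the model on ``samples``; returns (parameters, epoch loss history)."""
    if not samples:
        raise ValueError("training set is empty")
    labels = {s.label for s in samples}
    if len(labels) < 2:
        raise ValueError("training set must contain both classes")
    params = fusion.init_model(model_config, seed=tc.rng_seed)
    if params.series is not None:
        mean, std = _series_norm_stats(samples)
        params.series.norm_mean = mean
        params.series.norm_std = std
    leaves = fusion.tensorize(params)
    opt = AdamW(leaves, tc)
    shuffle_rng = np.random.default_rng(tc.rng_seed + 1)
    history = []
    n = len(samples)
    for _ in range(tc.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, tc.batch_size):
            batch = [samples[i] for i in order[lo:lo + tc.batch_size]]
            loss = fusion.batch_loss(params, batch)
            epoch_loss += float(loss.data) * len(batch)
            if tc.learning_rate > 0:
                loss.backward()
                opt.step()
        history.append(epoch_loss / n)
    return fusion.detensorize(params), history


# ------------------------------------------------------------ metrics

def classification_metrics(tn: int, fp: int, fn: int, tp: int):
    """(precision, recall, F1) for the positive class from 2x2 counts."""
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    return precision, recall, f1


def auc_mann_whitney(y_true, scores) -> float:
    """P(score_case > score_control) with ties counted 1/2 (rank form)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = y_true == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: need both classes in the test split")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(params: fusion.ModelParameters, samples: list[MultimodalSample],
             positive_class: int = 1) -> MetricReport:
    """Score a test split; AUC is None (and ROC empty) if only one class."""
    if not samples:
        raise ValueError("test set is empty")
    scores = np.empty(len(samples))
    preds = np.empty(len(samples), dtype=int)
    y = np.asarray([s.label for s in samples])
    for i in range(0, len(samples), 64):
        chunk = samples[i:i + 64]
        probs = fusion.forward_batch(params, chunk)[0].data
        scores[i:i + 64] = probs[:, positive_class]
        preds[i:i + 64] = probs.argmax(axis=1)
    tp = int(np.sum((y == 1) & (preds == 1)))
    fp = int(np.sum((y == 0) & (preds == 1)))
    fn = int(np.sum((y == 1) & (preds == 0)))
    tn = int(np.sum((y == 0) & (preds == 0)))
    precision, recall, f1 = classification_metrics(tn, fp, fn, tp)
    if len(np.unique(y)) == 2:
        auc = auc_mann_whitney(y, scores)
        fpr, tpr, _ = roc_curve(y, scores)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    else:
        auc, roc_points = None, []
    return MetricReport(
        precision=precision, recall=recall, f1=f1, auc=auc,
        confusion=np.array([[tn, fp], [fn, tp]]), roc_points=roc_points,
    )


# ------------------------------------------------------------ ablation

def ablate(dataset, model_config: ModelConfig, tc: TrainConfig,
           subsets=ABLATION_SUBSETS):
    """Retrain from scratch per modality subset; returns {subset: report}.

    ``dataset`` is the (samples, manifest) pair from the generator; the
    manifest's split tags select train/test.  Seeds are shared across
    subsets so differences reflect the modalities, not the draw.
    """
    samples, manifest = dataset
    train_s, test_s = split_samples(samples, manifest)
    reports = {}
    for subset in subsets:
        subset = tuple(subset)
        if not subset:
            raise ValueError("modality subset must be non-empty")
        cfg = model_config.with_modalities(subset)
        params, _ = train(train_s, cfg, tc)
        reports[subset] = evaluate(params, test_s)
    return reports


def rank_subsets(reports: dict) -> list:
    """Subsets ordered best-first by AUC (F1 as tie-break)."""
    return sorted(
        reports,
        key=lambda s: (-(reports[s].auc if reports[s].auc is not None else -1),
                       -reports[s].f1),
    )


def run_experiment(dataset, model_config: ModelConfig, tc: TrainConfig):
    """Plain train+evaluate on the manifest split; returns (params, history,
    report)."""
    samples, manifest = dataset
    train_s, test_s = split_samples(samples, manifest)
    params, history = train(train_s, model_config, tc)
    return params, history, evaluate(params, test_s)


def repeat_study(subsets, seeds, generator_config=None, model_config=None,
                 epochs: int = 10, batch_size: int = 64,
                 shuffle_labels: bool = False):
    """Multi-seed modality study: regenerate the cohort and retrain per seed.

    For each seed a fresh synthetic cohort is drawn (the seed drives both
    the generator and the training run) and every subset is retrained from
    scratch.  With ``shuffle_labels`` the labels are randomly permuted
    across subjects before splitting — the null experiment.  Returns
    {subset: [MetricReport per seed]}.
    """
    from .synthetic import GeneratorConfig, MultimodalSample, generate_dataset

    base_gen = generator_config or GeneratorConfig()
    model_config = model_config or ModelConfig()
    results = {tuple(s): [] for s in subsets}
    for seed in seeds:
        gen_cfg = GeneratorConfig(**{**base_gen.to_dict(), "rng_seed": seed})
        samples, manifest = generate_dataset(gen_cfg)
        if shuffle_labels:
            rng = np.random.default_rng(seed + 500_009)
            labels = rng.permutation([s.label for s in samples])
            samples = [
                MultimodalSample(s.sample_id, s.image, s.series, s.tokens,
                                 int(lab))
                for s, lab in zip(samples, labels)
            ]
            manifest = manifest.assign(label=[s.label for s in samples])
        tc = TrainConfig(rng_seed=seed, epochs=epochs, batch_size=batch_size)
        reports = ablate((samples, manifest), model_config, tc, subsets=subsets)
        for subset, rep in reports.items():
            results[subset].append(rep)
    return results


# ------------------------------------------------------------ introspection

def dense_param_count(n_in: int, n_out: int, bias: bool = True) -> int:
    """Trainable parameters of a fully connected layer."""
    return n_out * n_in + (n_out if bias else 0)


def conv_param_count(c_in: int, c_out: int, kh: int, kw: int,
                     bias: bool = True) -> int:
    """Trainable parameters of a 2-D convolution layer."""
    return c_out * c_in * kh * kw + (c_out if bias else 0)


def _conv_shapes(cfg: ModelConfig):
    """(post-conv, post-pool) spatial shapes per block of the image branch."""
    shapes = []
    h = w = cfg.image_size
    k = cfg.image_encoder.kernel_size
    for c_out in cfg.image_encoder.channels:
        h, w = h - k + 1, w - k + 1
        conv_shape = (c_out, h, w)
        h, w = h // 2, w // 2
        shapes.append((conv_shape, (c_out, h, w)))
    return shapes


def count_parameters(model_config: ModelConfig):
    """Per-layer parameter table plus total; the total matches an exhaustive
    enumeration of the instantiated parameter arrays exactly."""
    cfg = model_config
    rows = []
    ic, sc, tc_, fc = (cfg.image_encoder, cfg.sequence_encoder,
                       cfg.text_encoder, cfg.fusion)
    if "image" in cfg.modalities:
        c_in = ic.in_channels
        for shapes, c_out in zip(_conv_shapes(cfg), ic.channels):
            conv_shape, pool_shape = shapes
            rows.append(LayerParamRow(
                f"Conv2d (in_channels={c_in}, out_channels={c_out})",
                conv_shape,
                conv_param_count(c_in, c_out, ic.kernel_size, ic.kernel_size),
            ))
            rows.append(LayerParamRow("ReLU", conv_shape, 0))
            rows.append(LayerParamRow("MaxPool2d (kernel_size=2)", pool_shape, 0))
            c_in = c_out
        rows.append(LayerParamRow(
            "Linear (Image Feature)", (cfg.d_model,),
            dense_param_count(ic.channels[-1], cfg.d_model),
        ))
    if "series" in cfg.modalities:
        h, d = sc.hidden_size, sc.channels
        rows.append(LayerParamRow(
            f"Bi-LSTM (input_size={d}, hidden_size={h})",
            (cfg.series_length, h),
            2 * 4 * (h * (h + d) + h),
        ))
        rows.append(LayerParamRow(
            "Linear (Series Feature)", (cfg.d_model,),
            dense_param_count(h, cfg.d_model),
        ))
    if "text" in cfg.modalities:
        rows.append(LayerParamRow(
            "Embedding", (tc_.vocab_size, cfg.d_model),
            tc_.vocab_size * cfg.d_model,
        ))
        rows.append(LayerParamRow(
            f"SelfAttention (heads={tc_.heads})", (cfg.d_model,),
            4 * cfg.d_model * cfg.d_model,
        ))
    k = len(cfg.modalities)
    rows.append(LayerParamRow(
        "Linear (Modality Projections)", (k, cfg.d_model),
        k * cfg.d_model * cfg.d_model,
    ))
    rows.append(LayerParamRow(
        f"FusionAttention (heads={fc.heads})", (k, cfg.d_model),
        4 * cfg.d_model * cfg.d_model,
    ))
    rows.append(LayerParamRow("Linear (Attention Weights)", (k,), cfg.d_model))
    rows.append(LayerParamRow(
        "Linear (Classifier)", (cfg.n_classes,),
        dense_param_count(cfg.d_model, cfg.n_classes),
    ))
    total = sum(r.params for r in rows)
    return rows, total


def estimate_flops(model_config: ModelConfig):
    """Analytic multiply-accumulate counts per layer (1 MAC = 2 FLOPs).

    Elementwise gates/activations and softmaxes are not counted; the
    matmul-dominated terms are.  Text cost uses a nominal sequence length
    equal to the mean of the generator's length range (24 tokens).
    """
    cfg = model_config
    rows = []
    ic, sc, tc_ = cfg.image_encoder, cfg.sequence_encoder, cfg.text_encoder
    if "image" in cfg.modalities:
        h = w = cfg.image_size
        c_in = ic.in_channels
        k = ic.kernel_size
        for i, c_out in enumerate(ic.channels):
            ho, wo = h - k + 1, w - k + 1
            rows.append((f"conv{i}", ho * wo * c_out * c_in * k * k))
            h, w = ho // 2, wo // 2
            c_in = c_out
        rows.append(("image_out", ic.channels[-1] * cfg.d_model))
    if "series" in cfg.modalities:
        hd, d, T = sc.hidden_size, sc.channels, cfg.series_length
        rows.append(("bilstm", 2 * T * 4 * hd * (hd + d)))
        rows.append(("series_out", hd * cfg.d_model))
    if "text" in cfg.modalities:
        n, dm = 24, cfg.d_model
        d_k = dm // tc_.heads
        proj = 3 * n * dm * d_k * tc_.heads
        attn = 2 * n * n * d_k * tc_.heads
        rows.append(("text_attention", proj + attn + n * dm * dm))
    kmod, dm = len(cfg.modalities), cfg.d_model
    d_k = dm // cfg.fusion.heads
    rows.append(("projections", kmod * dm * dm))
    rows.append(("fusion_attention",
                 3 * kmod * dm * d_k * cfg.fusion.heads
                 + 2 * kmod * kmod * d_k * cfg.fusion.heads
                 + kmod * dm * dm))
    rows.append(("scores+classifier", kmod * dm + cfg.n_classes * dm))
    total_macs = sum(m for _, m in rows)
    return rows, total_macs, 2 * total_macs
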