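"""Attention-weighted modality fusion and the assembled classifier.

Given per-modality features H_m (m in {image, series, text}, each of
length d_model) the fusion head:

1. projects each modality, alpha_m = E(W_m H_m), with E an elementwise
   nonlinearity (tanh by default, identity by config);
2. stacks the alphas as a short token sequence and applies multi-head
   self-attention across modalities, giving fused tokens beta_m;
3. scores each fused token with a learned vector s, E_m = s . beta_m, and
   softmaxes the scores into simplex fusion weights w;
4. forms the fused representation M = sum_m w_m beta_m;
5. classifies with softmax(lambda M + b) and trains with cross-entropy.

Under a modality-subset (ablation) configuration only the present branches
are instantiated and the fusion softmax runs over the present modalities.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from . import image_encoder as ie
from . import sequence_encoder as se
from . import text_encoder as te
from .config import ModelConfig, copy_config
from .synthetic import MultimodalSample

__all__ = ["ModalityProjection", "FusionState", "ClassifierParams",
           "ModelParameters", "project_modalities", "fuse_attention",
           "fusion_weights", "weighted_fuse", "classify", "cross_entropy",
           "predict", "init_model", "forward_batch", "batch_loss",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModalityProjection:
    """Square encoding weights per modality; absent modalities are None."""

    w_image: np.ndarray | None
    w_series: np.ndarray | None
    w_text: np.ndarray | None
    nonlinearity: str = "tanh"

    def get(self, name: str):
        return {"image": self.w_image, "series": self.w_series,
                "text": self.w_text}[name]


@dataclass
class FusionState:
    """Intermediates of one fused forward pass (diagnostic output)."""

    alphas: dict          # modality -> [d_model]
    betas: np.ndarray     # [k, d_model] fused tokens
    scores: np.ndarray    # [k]
    weights: np.ndarray   # [k] simplex
    fused: np.ndarray     # [d_model]


@dataclass
class ClassifierParams:
    weight: np.ndarray    # [K, d_model]
    bias: np.ndarray      # [K]


@dataclass
class ModelParameters:
    """All trainable arrays plus the configuration that shaped them."""

    config: ModelConfig
    image: ie.ImageEncoderParams | None
    series: se.SeriesEncoderParams | None
    text: te.TextEncoderParams | None
    projection: ModalityProjection
    fusion_attn: te.AttentionParams
    score_vector: np.ndarray   # [d_model]
    classifier: ClassifierParams

    def named_parameters(self):
        """Stable-ordered (name, array) pairs over every trainable array."""
        out = []
        if self.image is not None:
            for i, blk in enumerate(self.image.blocks):
                out.append((f"image.conv{i}.weights", blk.weights))
                out.append((f"image.conv{i}.bias", blk.bias))
            out.append(("image.out.weight", self.image.w_out))
            out.append(("image.out.bias", self.image.b_out))
        if self.series is not None:
            for tag, p in (("fwd", self.series.fwd), ("bwd", self.series.bwd)):
                for g in ("i", "f", "o", "c"):
                    out.append((f"series.{tag}.w_{g}", getattr(p, f"w_{g}")))
                    out.append((f"series.{tag}.b_{g}", getattr(p, f"b_{g}")))
            out.append(("series.out.weight", self.series.w_out))
            out.append(("series.out.bias", self.series.b_out))
        if self.text is not None:
            out.append(("text.embedding", self.text.embedding))
            for g in ("w_q", "w_k", "w_v", "w_o"):
                out.append((f"text.attn.{g}", getattr(self.text.attn, g)))
        for name in self.config.modalities:
            out.append((f"projection.w_{name}", self.projection.get(name)))
        for g in ("w_q", "w_k", "w_v", "w_o"):
            out.append((f"fusion.attn.{g}", getattr(self.fusion_attn, g)))
        out.append(("fusion.score_vector", self.score_vector))
        out.append(("classifier.weight", self.classifier.weight))
        out.append(("classifier.bias", self.classifier.bias))
        return out

    def n_parameters(self) -> int:
        return sum(int(np.size(a.data if isinstance(a, ag.Tensor) else a))
                   for _, a in self.named_parameters())


# ------------------------------------------------------------ operations

def _nonlin(x, tag: str):
    if tag == "tanh":
        return ag.tanh(x)
    if tag == "identity":
        return x if isinstance(x, ag.Tensor) else ag.as_tensor(x)
    raise ValueError(f"unknown projection nonlinearity {tag!r}")


def project_modalities(H_i, H_n, H_t, proj: ModalityProjection):
    """(alpha_i, alpha_n, alpha_t) = E(W_m H_m) for each modality."""
    outs = []
    for H, W in ((H_i, proj.w_image), (H_n, proj.w_series), (H_t, proj.w_text)):
        H = np.asarray(H, dtype=np.float64)
        W = np.asarray(W, dtype=np.float64)
        if H.shape[0] != W.shape[1]:
            raise ValueError(
                f"feature length {H.shape[0]} does not match projection "
                f"width {W.shape[1]}"
            )
        outs.append(_nonlin(ag.Tensor(W @ H), proj.nonlinearity).data)
    return tuple(outs)


def fuse_attention(alpha_i, alpha_n, alpha_t, attn: te.AttentionParams,
                   score_scale: str = "sqrt_dk") -> np.ndarray:
    """Cross-modality self-attention over the 3-token [alpha] sequence."""
    X = np.stack([np.asarray(a, dtype=np.float64)
                  for a in (alpha_i, alpha_n, alpha_t)])
    return te.multi_head(X, attn, score_scale)


def fusion_weights(scores) -> np.ndarray:
    """Softmax of the per-modality scores onto the simplex."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("fusion scores must be finite")
    z = scores - scores.max()
    ez = np.exp(z)
    return ez / ez.sum()


def weighted_fuse(betas, w) -> np.ndarray:
    """M = sum_m w_m beta_m with w on the simplex."""
    betas = np.asarray(betas, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1 or betas.shape[0] != w.shape[0]:
        raise ValueError("one weight per fused token is required")
    if np.any(w < -1e-9) or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("fusion weights must be non-negative and sum to 1")
    return w @ betas


def classify(M, cls: ClassifierParams) -> np.ndarray:
    """softmax(lambda M + b): class probabilities on the K-simplex."""
    M = np.asarray(M, dtype=np.float64)
    W = np.asarray(cls.weight, dtype=np.float64)
    if M.shape[0] != W.shape[1]:
        raise ValueError(
            f"fused vector length {M.shape[0]} != classifier width {W.shape[1]}"
        )
    logits = W @ M + np.asarray(cls.bias, dtype=np.float64)
    z = logits - logits.max()
    ez = np.exp(z)
    return ez / ez.sum()


def cross_entropy(y_hat, y_onehot) -> float:
    """-sum_k Y_k log(Yhat_k), probabilities clamped at 1e-12 before log."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y_onehot, dtype=np.float64)
    if y.shape != y_hat.shape or not (
        np.all((y == 0) | (y == 1)) and y.sum() == 1
    ):
        raise ValueError("label must be one-hot with the classifier's width")
    return float(-(y * np.log(np.maximum(y_hat, 1e-12))).sum())


# ------------------------------------------------------------ full model

def init_model(cfg: ModelConfig, seed: int) -> ModelParameters:
    """Seeded uniform +-1/sqrt(fan_in) initialization of every branch."""
    rng = np.random.default_rng(seed)
    mods = cfg.modalities
    image = ie.init_image_encoder(cfg, rng) if "image" in mods else None
    series = se.init_series_encoder(cfg, rng) if "series" in mods else None
    text = te.init_text_encoder(cfg, rng) if "text" in mods else None
    d = cfg.d_model
    bound = 1.0 / np.sqrt(d)
    u = lambda *shape: rng.uniform(-bound, bound, size=shape)
    proj = ModalityProjection(
        w_image=u(d, d) if "image" in mods else None,
        w_series=u(d, d) if "series" in mods else None,
        w_text=u(d, d) if "text" in mods else None,
        nonlinearity=cfg.fusion.projection_nonlinearity,
    )
    return ModelParameters(
        config=cfg,
        image=image,
        series=series,
        text=text,
        projection=proj,
        fusion_attn=te.init_attention(d, cfg.fusion.heads, rng),
        score_vector=u(d),
        classifier=ClassifierParams(weight=u(cfg.n_classes, d),
                                    bias=u(cfg.n_classes)),
    )


def forward_batch(params: ModelParameters, batch: list[MultimodalSample]):
    """Differentiable forward pass: list of samples -> probability Tensor [B, K]."""
    cfg = params.config
    mods = cfg.modalities
    B = len(batch)
    features = {}
    if "image" in mods:
        imgs = np.stack([np.atleast_3d(s.image).transpose(2, 0, 1)
                         if s.image.ndim == 3 else s.image[None]
                         for s in batch])
        features["image"] = ie._encode_image_graph(ag.Tensor(imgs), params.image)
    if "series" in mods:
        X = np.stack([s.series for s in batch])
        features["series"] = se._encode_series_graph(
            ag.Tensor(X), params.series, cfg.sequence_encoder.pooling
        )
    if "text" in mods:
        features["text"] = te._encode_text_graph(
            [s.tokens for s in batch], params.text, cfg
        )
    # modality projections: alpha_m = E(H_m W_m^T), batched [B, d]
    alphas = []
    for name in mods:
        W = ag.as_tensor(params.projection.get(name))
        a = ag.matmul(features[name], ag.transpose(W, (1, 0)))
        alphas.append(_nonlin(a, params.projection.nonlinearity))
    tokens = ag.stack(alphas, axis=1)              # [B, k, d]
    betas = te._multi_head_graph(tokens, params.fusion_attn,
                                 cfg.text_encoder.score_scale)
    if cfg.fusion.fuse_input == "alpha":
        betas = tokens
    s = ag.reshape(ag.as_tensor(params.score_vector), (cfg.d_model, 1))
    scores = ag.matmul(betas, s)                   # [B, k, 1]
    w = ag.softmax(ag.reshape(scores, (B, len(mods))), axis=-1)
    fused = ag.tsum(ag.mul(betas, ag.reshape(w, (B, len(mods), 1))), axis=1)
    Wc = ag.as_tensor(params.classifier.weight)
    logits = ag.add(ag.matmul(fused, ag.transpose(Wc, (1, 0))),
                    params.classifier.bias)
    return ag.softmax(logits, axis=-1), logits


def batch_loss(params: ModelParameters, batch: list[MultimodalSample]):
    """Mean cross-entropy over a batch, as a differentiable scalar Tensor."""
    _, logits = forward_batch(params, batch)
    y = np.asarray([s.label for s in batch])
    # log-softmax route: stable even for extreme logits
    shift = logits.data.max(axis=-1, keepdims=True)
    z = ag.sub(logits, shift)
    lse = ag.log(ag.tsum(ag.exp(z), axis=-1, keepdims=True))
    logp = ag.sub(z, lse)
    picked = ag.getitem(logp, (np.arange(len(batch)), y))
    return ag.neg(ag.tmean(picked))


def predict(sample: MultimodalSample, params: ModelParameters):
    """(probability vector, predicted label); ties break to the lower class."""
    cfg = params.config
    for name in cfg.modalities:
        attr = {"image": "image", "series": "series", "text": "tokens"}[name]
        if getattr(sample, attr) is None:
            raise ValueError(f"sample {sample.sample_id} missing modality {name}")
    probs = forward_batch(params, [sample])[0].data[0]
    return probs, int(np.argmax(probs))


def fusion_state(sample: MultimodalSample, params: ModelParameters) -> FusionState:
    """Expose the fusion intermediates for one sample (diagnostics)."""
    cfg = params.config
    probs, logits = forward_batch(params, [sample])
    # recompute pieces on the numpy path
    feats = {}
    if params.image is not None and "image" in cfg.modalities:
        feats["image"] = ie.encode_image(sample.image, params.image)
    if params.series is not None and "series" in cfg.modalities:
        feats["series"] = se.encode_series(
            sample.series, params.series, cfg.sequence_encoder.pooling
        )
    if params.text is not None and "text" in cfg.modalities:
        feats["text"] = te.encode_text(sample.tokens, params.text, cfg)
    alphas = {}
    for name in cfg.modalities:
        W = _np(params.projection.get(name))
        a = W @ feats[name]
        alphas[name] = np.tanh(a) if params.projection.nonlinearity == "tanh" else a
    X = np.stack([alphas[m] for m in cfg.modalities])
    betas = te.multi_head(X, params.fusion_attn, cfg.text_encoder.score_scale)
    if cfg.fusion.fuse_input == "alpha":
        betas = X
    scores = betas @ _np(params.score_vector)
    w = fusion_weights(scores)
    return FusionState(alphas=alphas, betas=betas, scores=scores,
                       weights=w, fused=w @ betas)


def _np(a):
    return a.data if isinstance(a, ag.Tensor) else np.asarray(a)


# ------------------------------------------------------------ train plumbing

_NON_TRAINABLE_FIELDS = {"config", "norm_mean", "norm_std", "nonlinearity"}


def _map_arrays(obj, fn):
    """Recursively apply ``fn`` to every trainable array field, in place."""
    import dataclasses as dc

    if obj is None or isinstance(obj, (str, int, float, ModelConfig)):
        return obj
    if isinstance(obj, (np.ndarray, ag.Tensor)):
        return fn(obj)
    if isinstance(obj, list):
        return [_map_arrays(o, fn) for o in obj]
    if dc.is_dataclass(obj):
        for f in dc.fields(obj):
            if f.name in _NON_TRAINABLE_FIELDS:
                continue
            setattr(obj, f.name, _map_arrays(getattr(obj, f.name), fn))
        return obj
    return obj


def tensorize(params: ModelParameters):
    """Replace trainable arrays with autograd leaves (in place); return them
    in the stable ``named_parameters`` order."""
    _map_arrays(
        params,
        lambda a: a if isinstance(a, ag.Tensor) else ag.Tensor(a, requires_grad=True),
    )
    return [arr for _, arr in params.named_parameters()]


def detensorize(params: ModelParameters) -> ModelParameters:
    """Unwrap autograd leaves back to plain numpy arrays (in place)."""
    _map_arrays(params, lambda a: a.data if isinstance(a, ag.Tensor) else a)
    return params


# ------------------------------------------------------------ checkpoints

def save_checkpoint(params: ModelParameters, path) -> None:
    """Single-archive checkpoint: named float arrays + JSON config."""
    path = Path(path)
    arrays = {name: _np(arr) for name, arr in params.named_parameters()}
    if params.series is not None:
        arrays["series.norm_mean"] = _np(params.series.norm_mean)
        arrays["series.norm_std"] = _np(params.series.norm_std)
    buf = io.BytesIO()
    np.savez_compressed(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr("config.json",
                    json.dumps(params.config.to_dict(), default=list))


def load_checkpoint(path) -> ModelParameters:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with zipfile.ZipFile(path) as zf:
        cfg = ModelConfig.from_dict(json.loads(zf.read("config.json")))
        with zf.open("arrays.npz") as fh:
            arrays = dict(np.load(io.BytesIO(fh.read())))
    params = init_model(cfg, seed=0)
    for name, arr in params.named_parameters():
        tgt = _np(arr)
        tgt[...] = arrays[name]
    if params.series is not None:
        params.series.norm_mean[...] = arrays["series.norm_mean"]
        params.series.norm_std[...] = arrays["series.norm_std"]
    return params
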