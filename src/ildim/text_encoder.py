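"""Self-attention text encoder.

Token ids are embedded, sinusoidal positional encodings are added, and one
multi-head self-attention block (with a residual connection, no layer
norm) is applied.  Scaled dot-product attention:

    E[i, j] = (Q_i . K_j) / sqrt(d_k)       attention scores
    A = row-softmax(E)                      attention weights
    SA_i = sum_j A[i, j] V_j                per-head output

Per-head outputs are concatenated along the feature axis and mixed by
W_O; the mean over token positions yields the text feature H_t.  The
score denominator is sqrt(d_k) by default; ``score_scale: dk`` selects a
plain d_k denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .config import ModelConfig

__all__ = ["AttentionParams", "TextEncoderParams", "embed_and_position",
           "positional_encoding", "attention_scores", "attention_weights",
           "attention_output", "multi_head", "encode_text",
           "init_text_encoder", "init_attention"]


@dataclass
class AttentionParams:
    """Per-head projections w_q/w_k/w_v: [H, d_model, d_k]; w_o: [H*d_k, d_model]."""

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray


@dataclass
class TextEncoderParams:
    embedding: np.ndarray      # [vocab, d_model]
    attn: AttentionParams


def positional_encoding(n: int, d_model: int) -> np.ndarray:
    """Sinusoidal position code: sin on even dims, cos on odd dims."""
    pe = np.zeros((n, d_model))
    if n == 0:
        return pe
    pos = np.arange(n)[:, None]
    div = np.exp(np.arange(0, d_model, 2) * (-np.log(10000.0) / d_model))
    pe[:, 0::2] = np.sin(pos * div)
    pe[:, 1::2] = np.cos(pos * div[: pe[:, 1::2].shape[1]])
    return pe


def embed_and_position(tokens, params: TextEncoderParams,
                       use_positional: bool = True) -> np.ndarray:
    """Token ids -> [n, d_model] embedding rows plus positional code."""
    tokens = np.asarray(tokens, dtype=np.int64)
    emb = params.embedding.data if isinstance(params.embedding, ag.Tensor) \
        else np.asarray(params.embedding)
    vocab, d_model = emb.shape
    bad = np.flatnonzero((tokens < 0) | (tokens >= vocab))
    if bad.size:
        raise ValueError(
            f"token id {tokens[bad[0]]} at position {bad[0]} outside "
            f"vocabulary of size {vocab}"
        )
    out = emb[tokens].astype(np.float64, copy=True)
    if use_positional:
        out += positional_encoding(len(tokens), d_model)
    return out


def attention_scores(Qm: np.ndarray, Km: np.ndarray,
                     score_scale: str = "sqrt_dk") -> np.ndarray:
    """E[i, j] = Q_i . K_j scaled by the key dimension."""
    Qm, Km = np.asarray(Qm, dtype=np.float64), np.asarray(Km, dtype=np.float64)
    if Qm.shape[-1] != Km.shape[-1]:
        raise ValueError(
            f"query dim {Qm.shape[-1]} != key dim {Km.shape[-1]}"
        )
    d_k = Qm.shape[-1]
    scale = np.sqrt(d_k) if score_scale == "sqrt_dk" else float(d_k)
    return Qm @ Km.T / scale


def attention_weights(E: np.ndarray) -> np.ndarray:
    """Row-wise softmax of the score matrix (max-subtracted)."""
    E = np.asarray(E, dtype=np.float64)
    if not np.all(np.isfinite(E)):
        raise ValueError("attention scores must be finite")
    z = E - E.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


def attention_output(A: np.ndarray, Vm: np.ndarray) -> np.ndarray:
    """SA_i = sum_j A[i, j] V_j; rows are convex combinations of value rows."""
    A, Vm = np.asarray(A, dtype=np.float64), np.asarray(Vm, dtype=np.float64)
    if A.shape[-1] != Vm.shape[0]:
        raise ValueError(
            f"weight matrix has {A.shape[-1]} columns but {Vm.shape[0]} "
            f"value rows"
        )
    return A @ Vm


def _scale_for(d_k: int, score_scale: str) -> float:
    return float(np.sqrt(d_k)) if score_scale == "sqrt_dk" else float(d_k)


def _multi_head_graph(X, attn: AttentionParams, score_scale: str = "sqrt_dk",
                      key_mask=None):
    """Batched MHSA: X [B, n, d_model] -> [B, n, d_model].

    ``key_mask`` [B, n] (1 = real token) adds -1e30 to scores of padded
    keys so they receive zero attention weight.
    """
    w_q, w_k, w_v = (ag.as_tensor(attn.w_q), ag.as_tensor(attn.w_k),
                     ag.as_tensor(attn.w_v))
    w_o = ag.as_tensor(attn.w_o)
    H, _, d_k = w_q.shape
    scale = _scale_for(d_k, score_scale)
    heads = []
    bias = None
    if key_mask is not None:
        bias = np.where(key_mask[:, None, :] > 0, 0.0, -1e30)
    for h in range(H):
        Q = ag.matmul(X, w_q[h])
        K = ag.matmul(X, w_k[h])
        V = ag.matmul(X, w_v[h])
        E = ag.mul(ag.matmul(Q, ag.transpose(K, (0, 2, 1))), 1.0 / scale)
        if bias is not None:
            E = ag.add(E, bias)
        A = ag.softmax(E, axis=-1)
        heads.append(ag.matmul(A, V))
    return ag.matmul(ag.concat(heads, axis=-1), w_o)


def multi_head(Xp: np.ndarray, attn: AttentionParams,
               score_scale: str = "sqrt_dk") -> np.ndarray:
    """Multi-head self-attention over one [n, d_model] sequence."""
    Xp = np.asarray(Xp, dtype=np.float64)
    H, d_model, d_k = np.shape(attn.w_q)
    if H * d_k != d_model:
        raise ValueError(
            f"head count {H} must divide d_model {d_model} "
            f"(got per-head width {d_k})"
        )
    if Xp.shape[-1] != d_model:
        raise ValueError(
            f"input width {Xp.shape[-1]} != projection d_model {d_model}"
        )
    return _multi_head_graph(ag.Tensor(Xp[None]), attn, score_scale).data[0]


def _encode_text_graph(token_batch, p: TextEncoderParams, cfg: ModelConfig):
    """Differentiable forward for a list of token sequences -> [B, d_model].

    Sequences are padded to a common length; padded keys are masked out of
    the attention softmax and padded positions are excluded from the mean
    pool.  All-empty sequences encode to the zero vector.
    """
    tc = cfg.text_encoder
    B = len(token_batch)
    n = max((len(t) for t in token_batch), default=0)
    if n == 0:
        return ag.Tensor(np.zeros((B, cfg.d_model)))
    ids = np.zeros((B, n), dtype=np.int64)
    mask = np.zeros((B, n))
    for b, toks in enumerate(token_batch):
        ids[b, : len(toks)] = toks
        mask[b, : len(toks)] = 1.0
    emb = ag.as_tensor(p.embedding)
    X = ag.getitem(emb, ids)                       # [B, n, d_model]
    if tc.use_positional:
        X = ag.add(X, positional_encoding(n, cfg.d_model))
    X = ag.mul(X, mask[:, :, None])                # zero out padding rows
    attn_out = _multi_head_graph(X, p.attn, tc.score_scale, key_mask=mask)
    X = ag.add(X, attn_out)                        # residual connection
    X = ag.mul(X, mask[:, :, None])
    counts = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
    return ag.mul(ag.tsum(X, axis=1), 1.0 / counts)


def encode_text(tokens, params: TextEncoderParams, cfg: ModelConfig
                ) -> np.ndarray:
    """Token sequence -> H_t, a length-d_model feature vector."""
    tokens = np.asarray(tokens, dtype=np.int64)
    emb = params.embedding.data if isinstance(params.embedding, ag.Tensor) \
        else np.asarray(params.embedding)
    if tokens.size and (tokens.min() < 0 or tokens.max() >= emb.shape[0]):
        embed_and_position(tokens, params)  # raises with the position named
    return _encode_text_graph([tokens], params, cfg).data[0]


def init_attention(d_model: int, heads: int, rng: np.random.Generator
                   ) -> AttentionParams:
    if d_model % heads != 0:
        raise ValueError(f"head count {heads} must divide d_model {d_model}")
    d_k = d_model // heads
    bound = 1.0 / np.sqrt(d_model)
    u = lambda *shape: rng.uniform(-bound, bound, size=shape)
    return AttentionParams(
        w_q=u(heads, d_model, d_k), w_k=u(heads, d_model, d_k),
        w_v=u(heads, d_model, d_k), w_o=u(heads * d_k, d_model),
    )


def init_text_encoder(cfg: ModelConfig, rng: np.random.Generator
                      ) -> TextEncoderParams:
    tc = cfg.text_encoder
    bound = 1.0 / np.sqrt(cfg.d_model)
    return TextEncoderParams(
        embedding=rng.uniform(-bound, bound,
                              size=(tc.vocab_size, cfg.d_model)),
        attn=init_attention(cfg.d_model, tc.heads, rng),
    )
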