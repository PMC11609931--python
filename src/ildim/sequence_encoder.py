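"""Bidirectional LSTM encoder for the physiological time series.

Gate equations, per step, with [h, x] the concatenated previous hidden
state and current input:

    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        input gate
    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        forget gate
    c~_t = tanh(W_c [h_{t-1}, x_t] + b_c)          candidate cell state
    c_t = f_t * c_{t-1} + i_t * c~_t
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        output gate
    h_t = o_t * tanh(c_t)

The backward direction runs the same recursion over the reversed sequence
(zero-initialized state); the two directions' hidden states are merged by
elementwise SUM at each step, so both share one hidden size.  The encoder
pools the merged sequence over time (mean by default, last step optional)
and maps linearly to d_model, producing H_n.  Inputs are z-scored per
channel with statistics taken from the training split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .config import ModelConfig

__all__ = ["LSTMParams", "LSTMState", "SeriesEncoderParams", "lstm_step",
           "bilstm", "encode_series", "init_series_encoder"]


@dataclass
class LSTMParams:
    """Per-direction gate weights [hidden, hidden+input] and biases [hidden]."""

    w_i: np.ndarray
    w_f: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray


@dataclass
class LSTMState:
    h: np.ndarray
    c: np.ndarray


@dataclass
class SeriesEncoderParams:
    fwd: LSTMParams
    bwd: LSTMParams
    w_out: np.ndarray        # [d_model, hidden]
    b_out: np.ndarray        # [d_model]
    norm_mean: np.ndarray    # [D], not trainable
    norm_std: np.ndarray     # [D], not trainable


def lstm_step(x_t: np.ndarray, prev: LSTMState, p: LSTMParams) -> LSTMState:
    """One LSTM step on a single input vector."""
    x_t = np.asarray(x_t, dtype=np.float64)
    h, c = np.asarray(prev.h, dtype=np.float64), np.asarray(prev.c, dtype=np.float64)
    hidden = h.shape[0]
    if np.shape(p.w_i)[1] != hidden + x_t.shape[0]:
        raise ValueError(
            f"gate matrix expects input width {np.shape(p.w_i)[1]}, "
            f"got hidden {hidden} + input {x_t.shape[0]}"
        )
    hx = np.concatenate([h, x_t])

    def gate(w, b, fn):
        return fn(np.asarray(w) @ hx + np.asarray(b))

    sig = lambda z: np.where(z >= 0, 1 / (1 + np.exp(-np.abs(z))),
                             np.exp(-np.abs(z)) / (1 + np.exp(-np.abs(z))))
    i = gate(p.w_i, p.b_i, sig)
    f = gate(p.w_f, p.b_f, sig)
    o = gate(p.w_o, p.b_o, sig)
    c_hat = gate(p.w_c, p.b_c, np.tanh)
    c_new = f * c + i * c_hat
    h_new = o * np.tanh(c_new)
    return LSTMState(h=h_new, c=c_new)


def _gate_cat(p: LSTMParams):
    """Stack the four gate matrices/biases once per forward pass (order i,f,o,c)."""
    w = ag.concat([ag.as_tensor(p.w_i), ag.as_tensor(p.w_f),
                   ag.as_tensor(p.w_o), ag.as_tensor(p.w_c)], axis=0)
    b = ag.concat([ag.as_tensor(p.b_i), ag.as_tensor(p.b_f),
                   ag.as_tensor(p.b_o), ag.as_tensor(p.b_c)], axis=0)
    return w, b


def _direction_pass(x, p: LSTMParams, hidden: int):
    """Batched unidirectional pass: x [B,T,D] -> hidden sequence [B,T,hidden]."""
    B, T, _ = x.shape
    w, b = _gate_cat(p)
    wt = ag.transpose(w, (1, 0))
    h = ag.Tensor(np.zeros((B, hidden)))
    c = ag.Tensor(np.zeros((B, hidden)))
    outs = []
    for t in range(T):
        hx = ag.concat([h, x[:, t, :]], axis=1)
        z = ag.add(ag.matmul(hx, wt), b)
        i = ag.sigmoid(z[:, :hidden])
        f = ag.sigmoid(z[:, hidden:2 * hidden])
        o = ag.sigmoid(z[:, 2 * hidden:3 * hidden])
        c_hat = ag.tanh(z[:, 3 * hidden:])
        c = ag.add(ag.mul(f, c), ag.mul(i, c_hat))
        h = ag.mul(o, ag.tanh(c))
        outs.append(h)
    return ag.stack(outs, axis=1)


def _bilstm_graph(x, p_fwd: LSTMParams, p_bwd: LSTMParams):
    """x: Tensor [B,T,D] -> merged hidden sequence Tensor [B,T,hidden]."""
    hidden = np.shape(p_fwd.w_i)[0] if not isinstance(p_fwd.w_i, ag.Tensor) \
        else p_fwd.w_i.shape[0]
    fwd = _direction_pass(x, p_fwd, hidden)
    x_rev = ag.getitem(x, (slice(None), slice(None, None, -1), slice(None)))
    bwd = _direction_pass(x_rev, p_bwd, hidden)
    bwd = ag.getitem(bwd, (slice(None), slice(None, None, -1), slice(None)))
    return ag.add(fwd, bwd)


def bilstm(X: np.ndarray, p_fwd: LSTMParams, p_bwd: LSTMParams) -> np.ndarray:
    """Merged (summed) bidirectional hidden sequence for a T x D series."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("series must be a non-empty T x D matrix")
    return _bilstm_graph(ag.Tensor(X[None]), p_fwd, p_bwd).data[0]


def _encode_series_graph(x, p: SeriesEncoderParams, pooling: str):
    """Differentiable batched forward: x [B,T,D] -> [B, d_model]."""
    mean = np.asarray(p.norm_mean, dtype=np.float64)
    std = np.asarray(p.norm_std, dtype=np.float64)
    xn = ag.mul(ag.sub(x, mean), 1.0 / np.where(std > 0, std, 1.0))
    merged = _bilstm_graph(xn, p.fwd, p.bwd)
    if pooling == "last":
        pooled = merged[:, -1, :]
    else:
        pooled = ag.tmean(merged, axis=1)
    wt = ag.transpose(ag.as_tensor(p.w_out), (1, 0))
    return ag.add(ag.matmul(pooled, wt), p.b_out)


def encode_series(X: np.ndarray, params: SeriesEncoderParams,
                  pooling: str = "mean") -> np.ndarray:
    """Series -> H_n, a length-d_model feature vector."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("series must be a T x D matrix")
    if X.shape[1] != np.shape(params.norm_mean)[0]:
        raise ValueError(
            f"series has {X.shape[1]} channels, encoder expects "
            f"{np.shape(params.norm_mean)[0]}"
        )
    return _encode_series_graph(ag.Tensor(X[None]), params, pooling).data[0]


def _init_lstm(hidden: int, d: int, rng: np.random.Generator) -> LSTMParams:
    bound = 1.0 / np.sqrt(hidden + d)
    u = lambda *shape: rng.uniform(-bound, bound, size=shape)
    return LSTMParams(
        w_i=u(hidden, hidden + d), w_f=u(hidden, hidden + d),
        w_o=u(hidden, hidden + d), w_c=u(hidden, hidden + d),
        b_i=u(hidden), b_f=u(hidden), b_o=u(hidden), b_c=u(hidden),
    )


def init_series_encoder(cfg: ModelConfig, rng: np.random.Generator,
                        norm_mean=None, norm_std=None) -> SeriesEncoderParams:
    sc = cfg.sequence_encoder
    hidden, d = sc.hidden_size, sc.channels
    bound = 1.0 / np.sqrt(hidden)
    return SeriesEncoderParams(
        fwd=_init_lstm(hidden, d, rng),
        bwd=_init_lstm(hidden, d, rng),
        w_out=rng.uniform(-bound, bound, size=(cfg.d_model, hidden)),
        b_out=rng.uniform(-bound, bound, size=cfg.d_model),
        norm_mean=np.zeros(d) if norm_mean is None else np.asarray(norm_mean),
        norm_std=np.ones(d) if norm_std is None else np.asarray(norm_std),
    )
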