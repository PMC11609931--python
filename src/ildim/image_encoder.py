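"""Convolutional image encoder.

A small stack of [valid cross-correlation -> ReLU -> 2x2 max pool] blocks,
global average pooling over the remaining spatial grid, and a linear map to
the shared feature width ``d_model`` producing the image feature H_i.

No padding, stride 1: a kernel of height M and width N maps an H x W input
to (H - M + 1) x (W - N + 1); pooling halves (floor) each spatial dim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .config import ModelConfig

__all__ = ["ConvKernel", "ImageEncoderParams", "conv2d", "relu", "maxpool2",
           "encode_image", "init_image_encoder"]


@dataclass
class ConvKernel:
    """weights: [out_channels, in_channels, M, N]; bias: [out_channels]."""

    weights: np.ndarray
    bias: np.ndarray


@dataclass
class ImageEncoderParams:
    blocks: list          # list[ConvKernel]
    w_out: np.ndarray     # [d_model, last_channels]
    b_out: np.ndarray     # [d_model]


def _as_bchw(image: np.ndarray):
    """Accept [H,W], [C,H,W] or [B,C,H,W]; return 4-D plus the original ndim."""
    image = np.asarray(image, dtype=np.float64)
    nd = image.ndim
    if nd == 2:
        image = image[None, None]
    elif nd == 3:
        image = image[None]
    elif nd != 4:
        raise ValueError(f"expected 2-4 dims, got {nd}")
    return image, nd


def conv2d(image: np.ndarray, kernel: ConvKernel) -> np.ndarray:
    """Valid cross-correlation of an image with a multi-channel kernel.

    Sums image[x+i, y+j] * K[i, j] over the kernel window and all input
    channels, plus a per-output-channel bias.
    """
    x, nd = _as_bchw(image)
    out = ag.conv2d(x, np.asarray(kernel.weights, dtype=np.float64),
                    np.asarray(kernel.bias, dtype=np.float64)).data
    if nd == 2 and out.shape[1] == 1:
        return out[0, 0]
    return out[0] if nd <= 3 else out


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def maxpool2(fm: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 max pooling, stride 2; odd trailing row/col dropped."""
    x, nd = _as_bchw(fm)
    out = ag.maxpool2(x).data
    if nd == 2:
        return out[0, 0]
    return out[0] if nd == 3 else out


def _encode_image_graph(x, p: ImageEncoderParams):
    """Differentiable batched forward: x [B,C,H,W] -> [B, d_model]."""
    h = x
    for k in p.blocks:
        h = ag.maxpool2(ag.relu(ag.conv2d(h, k.weights, k.bias)))
    pooled = ag.tmean(h, axis=(2, 3))               # global average pool
    return ag.add(ag.matmul(pooled, _t(p.w_out)), p.b_out)


def _t(w):
    w = ag.as_tensor(w)
    return ag.transpose(w, (1, 0))


def encode_image(image: np.ndarray, params: ImageEncoderParams) -> np.ndarray:
    """Image -> H_i, a length-d_model feature vector."""
    x, _ = _as_bchw(image)
    first = params.blocks[0].weights
    if x.shape[1] != np.shape(first)[1]:
        raise ValueError(
            f"image has {x.shape[1]} channels, encoder expects "
            f"{np.shape(first)[1]}"
        )
    return _encode_image_graph(ag.as_tensor(x), params).data[0]


def init_image_encoder(cfg: ModelConfig, rng: np.random.Generator
                       ) -> ImageEncoderParams:
    """Uniform +-1/sqrt(fan_in) initialization, seeded."""
    ic = cfg.image_encoder
    blocks = []
    c_in = ic.in_channels
    k = ic.kernel_size
    for c_out in ic.channels:
        bound = 1.0 / np.sqrt(c_in * k * k)
        blocks.append(
            ConvKernel(
                weights=rng.uniform(-bound, bound, size=(c_out, c_in, k, k)),
                bias=rng.uniform(-bound, bound, size=c_out),
            )
        )
        c_in = c_out
    bound = 1.0 / np.sqrt(c_in)
    return ImageEncoderParams(
        blocks=blocks,
        w_out=rng.uniform(-bound, bound, size=(cfg.d_model, c_in)),
        b_out=rng.uniform(-bound, bound, size=cfg.d_model),
    )
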