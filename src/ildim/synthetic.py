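"""Synthetic multimodal ILD cohort generator.

Real cohorts pair a chest-CT slice, a physiological time series and a
free-text history for each subject.  No such data ships with this package,
so this module plants a controllable class signal in each modality:

* image — a smooth low-frequency background plus pixel noise; cases
  additionally carry a high-frequency periodic "honeycomb" texture in a
  peripheral annulus, a stand-in for the subpleural reticulation seen in
  fibrotic ILD.  Texture amplitude scales linearly with ``strength``.
* series — channel 0 plays the role of PaO2 (mmHg): a stationary AR(1)
  process whose mean slides from the control value (95 mmHg) toward the
  case value (85 mmHg) as ``strength`` goes 0 -> 1.  Remaining channels are
  nuisance noise.
* text — token sequences from a background vocabulary mixed with symptom
  tokens; the probability that a symptom token comes from the class's own
  sub-vocabulary grows with ``strength`` (at strength 0 both classes share
  one distribution).

The default cohort shape is 40 cases / 20 controls.  Identical config and
seed give bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage

__all__ = [
    "GeneratorConfig", "MultimodalSample", "generate_image", "generate_series",
    "generate_text", "generate_dataset", "write_fixtures", "read_fixtures",
    "split_samples", "honeycomb_pattern", "peripheral_mask",
    "TEXTURE_AMPLITUDE", "SYMPTOM_RATE", "SYMPTOM_VOCAB_SIZE",
]

# image texture constants (exposed so tests can recompute expected offsets
# from the generator's own definition)
TEXTURE_AMPLITUDE = 0.25   # intensity added at the texture's crests, strength 1
TEXTURE_PERIOD = 4         # pixels per honeycomb cell
BACKGROUND_LEVEL = 0.4
BACKGROUND_FIELD_SD = 0.08
PIXEL_NOISE_SD = 0.04

# text constants: ids [0, 8) = case symptom tokens, [8, 16) = control symptom
# tokens, the rest of the vocabulary is background.
SYMPTOM_VOCAB_SIZE = 8
SYMPTOM_RATE = 0.4         # probability a token is a symptom token at all
TEXT_LENGTH_RANGE = (16, 33)

AR_COEFF = 0.8             # AR(1) autocorrelation of the PaO2 channel

# human-readable words for the JSONL ``raw_text`` field
_CASE_WORDS = ["dyspnea", "honeycombing", "crackles", "fibrosis",
               "exertional", "hypoxemia", "clubbing", "reticulation"]
_CONTROL_WORDS = ["wheeze", "congestion", "rhinitis", "sorethroat",
                  "fever", "sputum", "headache", "myalgia"]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_cases: int = 40
    n_controls: int = 20
    image_size: int = 64
    series_length: int = 32
    series_channels: int = 4
    vocab_size: int = 120
    signal_image: float = 1.0
    signal_series: float = 1.0
    signal_text: float = 1.0
    pao2_case_mean: float = 85.0
    pao2_control_mean: float = 95.0
    pao2_sd: float = 5.0
    rng_seed: int = 0
    train_fraction: float = 0.8
    split_seed: int | None = None  # defaults to rng_seed + 10007

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        for s in (self.signal_image, self.signal_series, self.signal_text):
            if not 0.0 <= s <= 1.0:
                raise ValueError("signal strengths must lie in [0, 1]")
        if self.pao2_sd <= 0:
            raise ValueError("pao2_sd must be positive")
        if not 0.0 <= self.train_fraction <= 1.0:
            raise ValueError("train_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class MultimodalSample:
    """One subject: image in [0,1], T x D series, token ids, binary label."""

    sample_id: str
    image: np.ndarray
    series: np.ndarray
    tokens: np.ndarray
    label: int


# ---------------------------------------------------------------- image

def honeycomb_pattern(size: int) -> np.ndarray:
    """Periodic cell pattern in [0, 1]; mean ~0.25 over whole periods."""
    x = np.arange(size)
    sx = np.sin(np.pi * x / TEXTURE_PERIOD) ** 2
    return np.outer(sx, sx)


def peripheral_mask(size: int) -> np.ndarray:
    """Annulus covering the lung periphery where fibrosis typically sits."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c) / (size / 2.0)
    return (r >= 0.55) & (r <= 0.95)


def generate_image(label: int, strength: float, size: int, seed: int) -> np.ndarray:
    """One grayscale image [size x size] in [0, 1], deterministic per seed."""
    if size < 16:
        raise ValueError(f"image size {size} below minimum of 16")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 8.0)
    field = (field - field.mean()) / (field.std() + 1e-12)
    img = BACKGROUND_LEVEL + BACKGROUND_FIELD_SD * field
    img = img + PIXEL_NOISE_SD * rng.standard_normal((size, size))
    if label == 1 and strength > 0:
        img = img + (TEXTURE_AMPLITUDE * strength) * honeycomb_pattern(
            size
        ) * peripheral_mask(size)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------- series

def generate_series(
    label: int, strength: float, T: int, D: int, cfg: GeneratorConfig, seed: int
) -> np.ndarray:
    """T x D series; channel 0 is the PaO2-like AR(1) channel."""
    if T < 2:
        raise ValueError("series length must be >= 2")
    if D < 1:
        raise ValueError("need at least one channel")
    if cfg.pao2_sd <= 0:
        raise ValueError("pao2_sd must be positive")
    rng = np.random.default_rng(seed)
    gap = cfg.pao2_control_mean - cfg.pao2_case_mean
    mu = cfg.pao2_control_mean - (strength * gap if label == 1 else 0.0)
    # stationary AR(1): innovations scaled so the marginal sd equals pao2_sd
    innov_sd = cfg.pao2_sd * np.sqrt(1.0 - AR_COEFF ** 2)
    x = np.empty(T)
    x[0] = mu + cfg.pao2_sd * rng.standard_normal()
    eps = innov_sd * rng.standard_normal(T - 1)
    for t in range(1, T):
        x[t] = mu + AR_COEFF * (x[t - 1] - mu) + eps[t - 1]
    series = np.empty((T, D))
    series[:, 0] = x
    if D > 1:
        series[:, 1:] = rng.standard_normal((T, D - 1))
    return series


# ---------------------------------------------------------------- text

def generate_text(
    label: int, strength: float, vocab_size: int, seed: int
) -> np.ndarray:
    """Token-id sequence with a strength-controlled symptom-vocabulary mix."""
    if vocab_size < 2 * SYMPTOM_VOCAB_SIZE + 4:
        raise ValueError(
            f"vocab_size {vocab_size} too small to hold two symptom "
            f"sub-vocabularies of {SYMPTOM_VOCAB_SIZE} plus background"
        )
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(*TEXT_LENGTH_RANGE))
    # probability that a symptom token comes from the case sub-vocabulary;
    # at strength 0 both classes share one distribution (and one rng path)
    p_case_vocab = 0.5 + strength / 2.0 if label == 1 else 0.5 - strength / 2.0
    tokens = np.empty(n, dtype=np.int64)
    for i in range(n):
        if rng.random() < SYMPTOM_RATE:
            lo = 0 if rng.random() < p_case_vocab else SYMPTOM_VOCAB_SIZE
            tokens[i] = lo + rng.integers(SYMPTOM_VOCAB_SIZE)
        else:
            tokens[i] = rng.integers(2 * SYMPTOM_VOCAB_SIZE, vocab_size)
    return tokens


def token_word(token_id: int) -> str:
    if token_id < SYMPTOM_VOCAB_SIZE:
        return _CASE_WORDS[token_id]
    if token_id < 2 * SYMPTOM_VOCAB_SIZE:
        return _CONTROL_WORDS[token_id - SYMPTOM_VOCAB_SIZE]
    return f"w{token_id}"


# ---------------------------------------------------------------- dataset

def generate_dataset(cfg: GeneratorConfig):
    """Full cohort: (samples, manifest DataFrame with stratified split tags)."""
    master = np.random.default_rng(cfg.rng_seed)
    samples = []
    labels = [1] * cfg.n_cases + [0] * cfg.n_controls
    for idx, label in enumerate(labels):
        seeds = master.integers(2 ** 31, size=3)
        strength = {
            "image": cfg.signal_image,
            "series": cfg.signal_series,
            "text": cfg.signal_text,
        }
        samples.append(
            MultimodalSample(
                sample_id=f"S{idx:04d}",
                image=generate_image(
                    label, strength["image"], cfg.image_size, int(seeds[0])
                ),
                series=generate_series(
                    label,
                    strength["series"],
                    cfg.series_length,
                    cfg.series_channels,
                    cfg,
                    int(seeds[1]),
                ),
                tokens=generate_text(
                    label, strength["text"], cfg.vocab_size, int(seeds[2])
                ),
                label=label,
            )
        )
    split_seed = cfg.split_seed if cfg.split_seed is not None else cfg.rng_seed + 10007
    splits = _stratified_split(labels, cfg.train_fraction, split_seed)
    manifest = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "image": [f"images/{s.sample_id}.png" for s in samples],
            "series": [f"series/{s.sample_id}.csv" for s in samples],
            "text": [s.sample_id for s in samples],
            "label": [s.label for s in samples],
            "split": splits,
        }
    )
    return samples, manifest


def _stratified_split(labels, train_fraction: float, seed: int):
    """Per-label shuffled assignment preserving the label ratio within +-1."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    split = np.empty(len(labels), dtype=object)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"
    return list(split)


def split_samples(samples, manifest):
    """Return (train_samples, test_samples) per the manifest's split tags."""
    by_id = {s.sample_id: s for s in samples}
    train = [by_id[r.sample_id] for r in manifest.itertuples() if r.split == "train"]
    test = [by_id[r.sample_id] for r in manifest.itertuples() if r.split == "test"]
    return train, test


# ---------------------------------------------------------------- fixtures

def write_fixtures(samples, manifest, directory) -> Path:
    """Write PNG/CSV/JSONL fixtures plus manifest.csv; returns the directory."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    (directory / "series").mkdir(parents=True, exist_ok=True)
    channel_names = None
    with open(directory / "text.jsonl", "w") as jf:
        for s in samples:
            img8 = np.round(np.clip(s.image, 0, 1) * 255).astype(np.uint8)
            Image.fromarray(img8, mode="L").save(
                directory / "images" / f"{s.sample_id}.png"
            )
            if channel_names is None:
                channel_names = ["pao2"] + [
                    f"ch{i}" for i in range(1, s.series.shape[1])
                ]
            pd.DataFrame(s.series, columns=channel_names).to_csv(
                directory / "series" / f"{s.sample_id}.csv",
                index=False,
                float_format="%.6f",
            )
            jf.write(
                json.dumps(
                    {
                        "id": s.sample_id,
                        "tokens": [int(t) for t in s.tokens],
                        "raw_text": " ".join(token_word(int(t)) for t in s.tokens),
                    }
                )
                + "\n"
            )
    manifest.to_csv(directory / "manifest.csv", index=False)
    return directory


def read_fixtures(directory):
    """Inverse of :func:`write_fixtures`; raises on files the manifest names
    but that are absent."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    if manifest.empty:
        return [], manifest
    texts = {}
    text_path = directory / "text.jsonl"
    if text_path.exists():
        with open(text_path) as fh:
            for line in fh:
                rec = json.loads(line)
                texts[rec["id"]] = np.asarray(rec["tokens"], dtype=np.int64)
    samples = []
    for row in manifest.itertuples():
        img_path = directory / row.image
        if not img_path.exists():
            raise FileNotFoundError(f"manifest references missing image {img_path}")
        series_path = directory / row.series
        if not series_path.exists():
            raise FileNotFoundError(
                f"manifest references missing series {series_path}"
            )
        if row.text not in texts:
            raise FileNotFoundError(
                f"manifest references missing text record {row.text!r} "
                f"in {text_path}"
            )
        image = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
        series = pd.read_csv(series_path).to_numpy(dtype=np.float64)
        samples.append(
            MultimodalSample(
                sample_id=row.sample_id,
                image=image,
                series=series,
                tokens=texts[row.text],
                label=int(row.label),
            )
        )
    return samples, manifest
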