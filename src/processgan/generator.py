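"""Conditional transformer-encoder generator.

Takes a random activity index sequence and a normalized case duration and
emits, for every position in parallel, a probability row over the activity
vocabulary and a timestamp differential in [0, 1]. Discrete activity samples
cross the non-differentiable argmax through a straight-through Gumbel-softmax
bridge.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor, cat
from ._nn import (Dropout, Embedding, Linear, Module, TransformerEncoder,
                  sinusoidal_positions)
from .encoding import normalize_duration
from .event_log_io import ActivityVocabulary, EventLog

__all__ = [
    "GeneratorConfig", "GeneratorOutput", "Generator",
    "sample_random_input", "sample_conditional_duration",
    "gumbel_straight_through",
]


@dataclasses.dataclass
class GeneratorConfig:
    vocab_size: int                  # pad included
    max_length: int
    embedding_size: int = 8
    hidden_size: int = 64
    n_heads: int = 4
    n_layers: int = 3
    dropout: float = 0.1
    temperature: float = 1.0
    renormalize_differentials: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclasses.dataclass
class GeneratorOutput:
    activity_probs: Tensor    # (batch, max_length, vocab_size), simplex rows
    activity_logits: Tensor   # same shape, pre-softmax
    differentials: Tensor     # (batch, max_length) in [0, 1]
    duration_norm: np.ndarray  # (batch,) the conditional input echoed back


def sample_random_input(vocab: ActivityVocabulary, max_length: int,
                        rng: np.random.Generator, batch: int = 1) -> np.ndarray:
    """Uniform i.i.d. indices over the real (non-pad) labels, shape (batch, l)."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    return rng.integers(0, vocab.n_real, size=(batch, max_length))


def sample_conditional_duration(log: EventLog, rng: np.random.Generator,
                                batch: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Draw authentic case durations uniformly; returns (normalized, real)."""
    durations = log.durations()
    picks = rng.integers(0, len(durations), size=batch)
    real = durations[picks]
    norm = np.array([normalize_duration(t, log.duration_bounds) for t in real])
    return norm, real


class Generator(Module):
    """Embedding + duration conditioning + transformer encoder + two decoders."""

    def __init__(self, cfg: GeneratorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden_size
        self.embedding = Embedding(cfg.vocab_size, cfg.embedding_size, rng)
        # scalar duration is concatenated to every position's embedding, then
        # projected up to the encoder width
        self.input_proj = Linear(cfg.embedding_size + 1, h, rng)
        self.pos_table = sinusoidal_positions(cfg.max_length, h)
        self.drop = Dropout(cfg.dropout, rng)
        self.encoder = TransformerEncoder(h, cfg.n_heads, cfg.n_layers,
                                          cfg.dropout, rng)
        # activity decoder head: two-layer MLP to vocabulary logits
        self.act_fc1 = Linear(h, h, rng)
        self.act_fc2 = Linear(h, cfg.vocab_size, rng)
        # time decoder head: two-layer MLP to a scalar per position
        self.time_fc1 = Linear(h, h, rng)
        self.time_fc2 = Linear(h, 1, rng)

    def forward(self, z: np.ndarray, t_norm: np.ndarray) -> GeneratorOutput:
        """z: (batch, max_length) int indices; t_norm: (batch,) in [0, 1]."""
        z = np.atleast_2d(np.asarray(z, dtype=np.intp))
        t_norm = np.atleast_1d(np.asarray(t_norm, dtype=np.float64))
        b, l = z.shape
        if l != self.cfg.max_length:
            raise ValueError(f"expected length {self.cfg.max_length}, got {l}")
        if t_norm.shape != (b,):
            raise ValueError(f"duration batch {t_norm.shape} != {(b,)}")

        emb = self.embedding(z)                                  # (b, l, emb)
        dur = Tensor(np.broadcast_to(t_norm[:, None, None], (b, l, 1)).copy())
        x = self.input_proj(cat([emb, dur], axis=-1))            # (b, l, h)
        x = x + Tensor(self.pos_table)
        x = self.encoder(self.drop(x))

        logits = self.act_fc2(self.act_fc1(x).relu())            # (b, l, Nv)
        probs = logits.softmax(axis=-1)

        raw = self.time_fc2(self.time_fc1(x).relu())             # (b, l, 1)
        raw = raw.reshape(b, l).relu()
        # per-sequence min-max rescale into [0, 1]
        lo = raw.min(axis=-1, keepdims=True)
        hi = raw.max(axis=-1, keepdims=True)
        span = (hi - lo).clip_min(1e-12)
        diffs = (raw - lo) / span
        # force position 1 to zero: matches the authentic convention ta1 = 0
        mask = np.ones((1, l))
        mask[0, 0] = 0.0
        diffs = diffs * Tensor(mask)
        return GeneratorOutput(probs, logits, diffs, t_norm)


def gumbel_straight_through(logits: Tensor, temperature: float,
                            rng: np.random.Generator,
                            gumbel_noise: np.ndarray | None = None) -> Tensor:
    """One-hot forward value with the softmax relaxation's gradient.

    The forward value is onehot(argmax(logits + g)) with g ~ Gumbel(0, 1);
    the backward sensitivity is that of softmax((logits + g) / temperature).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if gumbel_noise is None:
        u = rng.random(logits.shape)
        gumbel_noise = -np.log(-np.log(np.clip(u, 1e-12, 1.0 - 1e-12)))
    perturbed = logits + Tensor(gumbel_noise)
    soft = (perturbed / temperature).softmax(axis=-1)
    hard = np.zeros_like(soft.data)
    idx = np.argmax(perturbed.data, axis=-1)
    np.put_along_axis(hard, idx[..., None], 1.0, axis=-1)
    # value = hard, gradient = d(soft)
    return soft + Tensor(hard - soft.data)
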