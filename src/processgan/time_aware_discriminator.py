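"""Time-aware multi-head self-attention discriminator.

Scores an encoded case as authentic vs synthetic from the interactions among
activity one-hots, per-position timestamp differentials, and the pairwise
time-interval matrix. Each attention layer learns, besides the activity
query/key/value maps, four scalar-to-vector linear maps (timestamp key/value,
interval key/value) whose outputs are added into the keys and values.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autograd import Tensor, cat
from ._nn import Dropout, LayerNorm, Linear, Module, ScalarLinear, TransformerEncoder

__all__ = [
    "DiscriminatorConfig", "TimeAwareAttentionLayer", "DiscriminatorBlock",
    "TimeAwareDiscriminator", "VanillaDiscriminator", "make_discriminator",
]


@dataclasses.dataclass
class DiscriminatorConfig:
    vocab_size: int                 # pad included
    max_length: int
    hidden_size: int = 8            # d
    n_heads: int = 2
    n_layers: int = 2
    dropout: float = 0.5
    time_aware: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")


class TimeAwareAttentionLayer(Module):
    """Single time-aware attention layer (all heads), input width ``in_dim``."""

    def __init__(self, in_dim: int, d: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.d = d
        self.n_heads = n_heads
        self.wq = Linear(in_dim, d, rng, bias=False)
        self.wk = Linear(in_dim, d, rng, bias=False)
        self.wv = Linear(in_dim, d, rng, bias=False)
        self.ts_key = ScalarLinear(d, rng)
        self.ts_value = ScalarLinear(d, rng)
        self.interval_key = ScalarLinear(d, rng)
        self.interval_value = ScalarLinear(d, rng)

    def project_time_features(self, diffs: Tensor, m: Tensor):
        """Scalar timestamps and intervals through their four linear maps.

        diffs: (batch, l); m: (batch, l, l). Returns (ts_k, ts_v) of shape
        (batch, l, d) and (m_k, m_v) of shape (batch, l, l, d).
        """
        return (self.ts_key(diffs), self.ts_value(diffs),
                self.interval_key(m), self.interval_value(m))

    def forward(self, x: Tensor, diffs: Tensor, m: Tensor) -> Tensor:
        b, l, _ = x.shape
        d, h = self.d, self.n_heads
        dh = d // h
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        ts_k, ts_v, m_k, m_v = self.project_time_features(diffs, m)

        # per-pair keys/values: k'_ij = k_j + Dt^k_ij + ts^k_j (likewise values)
        k_pair = k.expand_dims(1) + m_k + ts_k.expand_dims(1)   # (b, l, l, d)
        v_pair = v.expand_dims(1) + m_v + ts_v.expand_dims(1)
        heads = []
        for i in range(h):
            sl = slice(i * dh, (i + 1) * dh)
            q_h = q[:, :, sl]                                   # (b, l, dh)
            k_h = k_pair[:, :, :, sl]                           # (b, l, l, dh)
            v_h = v_pair[:, :, :, sl]
            # e_ij = q_i . k'_ij / sqrt(d) -- scaling uses the full width d
            e = (q_h.expand_dims(2) * k_h).sum(axis=-1) / np.sqrt(d)
            alpha = e.softmax(axis=-1)                          # (b, l, l)
            f = (alpha.expand_dims(-1) * v_h).sum(axis=2)       # (b, l, dh)
            heads.append(f)
        return cat(heads, axis=-1)


class DiscriminatorBlock(Module):
    """Post-attention block: FFN(ReLU(f)) + Dropout(FFN(LayerNorm(f)))."""

    def __init__(self, d: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.ffn_relu = Linear(d, d, rng)
        self.ffn_norm = Linear(d, d, rng)
        self.norm = LayerNorm(d)
        self.drop = Dropout(dropout, rng)

    def forward(self, f: Tensor) -> Tensor:
        return self.ffn_relu(f.relu()) + self.drop(self.ffn_norm(self.norm(f)))


class TimeAwareDiscriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.hidden_size
        self.layers = []
        self.blocks = []
        in_dim = cfg.vocab_size
        for _ in range(cfg.n_layers):
            self.layers.append(TimeAwareAttentionLayer(in_dim, d, cfg.n_heads, rng))
            self.blocks.append(DiscriminatorBlock(d, cfg.dropout, rng))
            in_dim = d
        self.head = Linear(d, 1, rng)

    def forward(self, onehot, diffs, m) -> Tensor:
        """onehot: (b, l, Nv); diffs: (b, l); m: (b, l, l) -> scores (b,) in (0,1)."""
        x = onehot if isinstance(onehot, Tensor) else Tensor(onehot)
        diffs = diffs if isinstance(diffs, Tensor) else Tensor(diffs)
        m = m if isinstance(m, Tensor) else Tensor(m)
        for attn, block in zip(self.layers, self.blocks):
            x = block(attn(x, diffs, m))
        pooled = x.mean(axis=1)                                 # (b, d)
        return self.head(pooled).reshape(-1).sigmoid()

    def zero_time_projections(self) -> None:
        """Null out all time maps; reduces to plain attention over activities."""
        for layer in self.layers:
            for mod in (layer.ts_key, layer.ts_value,
                        layer.interval_key, layer.interval_value):
                mod.weight.data[...] = 0.0
                mod.bias.data[...] = 0.0


class VanillaDiscriminator(Module):
    """Ablation: concatenated inputs into a plain transformer encoder."""

    def __init__(self, cfg: DiscriminatorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d = cfg.hidden_size
        in_dim = cfg.vocab_size + 1 + cfg.max_length
        self.input_proj = Linear(in_dim, d, rng)
        self.encoder = TransformerEncoder(d, cfg.n_heads, cfg.n_layers,
                                          cfg.dropout, rng)
        self.head = Linear(d, 1, rng)

    def forward(self, onehot, diffs, m) -> Tensor:
        x = onehot if isinstance(onehot, Tensor) else Tensor(onehot)
        diffs = diffs if isinstance(diffs, Tensor) else Tensor(diffs)
        m = m if isinstance(m, Tensor) else Tensor(m)
        x = cat([x, diffs.expand_dims(-1), m], axis=-1)
        x = self.encoder(self.input_proj(x))
        return self.head(x.mean(axis=1)).reshape(-1).sigmoid()


def make_discriminator(cfg: DiscriminatorConfig) -> Module:
    return TimeAwareDiscriminator(cfg) if cfg.time_aware else VanillaDiscriminator(cfg)
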