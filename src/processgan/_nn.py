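"""Neural-network building blocks (layers, transformer encoder, Adam).

Built on the package-local autograd in :mod:`processgan._autograd`. Weight
initialization is driven entirely by an explicit ``numpy.random.Generator``
so every model in the package is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, cat

__all__ = [
    "Parameter", "Module", "Linear", "LayerNorm", "Dropout", "Embedding",
    "MultiHeadSelfAttention", "TransformerEncoderLayer", "TransformerEncoder",
    "Adam", "sinusoidal_positions", "xavier",
]


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: parameter discovery, train/eval flag, state dict."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in obj.__dict__.values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for k, p in own.items():
            p.data = np.asarray(state[k], dtype=np.float64).reshape(p.data.shape)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, flag: bool) -> None:
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v._set_mode(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._set_mode(flag)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(xavier(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class ScalarLinear(Module):
    """Maps a scalar feature (last axis absent) to a d-vector: x*w + b."""

    def __init__(self, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(xavier(rng, 1, out_dim, shape=(out_dim,)))
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        # x: (...,) -> (..., out_dim)
        return x.expand_dims(-1) * self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(dim), (n_tokens, dim)))

    def forward(self, indices: np.ndarray) -> Tensor:
        return self.weight[np.asarray(indices, dtype=np.intp)]


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine position table of shape (length, dim)."""
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(dim)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    table = np.zeros((length, dim))
    table[:, 0::2] = np.sin(angle[:, 0::2])
    table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


def split_heads(x: Tensor, n_heads: int) -> Tensor:
    b, l, d = x.shape
    return x.reshape(b, l, n_heads, d // n_heads).swapaxes(1, 2)


def merge_heads(x: Tensor) -> Tensor:
    b, h, l, dh = x.shape
    return x.swapaxes(1, 2).reshape(b, l, h * dh)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        q = split_heads(self.wq(x), self.n_heads)
        k = split_heads(self.wk(x), self.n_heads)
        v = split_heads(self.wv(x), self.n_heads)
        dh = q.shape[-1]
        scores = (q @ k.swapaxes(-1, -2)) / np.sqrt(dh)
        attn = self.drop(scores.softmax(axis=-1))
        return self.wo(merge_heads(attn @ v))


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHA and position-wise FFN with residuals."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, dropout, rng)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x)))
        return self.norm2(x + self.drop(self.ff2(self.ff1(x).relu())))


class TransformerEncoder(Module):
    def __init__(self, dim: int, n_heads: int, n_layers: int, dropout: float,
                 rng: np.random.Generator, ff_dim: int | None = None):
        super().__init__()
        self.layers = [
            TransformerEncoderLayer(dim, n_heads, ff_dim or dim, dropout, rng)
            for _ in range(n_layers)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """First-order adaptive-moment optimizer."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
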