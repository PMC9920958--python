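"""Neural-network modules: linear/embedding/layer-norm primitives, dropout,
multi-head self-attention, and the transformer encoder stack.

Initialization follows the common transformer recipe: weights and
embeddings ~ N(0, 0.02^2), biases zero, layer-norm gain one. The encoder
uses post-layer-norm residual blocks with GELU feed-forward networks and
learned positional embeddings.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from skelseq.nn.autograd import (
    Tensor,
    embedding_lookup,
    layer_norm,
)

INIT_STD = 0.02


class RngRef:
    """Mutable holder for a shared numpy Generator (dropout, sampling)."""

    def __init__(self, seed: int | np.random.Generator = 0):
        self.reseed(seed)

    def reseed(self, seed: int | np.random.Generator) -> None:
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny module system: parameter discovery, train/eval, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{full}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)[:5]}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, INIT_STD, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, INIT_STD, size=(n_embeddings, dim)))

    def forward(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-12):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng_ref: RngRef):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p={p} outside [0, 1)")
        self.p = p
        self.rng_ref = rng_ref

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        u = self.rng_ref.rng.random(x.shape, dtype=np.float32)
        mask = (u < keep).astype(x.data.dtype)
        mask /= keep
        return x * Tensor(mask)


class MultiHeadSelfAttention(Module):
    def __init__(self, hidden: int, heads: int, dropout: float, rng: np.random.Generator, rng_ref: RngRef):
        super().__init__()
        if hidden % heads:
            raise ValueError(f"hidden ({hidden}) not divisible by heads ({heads})")
        self.heads = heads
        self.head_dim = hidden // heads
        self.q = Linear(hidden, hidden, rng)
        self.k = Linear(hidden, hidden, rng)
        self.v = Linear(hidden, hidden, rng)
        self.out = Linear(hidden, hidden, rng)
        self.drop = Dropout(dropout, rng_ref)

    def forward(self, x: Tensor) -> Tensor:
        B, T, H = x.shape
        nh, hd = self.heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B,T,H) -> (B,nh,T,hd)
            return t.reshape(B, T, nh, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        attn = self.drop(scores.softmax(axis=-1))
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, H)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-LN residual block: LN(x + Drop(Attn(x))), LN(x + Drop(FFN(x)))."""

    def __init__(
        self,
        hidden: int,
        heads: int,
        ffn_dim: int,
        dropout: float,
        rng: np.random.Generator,
        rng_ref: RngRef,
    ):
        super().__init__()
        self.attn = MultiHeadSelfAttention(hidden, heads, dropout, rng, rng_ref)
        self.ln1 = LayerNorm(hidden)
        self.ffn_in = Linear(hidden, ffn_dim, rng)
        self.ffn_out = Linear(ffn_dim, hidden, rng)
        self.ln2 = LayerNorm(hidden)
        self.drop = Dropout(dropout, rng_ref)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x)))
        x = self.ln2(x + self.drop(self.ffn_out(self.ffn_in(x).gelu())))
        return x


class TransformerEncoder(Module):
    """Token + learned positional embeddings -> L encoder layers."""

    def __init__(
        self,
        vocab_size: int,
        max_len: int,
        hidden: int,
        layers: int,
        heads: int,
        ffn_dim: int,
        dropout: float,
        rng: np.random.Generator,
        rng_ref: RngRef,
    ):
        super().__init__()
        self.tok_emb = Embedding(vocab_size, hidden, rng)
        self.pos_emb = Embedding(max_len, hidden, rng)
        self.emb_ln = LayerNorm(hidden)
        self.emb_drop = Dropout(dropout, rng_ref)
        self.blocks = [
            TransformerEncoderLayer(hidden, heads, ffn_dim, dropout, rng, rng_ref)
            for _ in range(layers)
        ]
        self.max_len = max_len

    def forward(self, ids: np.ndarray) -> Tensor:
        B, T = ids.shape
        if T > self.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.max_len}")
        pos = np.broadcast_to(np.arange(T), (B, T))
        x = self.emb_drop(self.emb_ln(self.tok_emb(ids) + self.pos_emb(pos)))
        for block in self.blocks:
            x = block(x)
        return x  # (B, T, hidden)
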