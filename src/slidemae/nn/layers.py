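"""Parameter containers and transformer building blocks."""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, gelu, layer_norm, masked_softmax

__all__ = ["Module", "Linear", "LayerNorm", "MultiHeadSelfAttention", "TransformerBlock"]


class Module:
    """Base class with recursive named-parameter discovery."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.named_parameters(f"{key}.{i}."))
        return params

    def zero_grad(self) -> None:
        for p in self.named_parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        bound = 1.0 / math.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-bound, bound, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.bias = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias)


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    """H-head scaled dot-product self-attention with a key-validity mask.

    Keys flagged invalid receive exactly zero attention weight and rows
    renormalise over the remaining keys.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, dropout: float = 0.1):
        if d % n_heads:
            raise ValueError("model width must be divisible by the head count")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.dropout = dropout
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)

    def __call__(
        self,
        x: Tensor,
        key_valid: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        """x: (B, S, d); key_valid: (B, S) bool. Returns (out, attn (B,H,S,S))."""
        B, S, _ = x.shape
        H, dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(B, S, 3, H, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv.take([0], axis=0).reshape(B, H, S, dh), \
            qkv.take([1], axis=0).reshape(B, H, S, dh), \
            qkv.take([2], axis=0).reshape(B, H, S, dh)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = masked_softmax(logits, key_valid[:, None, None, :])
        attn_d = _dropout(attn, self.dropout, rng)
        out = (attn_d @ v).transpose(0, 2, 1, 3).reshape(B, S, H * dh)
        return self.proj(out), attn.data.copy()


class TransformerBlock(Module):
    """Pre-norm transformer encoder block with a 4x GELU MLP."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, dropout: float = 0.1):
        self.norm1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng, dropout)
        self.norm2 = LayerNorm(d)
        self.fc1 = Linear(d, 4 * d, rng)
        self.fc2 = Linear(4 * d, d, rng)
        self.dropout = dropout

    def __call__(
        self,
        x: Tensor,
        key_valid: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        a, attn = self.attn(self.norm1(x), key_valid, rng)
        x = x + _dropout(a, self.dropout, rng)
        h = self.fc2(gelu(self.fc1(self.norm2(x))))
        x = x + _dropout(h, self.dropout, rng)
        return x, attn
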