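"""Transformer region encoder with 2-D learnable positions and padding-aware attention.

A region is an n x n grid of d-dimensional patch features.  Each patch
receives the concatenation of learnable x- and y-axis positional vectors
(two tables of shape n_max x d/2); a learnable class token is prepended and
the sequence of length n^2 + 1 runs through L pre-norm transformer layers
with H heads each.  Background (zero-padded) cells are excluded from
attention as keys — they receive exactly zero attention weight — so padding
never leaks into foreground or class-token outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import Tensor, TransformerBlock, concat
from .nn.layers import LayerNorm, Module

__all__ = [
    "EncodedRegion",
    "RegionEncoder",
    "encode_region",
    "load_checkpoint",
    "positional_encoding",
    "save_checkpoint",
]


@dataclass
class EncodedRegion:
    """Outputs of the encoder for a single region."""

    class_out: np.ndarray  # (d,)
    patch_out: np.ndarray  # (n^2, d), row-major grid order
    attn: list[np.ndarray]  # per layer: (H, S, S), S = n^2 + 1


class RegionEncoder(Module):
    """L-layer, H-head ViT-style encoder over patch-feature grids.

    Parameters
    ----------
    d : model width; must be even (positions are two concatenated d/2 halves).
    L, H : transformer depth and heads per layer.
    n_max : largest supported region side, in patches (20 for the 10x
        profile: 4480 px / 224 px).
    dropout : attention/MLP dropout probability used only when a training
        rng is supplied to :meth:`forward`.
    pos_init_sd : initialisation scale of the positional tables.  The
        BERT/ViT convention of 0.02 assumes input embeddings of comparable
        (small) scale; when raw patch features of order-one scale are fed
        in and the step budget is short, position only influences attention
        if initialised at a comparable scale, so short-schedule profiles
        raise this.
    """

    def __init__(
        self,
        d: int = 512,
        L: int = 12,
        H: int = 8,
        n_max: int = 20,
        dropout: float = 0.1,
        pos_init_sd: float = 0.02,
        seed: int = 0,
    ):
        if d % 2:
            raise ValueError("model width d must be even")
        rng = np.random.Generator(np.random.PCG64(seed))
        self.d, self.L, self.H, self.n_max = d, L, H, n_max
        self.dropout = dropout
        self.pos_init_sd = pos_init_sd
        # class/mask tokens ~ Normal(0, 0.02); positional tables ~ Normal(0, pos_init_sd)
        self.pos_x = Tensor(rng.normal(0.0, pos_init_sd, (n_max, d // 2)), requires_grad=True)
        self.pos_y = Tensor(rng.normal(0.0, pos_init_sd, (n_max, d // 2)), requires_grad=True)
        self.class_token = Tensor(rng.normal(0.0, 0.02, (d,)), requires_grad=True)
        self.mask_token = Tensor(rng.normal(0.0, 0.02, (d,)), requires_grad=True)
        self.blocks = [TransformerBlock(d, H, rng, dropout) for _ in range(L)]
        self.final_norm = LayerNorm(d)

    def config(self) -> dict:
        return {
            "d": self.d,
            "L": self.L,
            "H": self.H,
            "n_max": self.n_max,
            "dropout": self.dropout,
            "pos_init_sd": self.pos_init_sd,
        }

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        features: np.ndarray,
        foreground: np.ndarray,
        masked: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor, list[np.ndarray]]:
        """Encode a batch of regions.

        features : (B, n, n, d) patch vectors (background cells zero).
        foreground : (B, n, n) bool.
        masked : optional (B, n, n) bool; masked foreground cells have their
            features replaced by the learnable mask token (with gradient).
        rng : enables dropout when given (training mode).

        Returns (class_out (B, d), patch_out (B, n^2, d), attention stack).
        """
        features = np.asarray(features, dtype=np.float64)
        if features.ndim == 3:
            features = features[None]
            foreground = np.asarray(foreground, dtype=bool)[None]
            if masked is not None:
                masked = np.asarray(masked, dtype=bool)[None]
        foreground = np.asarray(foreground, dtype=bool)
        B, n, n2, d = features.shape
        if n != n2 or d != self.d:
            raise ValueError(f"expected (B, n, n, {self.d}) features, got {features.shape}")
        if n > self.n_max:
            raise ValueError(f"region side {n} exceeds n_max={self.n_max}")
        if (~foreground.reshape(B, -1).any(axis=1)).any():
            raise ValueError("all-background region: no valid attention key")

        flat_fg = foreground.reshape(B, n * n)
        base = features.reshape(B, n * n, d).copy()
        base[~flat_fg] = 0.0  # background is the zero vector, whatever the caller sent
        if masked is not None:
            sub = masked.reshape(B, n * n) & flat_fg
            base[sub] = 0.0
            x = Tensor(base) + Tensor(sub[..., None].astype(np.float64)) * self.mask_token
        else:
            x = Tensor(base)

        ys, xs = np.divmod(np.arange(n * n), n)  # row-major: index = y*n + x
        pos = concat([self.pos_x.take(xs), self.pos_y.take(ys)], axis=-1)  # (n^2, d)
        x = x + pos

        cls = self.class_token.reshape(1, 1, d) * Tensor(np.ones((B, 1, 1)))
        seq = concat([cls, x], axis=1)  # (B, S, d)
        key_valid = np.concatenate([np.ones((B, 1), dtype=bool), flat_fg], axis=1)

        attn_stack: list[np.ndarray] = []
        for block in self.blocks:
            seq, attn = block(seq, key_valid, rng)
            attn_stack.append(attn)
        seq = self.final_norm(seq)
        S = n * n + 1
        class_out = seq.take([0], axis=1).reshape(B, d)
        patch_out = seq.take(np.arange(1, S), axis=1)
        return class_out, patch_out, attn_stack


def positional_encoding(x: int, y: int, model: RegionEncoder) -> np.ndarray:
    """The d-vector added to the patch at grid position (x, y).

    First d/2 entries are the x-axis table row, last d/2 the y-axis row.
    """
    if not (0 <= x < model.n_max and 0 <= y < model.n_max):
        raise IndexError(f"position ({x}, {y}) outside n_max={model.n_max}")
    return np.concatenate([model.pos_x.data[x], model.pos_y.data[y]])


def encode_region(
    features: np.ndarray,
    foreground: np.ndarray,
    model: RegionEncoder,
    masked: np.ndarray | None = None,
) -> EncodedRegion:
    """Deterministic (evaluation-mode) encoding of a single region."""
    class_out, patch_out, attn = model.forward(features, foreground, masked, rng=None)
    return EncodedRegion(
        class_out=class_out.data[0],
        patch_out=patch_out.data[0],
        attn=[a[0] for a in attn],
    )


def save_checkpoint(
    model: RegionEncoder,
    path: str | Path,
    extra: dict | None = None,
    arrays: dict[str, np.ndarray] | None = None,
) -> None:
    """Persist all weights plus the model config (npz with a JSON header).

    ``extra`` holds JSON-able metadata (e.g. training config); ``arrays``
    holds additional weight arrays such as a fitted prediction head.
    """
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    for k, v in (arrays or {}).items():
        payload[f"array/{k}"] = np.asarray(v)
    payload["config_json"] = np.frombuffer(
        json.dumps({"model": model.config(), "extra": extra or {}}).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[RegionEncoder, dict, dict[str, np.ndarray]]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["config_json"].tobytes()).decode())
        cfg = meta["model"]
        model = RegionEncoder(
            d=cfg["d"],
            L=cfg["L"],
            H=cfg["H"],
            n_max=cfg["n_max"],
            dropout=cfg["dropout"],
            pos_init_sd=cfg.get("pos_init_sd", 0.02),
        )
        model.load_state_dict(
            {k[len("param/") :]: z[k] for k in z.files if k.startswith("param/")}
        )
        arrays = {k[len("array/") :]: z[k] for k in z.files if k.startswith("array/")}
    return model, meta["extra"], arrays
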