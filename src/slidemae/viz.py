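"""Attention maps: per-query key maps, class-token rollout, adaptation maps.

The rollout attributes the final class token's information intake to input
patches by head-averaging each layer's attention matrix and recursively
multiplying the per-layer matrices, later layers on the left::

    A = A_L @ A_{L-1} @ ... @ A_1

The class-token row of ``A`` restricted to patch columns, renormalised to
sum to one over foreground patches, is the rollout map.  The adaptation map
is the elementwise difference between the fine-tuned and pre-trained rollout
maps of the same region and highlights where fine-tuning moved the class
token's attention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = [
    "RolloutMap",
    "adaptation_map",
    "head_average",
    "query_key_map",
    "render_slide_map",
    "rollout",
]


@dataclass
class RolloutMap:
    """Class-token attention over an n x n patch grid; background is zero."""

    weights: np.ndarray  # (n, n), non-negative, sums to 1 over foreground
    foreground: np.ndarray  # (n, n) bool

    def __post_init__(self):
        if self.weights.shape != self.foreground.shape:
            raise ValueError("weights and foreground must share shape")


def head_average(stack: list[np.ndarray]) -> list[np.ndarray]:
    """Mean over heads for each layer: (H, S, S) -> (S, S)."""
    return [np.asarray(layer).mean(axis=0) for layer in stack]


def _grid_side(S: int) -> int:
    n = int(round(np.sqrt(S - 1)))
    if n * n + 1 != S:
        raise ValueError(f"attention size {S} is not n^2 + 1 for integer n")
    return n


def query_key_map(
    stack: list[np.ndarray],
    layer: int,
    query: tuple[int, int],
    foreground: np.ndarray,
) -> np.ndarray:
    """Head-averaged attention paid by the query patch to every key patch.

    ``query`` is the (x, y) grid position; the class-token column is dropped
    and the row renormalised over patches.  Background queries are invalid.
    """
    A = head_average(stack)[layer]
    n = _grid_side(A.shape[0])
    x, y = query
    foreground = np.asarray(foreground, dtype=bool)
    if not (0 <= x < n and 0 <= y < n):
        raise ValueError(f"query ({x}, {y}) outside the {n}x{n} grid")
    if not foreground[y, x]:
        raise ValueError(f"query ({x}, {y}) is a background patch")
    row = A[1 + y * n + x, 1:]
    total = row.sum()
    if total > 0:
        row = row / total
    return row.reshape(n, n)


def rollout(stack: list[np.ndarray], foreground: np.ndarray) -> RolloutMap:
    """Recursive head-averaged attention product, read at the class token.

    If the class-token row leaves (numerically) no mass on patches — as for
    identity attention, where the class token only attends to itself — the
    map falls back to uniform over foreground with a warning so that the
    unit-sum contract always holds.
    """
    layers = head_average(stack)
    if not layers:
        raise ValueError("empty attention stack")
    n = _grid_side(layers[0].shape[0])
    foreground = np.asarray(foreground, dtype=bool)
    A = layers[0]
    for layer in layers[1:]:
        A = layer @ A  # later layers multiply on the left
    cls_row = A[0, 1:].copy()
    cls_row[~foreground.reshape(-1)] = 0.0
    total = cls_row.sum()
    if total <= 1e-12:
        warnings.warn(
            "class-token rollout mass on patches is ~0; falling back to a "
            "uniform map over foreground",
            stacklevel=2,
        )
        cls_row = foreground.reshape(-1).astype(np.float64)
        total = cls_row.sum()
    weights = (cls_row / total).reshape(n, n)
    return RolloutMap(weights=weights, foreground=foreground)


def adaptation_map(finetuned: RolloutMap, pretrained: RolloutMap) -> np.ndarray:
    """Fine-tuned minus pre-trained rollout; sums to zero over foreground."""
    if finetuned.weights.shape != pretrained.weights.shape:
        raise ValueError("rollout maps come from different grid sizes")
    if not np.array_equal(finetuned.foreground, pretrained.foreground):
        raise ValueError("rollout maps come from different foreground masks")
    return finetuned.weights - pretrained.weights


def render_slide_map(
    maps: list[tuple[tuple[int, int], np.ndarray]],
    slide_grid_shape: tuple[int, int],
    cmap: str = "coolwarm",
    out_path=None,
) -> np.ndarray:
    """Paint per-patch values onto the slide grid; overlaps are averaged.

    ``maps`` holds (region origin (x0, y0), n x n value array) pairs; cells
    never covered by any region stay NaN (rendered transparent).  Returns
    the painted value grid; when ``out_path`` is given, a diverging heatmap
    (red = high, blue = low) is also written there as PNG alongside a
    ``.npy`` sidecar with the raw values.
    """
    rows, cols = slide_grid_shape
    acc = np.zeros((rows, cols))
    cnt = np.zeros((rows, cols))
    for (x0, y0), values in maps:
        values = np.asarray(values, dtype=np.float64)
        n = values.shape[0]
        if x0 < 0 or y0 < 0 or y0 + n > rows or x0 + n > cols:
            raise ValueError(f"region at ({x0}, {y0}) exceeds slide grid {slide_grid_shape}")
        acc[y0 : y0 + n, x0 : x0 + n] += values
        cnt[y0 : y0 + n, x0 : x0 + n] += 1
    covered = cnt > 0
    painted = np.full((rows, cols), np.nan)
    painted[covered] = acc[covered] / cnt[covered]
    if out_path is not None:
        if covered.any():
            vmax = float(np.abs(painted[covered]).max()) or 1.0
            norm = matplotlib.colors.Normalize(vmin=-vmax, vmax=vmax)
            rgba = plt.get_cmap(cmap)(norm(np.nan_to_num(painted)))
        else:
            rgba = np.zeros((rows, cols, 4))
        rgba[..., 3] = covered.astype(float)
        plt.imsave(out_path, rgba)
        np.save(str(out_path) + ".npy", painted)
    return painted
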