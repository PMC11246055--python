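"""Region sampling from slide grids and blockwise mask generation.

Regions are n x n patch windows drawn from a slide's patch grid subject to
two constraints: at least 25% of the window must be foreground, and no two
sampled regions may overlap by more than a configurable fraction (default
50%) of the region area.  Masking for the pretext task accumulates
rectangular blocks until the achieved rate lands within +/-0.05 of the
target rate p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .store import PatchGrid, SlideFeatureSet, load_grid

__all__ = [
    "MaskPlan",
    "RegionSample",
    "apply_mask",
    "blockwise_mask",
    "propose_regions",
    "systematic_regions",
]

MIN_REGION_FOREGROUND = 0.25
MAX_REGION_OVERLAP = 0.5
RATE_TOLERANCE = 0.05

# blockwise-mask geometry, after the BEiT-style blockwise scheme: the
# minimum block area is 16 patches on a full-size 20x20 region and scales
# down proportionally for smaller grids (a fixed 16 would swallow a quarter
# of a toy 8x8 region in one block, leaving masked cells with no visible
# context at all); aspect ratio is log-uniform in ASPECT_RANGE
MIN_BLOCK_FRACTION = 16 / 400
ASPECT_RANGE = (0.3, 1.0 / 0.3)


@dataclass
class RegionSample:
    slide_id: str
    origin: tuple[int, int]
    n: int
    grid: PatchGrid


@dataclass
class MaskPlan:
    """Blockwise masking layout for one region.

    ``achieved_rate`` counts masked cells over *all* grid cells; positions
    contributing to the pretext loss are ``masked & foreground``.
    """

    masked: np.ndarray  # (n, n) bool
    target_rate: float
    achieved_rate: float

    def loss_positions(self, foreground: np.ndarray) -> np.ndarray:
        return self.masked & np.asarray(foreground, dtype=bool)


def _foreground_ok(window_count: int, n: int, min_fraction: float) -> bool:
    # integer arithmetic keeps the >= 25% boundary exact
    return window_count * 10_000 >= int(round(min_fraction * 10_000)) * n * n


def _window_counts(mask: np.ndarray, n: int) -> np.ndarray:
    """Foreground-cell count of every n x n window via a summed-area table."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.astype(np.int64), axis=0), axis=1)
    rows, cols = mask.shape
    out_r, out_c = rows - n + 1, cols - n + 1
    if out_r <= 0 or out_c <= 0:
        return np.zeros((0, 0), dtype=np.int64)
    return (
        ii[n : n + out_r, n : n + out_c]
        - ii[:out_r, n : n + out_c]
        - ii[n : n + out_r, :out_c]
        + ii[:out_r, :out_c]
    )


def _pairwise_overlap(a: tuple[int, int], b: tuple[int, int], n: int) -> float:
    ox = max(0, min(a[0] + n, b[0] + n) - max(a[0], b[0]))
    oy = max(0, min(a[1] + n, b[1] + n) - max(a[1], b[1]))
    return ox * oy / float(n * n)


def propose_regions(
    fset: SlideFeatureSet,
    n: int,
    count: int,
    max_overlap: float = MAX_REGION_OVERLAP,
    rng_seed: int | np.random.Generator = 0,
    min_foreground: float = MIN_REGION_FOREGROUND,
    max_proposals_per_region: int = 1000,
) -> list[RegionSample]:
    """Rejection-sample up to ``count`` admissible regions from one slide.

    Origins are uniform over grid-snapped positions; a proposal is accepted
    iff its foreground fraction is >= ``min_foreground`` and its overlap with
    every previously accepted region is <= ``max_overlap``.  Deterministic
    given the seed.  Returns fewer than ``count`` regions (with a warning)
    when proposals are exhausted; raises when no admissible window exists.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(rng_seed))
    )
    rows, cols = fset.grid_shape
    if n > rows or n > cols:
        raise ValueError(f"region size n={n} exceeds grid shape {fset.grid_shape}")
    counts = _window_counts(fset.foreground_mask(), n)
    admissible = np.argwhere(
        counts * 10_000 >= int(round(min_foreground * 10_000)) * n * n
    )
    if len(admissible) == 0:
        raise ValueError(
            f"slide {fset.slide_id!r}: no {n}x{n} window reaches "
            f"{min_foreground:.0%} foreground"
        )
    accepted: list[tuple[int, int]] = []
    out: list[RegionSample] = []
    for _ in range(count):
        placed = False
        for _ in range(max_proposals_per_region):
            y0 = int(rng.integers(0, rows - n + 1))
            x0 = int(rng.integers(0, cols - n + 1))
            if not _foreground_ok(int(counts[y0, x0]), n, min_foreground):
                continue
            if any(_pairwise_overlap((x0, y0), o, n) > max_overlap for o in accepted):
                continue
            accepted.append((x0, y0))
            out.append(
                RegionSample(fset.slide_id, (x0, y0), n, load_grid(fset, (x0, y0), n))
            )
            placed = True
            break
        if not placed:
            break
    if len(out) < count:
        warnings.warn(
            f"slide {fset.slide_id!r}: only {len(out)}/{count} admissible regions "
            f"found under overlap cap {max_overlap}",
            stacklevel=2,
        )
    return out


def systematic_regions(
    fset: SlideFeatureSet,
    n: int,
    count: int | None = None,
    max_overlap: float = MAX_REGION_OVERLAP,
    min_foreground: float = MIN_REGION_FOREGROUND,
) -> list[RegionSample]:
    """Deterministic raster of admissible regions with overlap-respecting stride.

    The stride is the smallest step guaranteeing pairwise overlap <=
    ``max_overlap``; the raster is clipped to the grid and filtered by the
    foreground threshold.  When ``count`` is given, the raster is subsampled
    evenly to that many regions.
    """
    rows, cols = fset.grid_shape
    if n > rows or n > cols:
        raise ValueError(f"region size n={n} exceeds grid shape {fset.grid_shape}")
    stride = max(1, int(np.ceil(n * (1.0 - max_overlap))))
    ys = sorted(set(list(range(0, rows - n + 1, stride)) + [rows - n]))
    xs = sorted(set(list(range(0, cols - n + 1, stride)) + [cols - n]))
    counts = _window_counts(fset.foreground_mask(), n)
    origins = [
        (x0, y0)
        for y0 in ys
        for x0 in xs
        if _foreground_ok(int(counts[y0, x0]), n, min_foreground)
    ]
    if not origins:
        raise ValueError(
            f"slide {fset.slide_id!r}: no systematic {n}x{n} window reaches "
            f"{min_foreground:.0%} foreground"
        )
    if count is not None and count < len(origins):
        idx = np.linspace(0, len(origins) - 1, count).round().astype(int)
        origins = [origins[i] for i in idx]
    return [
        RegionSample(fset.slide_id, (x0, y0), n, load_grid(fset, (x0, y0), n))
        for x0, y0 in origins
    ]


def blockwise_mask(
    foreground: np.ndarray,
    p: float,
    rng_seed: int | np.random.Generator = 0,
    tolerance: float = RATE_TOLERANCE,
    min_block_area: int | None = None,
) -> MaskPlan:
    """Accumulate rectangular blocks until the masking rate reaches p.

    Blocks have area uniform in [min_block_area, cells still needed]
    (clipped), log-uniform aspect ratio, uniform placement (blocks may
    overhang the grid edge and are clipped, keeping per-cell coverage
    uniform), and may overlap already-masked cells.  A block whose fresh
    cells would overshoot the target count is rejected and re-drawn; after
    repeated rejections single cells fill the remaining gap, so the achieved
    rate always lands within +/- tolerance of p.  The rate is counted over
    all grid cells, foreground or not.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if not 0.0 < p < 1.0:
        raise ValueError(f"masking rate p must be in (0, 1), got {p}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(rng_seed))
    )
    rows, cols = foreground.shape
    total = rows * cols
    if min_block_area is None:
        min_block_area = max(1, int(round(MIN_BLOCK_FRACTION * total)))
    target = max(1, int(round(p * total)))
    masked = np.zeros((rows, cols), dtype=bool)
    n_masked = 0
    rejects = 0
    while n_masked < target:
        if rejects >= 100:
            # fall back to single-cell blocks; lands exactly on target
            unmasked = np.flatnonzero(~masked.ravel())
            pick = rng.choice(unmasked, size=target - n_masked, replace=False)
            masked.ravel()[pick] = True
            n_masked = int(masked.sum())
            break
        area_hi = max(1, min(target - n_masked, total))
        area = int(rng.integers(min(min_block_area, area_hi), area_hi + 1))
        aspect = float(np.exp(rng.uniform(np.log(ASPECT_RANGE[0]), np.log(ASPECT_RANGE[1]))))
        h = max(1, min(rows, int(round(np.sqrt(area * aspect)))))
        w = max(1, min(cols, int(round(area / h))))
        # blocks may overhang the grid and are clipped: every cell then has
        # the same number of covering placements, so masking is spatially
        # unbiased (fully-interior placement would under-mask the borders)
        y0 = int(rng.integers(1 - h, rows))
        x0 = int(rng.integers(1 - w, cols))
        block = np.zeros_like(masked)
        block[max(0, y0) : y0 + h, max(0, x0) : x0 + w] = True
        if not block.any():
            continue
        new = int((block & ~masked).sum())
        if n_masked + new > target:
            rejects += 1
            continue
        masked |= block
        n_masked += new
    achieved = n_masked / total
    return MaskPlan(masked=masked, target_rate=p, achieved_rate=achieved)


def apply_mask(grid: PatchGrid, plan: MaskPlan, mask_token: np.ndarray) -> np.ndarray:
    """Substitute the mask token at masked foreground positions.

    Background cells stay zero (they are excluded from attention and from
    the loss); unmasked foreground features pass through unchanged.
    """
    mask_token = np.asarray(mask_token, dtype=np.float64)
    if mask_token.shape != (grid.features.shape[2],):
        raise ValueError("mask token dimension does not match grid features")
    out = grid.features.astype(np.float64).copy()
    out[plan.loss_positions(grid.foreground)] = mask_token
    return out
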