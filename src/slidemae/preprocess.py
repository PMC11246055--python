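"""Slide preprocessing: tissue masking, tiling and patch feature extraction.

The tissue mask is computed on a low-magnification thumbnail (0.3125x,
32 um/px for a 10x pipeline) with a purple-hue threshold tuned to H&E
staining, then cleaned with binary closing and opening.  Patches whose
footprint contains at least 5% tissue count as foreground; only foreground
patches are encoded and stored, background positions become zero vectors
downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from skimage.morphology import closing, opening
from skimage.transform import resize

from .store import SlideFeatureSet

__all__ = [
    "ArraySlideReader",
    "HashingPatchEncoder",
    "PatchEncoder",
    "RandomProjectionEncoder",
    "TissueMask",
    "classify_foreground",
    "compute_tissue_mask",
    "extract_features",
    "tile_slide",
]

FOREGROUND_TISSUE_FRACTION = 0.05


@dataclass
class TissueMask:
    """Binary tissue map at thumbnail resolution.

    ``scale_factor`` is the number of full-resolution pixels per mask pixel
    along each axis (32 for a 10x/1 um-per-px pipeline masked at 32 um/px).
    """

    mask: np.ndarray  # 2-D bool
    scale_factor: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("tissue mask must be 2-D")


def _purple_rule(
    rgb: np.ndarray,
    white_min_channel: int = 220,
    green_slack: int = 10,
) -> np.ndarray:
    """Per-pixel H&E tissue rule: not near-white, and red+blue dominate green."""
    r = rgb[..., 0].astype(np.int16)
    g = rgb[..., 1].astype(np.int16)
    b = rgb[..., 2].astype(np.int16)
    not_white = np.min(rgb, axis=-1) < white_min_channel
    purple = (b >= g) & (r >= g - green_slack)
    return not_white & purple


def compute_tissue_mask(
    thumbnail: np.ndarray,
    scale_factor: float = 32.0,
    structure_size: int = 3,
) -> TissueMask:
    """Threshold a thumbnail for tissue and clean the result morphologically.

    Binary closing (dilation then erosion) removes single-pixel holes inside
    tissue; a following opening drops isolated debris.  The structuring
    element is a ``structure_size`` square.
    """
    thumbnail = np.asarray(thumbnail)
    if thumbnail.size == 0:
        raise ValueError("empty thumbnail image")
    if thumbnail.ndim != 3 or thumbnail.shape[-1] != 3:
        raise ValueError("thumbnail must be an H x W x 3 RGB image")
    raw = _purple_rule(thumbnail.astype(np.uint8))
    footprint = np.ones((structure_size, structure_size), dtype=bool)
    cleaned = opening(closing(raw, footprint), footprint)
    return TissueMask(mask=cleaned, scale_factor=scale_factor)


def classify_foreground(
    patch_mask_region: np.ndarray,
    min_tissue_fraction: float = FOREGROUND_TISSUE_FRACTION,
) -> bool:
    """True iff the tissue fraction over the patch footprint is >= threshold."""
    region = np.asarray(patch_mask_region, dtype=bool)
    if region.size == 0:
        return False
    # integer comparison keeps the >= boundary exact (e.g. 5.0% is foreground)
    num = int(round(min_tissue_fraction * 10_000))
    return int(region.sum()) * 10_000 >= num * region.size


def tile_slide(slide_dims_px: tuple[int, int], patch_size_px: int) -> list[tuple[int, int]]:
    """Non-overlapping patch-grid coordinates (x, y), row-major.

    ``slide_dims_px`` is (width, height); patches that would cross the slide
    boundary are dropped, so the count is ``floor(W/l) * floor(H/l)``.
    """
    width, height = slide_dims_px
    l = patch_size_px
    if width <= 0 or height <= 0 or l <= 0:
        raise ValueError("slide dimensions and patch size must be positive")
    return [(x, y) for y in range(height // l) for x in range(width // l)]


class PatchEncoder(Protocol):
    """Fixed feature extractor mapping a patch image to a d_out vector."""

    name: str
    d_out: int

    def encode(self, patch: np.ndarray) -> np.ndarray: ...


class HashingPatchEncoder:
    """Deterministic stub encoder: hashes patch bytes into a pseudo-random vector.

    Identical pixel content always maps to the identical vector, which makes
    store round-trips and extraction order-invariance exactly testable.  It
    carries no visual similarity structure and exists for plumbing tests.
    """

    def __init__(self, d_out: int = 512):
        self.name = f"hash-{d_out}"
        self.d_out = d_out

    def encode(self, patch: np.ndarray) -> np.ndarray:
        patch = np.ascontiguousarray(patch, dtype=np.uint8)
        digest = hashlib.blake2b(patch.tobytes(), digest_size=8).digest()
        seed = int.from_bytes(digest, "little") % (2**31)
        rng = np.random.Generator(np.random.PCG64(seed))
        return rng.standard_normal(self.d_out).astype(np.float32)


class RandomProjectionEncoder:
    """Fixed random projection of a downsampled patch; similarity-preserving.

    The patch is resized to ``thumb`` x ``thumb`` RGB, flattened, and passed
    through a frozen Gaussian projection drawn once from ``seed``; nearby
    patches in pixel space land near each other in feature space
    (Johnson-Lindenstrauss), which is the property the transformer's pretext
    task relies on.
    """

    def __init__(self, d_out: int = 512, thumb: int = 16, seed: int = 7):
        self.name = f"randproj-{d_out}"
        self.d_out = d_out
        self.thumb = thumb
        rng = np.random.Generator(np.random.PCG64(seed))
        d_in = thumb * thumb * 3
        self._proj = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)

    def encode(self, patch: np.ndarray) -> np.ndarray:
        small = resize(
            np.asarray(patch, dtype=np.float64) / 255.0,
            (self.thumb, self.thumb, 3),
            anti_aliasing=True,
        )
        return (small.ravel() @ self._proj).astype(np.float32)


class ArraySlideReader:
    """Level-aware reader over an in-memory full-resolution RGB array.

    Stands in for a pyramidal slide file; ``thumbnail`` emulates reading a
    low-magnification pyramid level by block-averaging.
    """

    def __init__(self, image: np.ndarray):
        image = np.asarray(image, dtype=np.uint8)
        if image.ndim != 3 or image.shape[-1] != 3:
            raise ValueError("slide image must be H x W x 3 RGB")
        self.image = image

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height) at full resolution."""
        return self.image.shape[1], self.image.shape[0]

    def read_region(self, x_px: int, y_px: int, size: int) -> np.ndarray:
        return self.image[y_px : y_px + size, x_px : x_px + size]

    def thumbnail(self, scale_factor: int) -> np.ndarray:
        h, w = self.image.shape[:2]
        th, tw = max(1, h // scale_factor), max(1, w // scale_factor)
        cropped = self.image[: th * scale_factor, : tw * scale_factor].astype(np.float64)
        blocks = cropped.reshape(th, scale_factor, tw, scale_factor, 3)
        return blocks.mean(axis=(1, 3)).round().astype(np.uint8)


def extract_features(
    slide,
    mask: TissueMask,
    encoder: PatchEncoder,
    patch_size_px: int,
    slide_id: str = "slide",
    magnification_tag: str = "10x",
) -> SlideFeatureSet:
    """Encode every foreground patch of a slide into a SlideFeatureSet.

    Foreground is decided on the thumbnail-resolution mask over each patch
    footprint; background patches are skipped entirely.  Raises when the
    slide has no foreground patch.
    """
    width, height = slide.dims
    l = patch_size_px
    sf = mask.scale_factor
    coords, vectors = [], []
    for x, y in tile_slide((width, height), l):
        mx0 = int(np.floor(x * l / sf))
        mx1 = max(mx0 + 1, int(np.ceil((x + 1) * l / sf)))
        my0 = int(np.floor(y * l / sf))
        my1 = max(my0 + 1, int(np.ceil((y + 1) * l / sf)))
        footprint = mask.mask[my0:my1, mx0:mx1]
        if not classify_foreground(footprint):
            continue
        patch = slide.read_region(x * l, y * l, l)
        vectors.append(np.asarray(encoder.encode(patch), dtype=np.float32))
        coords.append((x, y))
    if not coords:
        raise ValueError(f"slide {slide_id!r} contains no foreground patch")
    return SlideFeatureSet(
        slide_id=slide_id,
        magnification_tag=magnification_tag,
        patch_size_px=l,
        grid_shape=(height // l, width // l),
        features=np.stack(vectors),
        coords=np.asarray(coords, dtype=np.int64),
    )
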