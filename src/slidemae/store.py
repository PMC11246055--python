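"""On-disk contract for per-slide patch features.

A cohort lives in one HDF5 file with one group per slide under
``slides/<slide_id>``, holding ``features`` (Nf x d, float32) and ``coords``
(Nf x 2, int64) arrays plus grid metadata attributes.  Only foreground
patches are stored; background positions are reconstructed as zero vectors
when a region is materialised.

Coordinates are 0-based patch-grid positions with ``x`` = column and ``y`` =
row; patch (x, y) covers pixels ``[x*l, (x+1)*l) x [y*l, (y+1)*l)`` for patch
size ``l``.  All in-memory grids are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PatchGrid",
    "SlideFeatureSet",
    "list_slides",
    "load_grid",
    "read_classification_labels",
    "read_survival_labels",
    "read_slide",
    "write_slide",
]


@dataclass
class SlideFeatureSet:
    """Feature vectors and grid coordinates of one slide's foreground patches."""

    slide_id: str
    magnification_tag: str
    patch_size_px: int
    grid_shape: tuple[int, int]  # (rows, cols)
    features: np.ndarray  # (Nf, d)
    coords: np.ndarray  # (Nf, 2) as (x, y)

    def __post_init__(self):
        self.features = np.asarray(self.features)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.validate()

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def n_foreground(self) -> int:
        return self.features.shape[0]

    def validate(self) -> None:
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError(
                f"slide {self.slide_id!r}: features must be a non-empty Nf x d matrix"
            )
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError(f"slide {self.slide_id!r}: coords/features row mismatch")
        rows, cols = self.grid_shape
        x, y = self.coords[:, 0], self.coords[:, 1]
        if (x < 0).any() or (x >= cols).any() or (y < 0).any() or (y >= rows).any():
            bad = self.coords[(x < 0) | (x >= cols) | (y < 0) | (y >= rows)][0]
            raise ValueError(
                f"slide {self.slide_id!r}: coord ({int(bad[0])}, {int(bad[1])}) "
                f"outside grid shape (rows={rows}, cols={cols})"
            )
        keys = y.astype(np.int64) * cols + x
        if len(np.unique(keys)) != len(keys):
            raise ValueError(f"slide {self.slide_id!r}: duplicate patch coordinates")

    def foreground_mask(self) -> np.ndarray:
        """Dense (rows, cols) boolean foreground map."""
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[self.coords[:, 1], self.coords[:, 0]] = True
        return mask


@dataclass
class PatchGrid:
    """An n x n window of patch features cut from a slide grid.

    ``features[y, x]`` is the all-zero vector wherever ``foreground[y, x]``
    is False.
    """

    origin: tuple[int, int]  # (x0, y0) in patch-grid units
    n: int
    features: np.ndarray  # (n, n, d)
    foreground: np.ndarray  # (n, n) bool

    def __post_init__(self):
        if self.features.shape[:2] != (self.n, self.n):
            raise ValueError("features must be n x n x d")
        if self.foreground.shape != (self.n, self.n):
            raise ValueError("foreground must be n x n")

    @property
    def foreground_fraction(self) -> float:
        return float(self.foreground.mean())


def write_slide(fset: SlideFeatureSet, store_path: str | Path) -> None:
    """Append one slide to a cohort store, creating the file if needed.

    Features are stored as float32.  Raises if the slide id already exists
    or if the store's feature dimension disagrees.
    """
    fset.validate()
    with h5py.File(store_path, "a") as f:
        slides = f.require_group("slides")
        if fset.slide_id in slides:
            raise ValueError(f"slide id {fset.slide_id!r} already present in store")
        if "d" in f.attrs and int(f.attrs["d"]) != fset.d:
            raise ValueError(
                f"store feature dimension {int(f.attrs['d'])} != slide d {fset.d}"
            )
        f.attrs["d"] = fset.d
        g = slides.create_group(fset.slide_id)
        g.create_dataset("features", data=fset.features.astype(np.float32), chunks=True)
        g.create_dataset("coords", data=fset.coords.astype(np.int64))
        g.attrs["grid_shape"] = np.asarray(fset.grid_shape, dtype=np.int64)
        g.attrs["patch_size_px"] = int(fset.patch_size_px)
        g.attrs["magnification_tag"] = fset.magnification_tag
        g.attrs["d"] = fset.d


def read_slide(store_path: str | Path, slide_id: str) -> SlideFeatureSet:
    with h5py.File(store_path, "r") as f:
        try:
            g = f["slides"][slide_id]
        except KeyError:
            raise KeyError(f"slide id {slide_id!r} not found in {store_path}") from None
        return SlideFeatureSet(
            slide_id=slide_id,
            magnification_tag=str(g.attrs["magnification_tag"]),
            patch_size_px=int(g.attrs["patch_size_px"]),
            grid_shape=tuple(int(v) for v in g.attrs["grid_shape"]),
            features=g["features"][...].astype(np.float32),
            coords=g["coords"][...],
        )


def list_slides(store_path: str | Path) -> list[str]:
    with h5py.File(store_path, "r") as f:
        if "slides" not in f:
            return []
        return sorted(f["slides"].keys())


def load_grid(fset: SlideFeatureSet, origin: tuple[int, int], n: int) -> PatchGrid:
    """Materialise the n x n window at ``origin`` (x0, y0) as a dense grid.

    Stored vectors land at their local positions; everything else is the
    zero vector with ``foreground`` False.
    """
    x0, y0 = origin
    rows, cols = fset.grid_shape
    if x0 < 0 or y0 < 0 or x0 + n > cols or y0 + n > rows:
        raise ValueError(
            f"window origin ({x0}, {y0}) with n={n} falls outside grid "
            f"(rows={rows}, cols={cols})"
        )
    d = fset.d
    features = np.zeros((n, n, d), dtype=np.float64)
    foreground = np.zeros((n, n), dtype=bool)
    x, y = fset.coords[:, 0], fset.coords[:, 1]
    inside = (x >= x0) & (x < x0 + n) & (y >= y0) & (y < y0 + n)
    lx, ly = x[inside] - x0, y[inside] - y0
    features[ly, lx] = fset.features[inside]
    foreground[ly, lx] = True
    return PatchGrid(origin=(x0, y0), n=n, features=features, foreground=foreground)


def _read_labels(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"label table {path} missing columns: {missing}")
    df["slide_id"] = df["slide_id"].astype(str)
    return df


def read_survival_labels(path: str | Path) -> pd.DataFrame:
    """CSV with columns slide_id, time_years, event (0/1)."""
    df = _read_labels(path, ["slide_id", "time_years", "event"])
    if (df["time_years"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df


def read_classification_labels(path: str | Path) -> pd.DataFrame:
    """CSV with columns slide_id, label."""
    return _read_labels(path, ["slide_id", "label"])
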