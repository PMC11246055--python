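"""Synthetic feature stores and outcome tables for end-to-end testing.

Real slide feature grids have two statistical properties the region
transformer exploits: patches cluster into a small number of recurring
tissue motifs, and motif identity is spatially autocorrelated (neighbouring
patches tend to share a motif).  The generator emulates exactly that: each
slide carries a latent motif field obtained by nearest-centroid
classification of independently smoothed Gaussian noise fields (correlation
length ``spatial_corr_len``), a blob-shaped foreground mask covering about
``foreground_fraction`` of the grid, and patch features equal to the motif
centroid plus isotropic Gaussian noise.

Outcomes depend on the *spatial co-occurrence* of motifs, so slide-level
labels are only predictable by a model that integrates context across
patches:

* survival — the log hazard is a linear function of the slide's normalised
  motif-adjacency count for a designated motif pair; times are exponential
  with independent uniform censoring;
* classification — the class indicates which of two designated motif pairs
  is more often adjacent on the slide.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .store import SlideFeatureSet, write_slide

__all__ = ["FixtureSpec", "SyntheticCohort", "gen_outcomes", "gen_store"]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic cohort.

    Defaults give a cohort that a toy-profile model (d=32, 2 layers) can
    learn from in ~10^3 optimisation steps while remaining non-trivial:
    four motifs whose centroids are unit-scale Gaussian vectors, noise at
    three quarters of the centroid scale — enough ambiguity that context
    genuinely helps patch identification — and motif territories of a few
    grid cells.
    """

    n_slides: int = 24
    grid_shape: tuple[int, int] = (16, 16)
    d: int = 32
    n_motifs: int = 4
    motif_centroids: np.ndarray | None = None
    spatial_corr_len: float = 2.5
    noise_sd: float = 0.75
    noise_corr_len: float = 1.5  # 0 -> white per-patch noise
    foreground_fraction: float = 0.8
    outcome: str = "survival"  # "survival" | "classification"
    baseline_hazard: float = 0.1
    risk_coefficient: float = 1.5
    risk_pair: tuple[int, int] = (0, 1)
    class_pair_a: tuple[int, int] = (0, 1)
    class_pair_b: tuple[int, int] = (2, 3)
    censoring_rate: float = 0.3
    seed: int = 0
    # the motif "vocabulary" is shared across cohorts (tissue appearance is
    # common to datasets even when slides differ), so centroids draw from
    # their own seed, independent of the per-cohort stream
    centroid_seed: int = 7

    def __post_init__(self):
        if not 0.0 < self.foreground_fraction <= 1.0:
            raise ValueError("foreground_fraction must be in (0, 1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        for pair in (self.risk_pair, self.class_pair_a, self.class_pair_b):
            if max(pair) >= self.n_motifs:
                raise ValueError(f"outcome rule references missing motif in {pair}")

    def centroids(self) -> np.ndarray:
        if self.motif_centroids is not None:
            c = np.asarray(self.motif_centroids, dtype=np.float64)
            if c.shape != (self.n_motifs, self.d):
                raise ValueError("motif_centroids must be n_motifs x d")
        else:
            rng = np.random.Generator(np.random.PCG64(self.centroid_seed))
            c = rng.normal(0.0, 1.0, (self.n_motifs, self.d))
        dists = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() < 1e-8:
            raise ValueError("motif centroids collide; increase d or respecify")
        return c


@dataclass
class SyntheticCohort:
    """Generated slides plus the latent fields the outcomes were built from."""

    slides: list[SlideFeatureSet]
    motif_fields: dict[str, np.ndarray]  # (rows, cols) int motif labels
    foreground: dict[str, np.ndarray]  # (rows, cols) bool
    centroids: np.ndarray

    def write(self, store_path: str | Path) -> None:
        for fset in self.slides:
            write_slide(fset, store_path)


def _motif_field(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid_shape
    scores = np.stack(
        [
            gaussian_filter(rng.standard_normal((rows, cols)), spec.spatial_corr_len, mode="wrap")
            for _ in range(spec.n_motifs)
        ]
    )
    return scores.argmax(axis=0)


def _foreground_blob(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid_shape
    if spec.foreground_fraction >= 1.0:
        return np.ones((rows, cols), dtype=bool)
    u = gaussian_filter(rng.standard_normal((rows, cols)), spec.spatial_corr_len, mode="wrap")
    thresh = np.quantile(u, 1.0 - spec.foreground_fraction)
    fg = u >= thresh
    if not fg.any():  # numerical tie edge case
        fg.ravel()[int(np.argmax(u))] = True
    return fg


def _noise_field(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    """(rows, cols, d) Gaussian noise, spatially smooth when noise_corr_len > 0.

    Marginal scale is normalised back to ``noise_sd`` after smoothing.  The
    spatial correlation mirrors tissue continuity: a patch's appearance is
    partly predictable from its neighbours, which is what makes masked
    restoration (and its contrastive term) informative.
    """
    rows, cols = spec.grid_shape
    raw = rng.standard_normal((spec.d, rows, cols))
    if spec.noise_corr_len > 0:
        raw = gaussian_filter(raw, (0, spec.noise_corr_len, spec.noise_corr_len), mode="wrap")
        raw /= raw.std()
    return spec.noise_sd * raw.transpose(1, 2, 0)


def gen_store(spec: FixtureSpec) -> SyntheticCohort:
    """Generate the cohort's slides; deterministic given ``spec.seed``."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    centroids = spec.centroids()
    slides, motif_fields, foregrounds = [], {}, {}
    for s in range(spec.n_slides):
        slide_id = f"synthetic_{s:04d}"
        motifs = _motif_field(spec, rng)
        fg = _foreground_blob(spec, rng)
        ys, xs = np.nonzero(fg)
        feats = centroids[motifs[ys, xs]] + _noise_field(spec, rng)[ys, xs]
        slides.append(
            SlideFeatureSet(
                slide_id=slide_id,
                magnification_tag="10x",
                patch_size_px=224,
                grid_shape=spec.grid_shape,
                features=feats.astype(np.float32),
                coords=np.column_stack([xs, ys]).astype(np.int64),
            )
        )
        motif_fields[slide_id] = motifs
        foregrounds[slide_id] = fg
    return SyntheticCohort(slides, motif_fields, foregrounds, centroids)


def _adjacency_count(
    motifs: np.ndarray, fg: np.ndarray, pair: tuple[int, int]
) -> int:
    """Number of 4-neighbour foreground cell pairs carrying the two motifs."""
    a, b = pair
    count = 0
    for axis in (0, 1):
        m1 = np.take(motifs, range(motifs.shape[axis] - 1), axis=axis)
        m2 = np.take(motifs, range(1, motifs.shape[axis]), axis=axis)
        f1 = np.take(fg, range(fg.shape[axis] - 1), axis=axis)
        f2 = np.take(fg, range(1, fg.shape[axis]), axis=axis)
        both_fg = f1 & f2
        count += int((((m1 == a) & (m2 == b)) & both_fg).sum())
        count += int((((m1 == b) & (m2 == a)) & both_fg).sum())
    return count


def gen_outcomes(spec: FixtureSpec, cohort: SyntheticCohort) -> pd.DataFrame:
    """Build the slide-level label table matching ``spec.outcome``.

    Survival tables carry columns slide_id, time_years, event; the log
    hazard is ``risk_coefficient`` times the z-scored adjacency count of
    ``risk_pair``.  Classification tables carry slide_id, label with label 1
    iff ``class_pair_a`` adjacencies outnumber ``class_pair_b`` ones.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed + 1))
    ids = [s.slide_id for s in cohort.slides]
    if spec.outcome == "classification":
        labels = [
            int(
                _adjacency_count(cohort.motif_fields[i], cohort.foreground[i], spec.class_pair_a)
                > _adjacency_count(cohort.motif_fields[i], cohort.foreground[i], spec.class_pair_b)
            )
            for i in ids
        ]
        return pd.DataFrame({"slide_id": ids, "label": labels})
    if spec.outcome != "survival":
        raise ValueError(f"unknown outcome kind {spec.outcome!r}")
    counts = np.array(
        [
            _adjacency_count(cohort.motif_fields[i], cohort.foreground[i], spec.risk_pair)
            for i in ids
        ],
        dtype=np.float64,
    )
    sd = counts.std()
    z = (counts - counts.mean()) / (sd if sd > 0 else 1.0)
    risk = spec.risk_coefficient * z
    times = rng.exponential(1.0 / (spec.baseline_hazard * np.exp(risk)))
    if spec.censoring_rate > 0:
        # independent uniform censoring calibrated to the requested rate
        horizon = np.quantile(times, 1.0 - spec.censoring_rate) * 2.0
        censor = rng.uniform(0.0, horizon, len(times))
        target_censored = int(round(spec.censoring_rate * len(times)))
        lo, hi = 0.01, horizon
        for _ in range(40):  # bisect the horizon to hit the rate
            mid = 0.5 * (lo + hi)
            if (censor * mid / horizon < times).sum() > target_censored:
                lo = mid
            else:
                hi = mid
        censor = censor * (0.5 * (lo + hi)) / horizon
        events = (times <= censor).astype(int)
        observed = np.minimum(times, censor)
    else:
        events = np.ones(len(times), dtype=int)
        observed = times
    observed = np.maximum(observed, 1e-4)
    return pd.DataFrame(
        {"slide_id": ids, "time_years": observed, "event": events, "true_risk": risk}
    )
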