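"""Pre-training (masked restoration) and fine-tuning (slide-level) loops.

Pre-training samples a fixed number of regions per slide each iteration,
masks them blockwise, and optimises the restoration loss over the pooled
masked foreground patches of the whole batch.  The learning rate warms up
linearly and then follows a cosine decay.  80% of slides train the model;
the held-out 20% only monitor the loss.

Fine-tuning encodes unmasked regions, averages their class tokens into a
slide representation, and trains a linear head — a Cox risk score for
survival or logits for classification — with a large head learning rate and
a small backbone learning rate.  Early stopping ends training after a fixed
number of epochs without improvement of the monitor metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .losses import (
    concordance_index,
    cox_loss_t,
    cross_entropy_t,
    macro_auc,
    restoration_loss_t,
)
from .model import RegionEncoder
from .nn import AdamW, Linear, Tensor
from .nn.layers import Module
from .sampling import RegionSample, blockwise_mask, propose_regions
from .store import SlideFeatureSet, list_slides, read_slide

__all__ = [
    "EarlyStopper",
    "FinetuneConfig",
    "FinetuneResult",
    "LinearHead",
    "PretrainConfig",
    "PretrainResult",
    "evaluate",
    "finetune",
    "lr_at",
    "pretrain",
]


_NO_DECAY_MARKERS = ("bias", "gain", "pos_x", "pos_y", "class_token", "mask_token")


def _param_groups(module, lr_scale: float, prefix: str) -> dict:
    """Split a module's parameters into decay / no-decay optimizer groups.

    Norm gains, biases, positional tables and the class/mask tokens are
    exempt from weight decay (ViT convention); matrix weights decay.
    """
    params = module.named_parameters()
    decay = {k: v for k, v in params.items() if not any(m in k for m in _NO_DECAY_MARKERS)}
    no_decay = {k: v for k, v in params.items() if any(m in k for m in _NO_DECAY_MARKERS)}
    return {
        prefix: (decay, lr_scale, 1.0),
        f"{prefix}_no_decay": (no_decay, lr_scale, 0.0),
    }


def _resolve_slides(store) -> list[SlideFeatureSet]:
    if isinstance(store, (str, Path)):
        return [read_slide(store, sid) for sid in list_slides(store)]
    return list(store)


@dataclass
class PretrainConfig:
    """Masked pre-training schedule.

    Defaults are the full-scale recipe (peak rate 4e-5, 8000 warmup steps,
    400k total steps, batch of 64 regions, two regions per slide per
    iteration, AdamW, 80/20 slide split); :meth:`toy` shrinks the scale
    knobs for desk-size runs.
    """

    lr_peak: float = 4e-5
    warmup_steps: int = 8000
    total_steps: int = 400_000
    batch_size: int = 64
    regions_per_slide: int = 2
    region_n: int = 20
    mask_p: float = 0.5
    alpha: float = 2.0
    beta: float = 1.0
    tau: float = 0.1
    train_fraction: float = 0.8
    weight_decay: float = 0.05
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    monitor_every: int | None = None  # default: one nominal epoch
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.warmup_steps < self.total_steps:
            raise ValueError("need 0 < warmup_steps < total_steps")
        if not 0.0 < self.mask_p < 1.0:
            raise ValueError("mask_p must be in (0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    @classmethod
    def toy(cls, **overrides) -> "PretrainConfig":
        base = dict(
            lr_peak=3e-3,
            warmup_steps=50,
            total_steps=1000,
            batch_size=8,
            region_n=8,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class FinetuneConfig:
    """Slide-level fine-tuning schedule.

    ``head_lr`` defaults to the task convention (1e-3 survival, 3e-3
    classification) when left None; the transformer backbone always trains
    at ``backbone_lr``.  ``coverage`` is the fraction of each sampled
    region's foreground patches that are kept (the rest are blanked to
    background), mirroring the "regions x coverage" sampling schemas.
    """

    task: str = "survival"  # "survival" | "classification"
    head_lr: float | None = None
    backbone_lr: float = 1e-5
    region_n: int = 20
    regions_per_slide_train: int = 2
    coverage_train: float = 1.0
    regions_eval: int = 2
    coverage_eval: float = 1.0
    max_overlap: float = 0.5
    patience: int = 5
    max_epochs: int = 30
    slide_batch: int = 8
    val_fraction: float = 0.25
    weight_decay: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("survival", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        for c in (self.coverage_train, self.coverage_eval):
            if not 0.0 < c <= 1.0:
                raise ValueError("coverage must be in (0, 1]")

    @property
    def resolved_head_lr(self) -> float:
        if self.head_lr is not None:
            return self.head_lr
        return 1e-3 if self.task == "survival" else 3e-3


def lr_at(step: int, cfg: PretrainConfig) -> float:
    """Linear warmup to ``lr_peak`` then cosine decay to 0 at the last step."""
    if not 0 <= step <= cfg.total_steps:
        raise ValueError(f"step {step} outside [0, {cfg.total_steps}]")
    if step <= cfg.warmup_steps:
        return cfg.lr_peak * step / cfg.warmup_steps
    frac = (step - cfg.warmup_steps) / (cfg.total_steps - cfg.warmup_steps)
    return cfg.lr_peak * 0.5 * (1.0 + math.cos(math.pi * frac))


@dataclass
class PretrainResult:
    model: RegionEncoder
    history: pd.DataFrame  # step, lr, train_loss, monitor_loss (NaN between evals)
    best_state: dict
    best_monitor_loss: float
    train_slides: list[str]
    monitor_slides: list[str]
    skipped_batches: int


def _split_slides(
    slide_ids: list[str], train_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    order = list(slide_ids)
    rng.shuffle(order)
    n_train = max(1, int(round(train_fraction * len(order))))
    n_train = min(n_train, len(order) - 1) if len(order) > 1 else 1
    return sorted(order[:n_train]), sorted(order[n_train:])


def _sample_masked_batch(
    slides: dict[str, SlideFeatureSet],
    ids: list[str],
    cfg: PretrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """Draw regions until the batch is full; returns stacked arrays.

    Output: features (B, n, n, d), foreground, masked (B, n, n) and the
    original features (for loss targets).  None when no region in the batch
    has a masked foreground patch.
    """
    feats, fgs, masks = [], [], []
    order = list(ids)
    rng.shuffle(order)
    cursor = 0
    while len(feats) < cfg.batch_size:
        sid = order[cursor % len(order)]
        cursor += 1
        try:
            regions = propose_regions(
                slides[sid], cfg.region_n, cfg.regions_per_slide, rng_seed=rng
            )
        except ValueError:
            continue
        for region in regions:
            plan = blockwise_mask(region.grid.foreground, cfg.mask_p, rng_seed=rng)
            feats.append(region.grid.features)
            fgs.append(region.grid.foreground)
            masks.append(plan.masked)
            if len(feats) == cfg.batch_size:
                break
        if cursor > 50 * len(order):  # no admissible regions anywhere
            break
    if not feats:
        return None
    features = np.stack(feats)
    foreground = np.stack(fgs)
    masked = np.stack(masks)
    if not (masked & foreground).any():
        return None
    return features, foreground, masked, features


def _pooled_restoration_loss(
    model: RegionEncoder,
    features: np.ndarray,
    foreground: np.ndarray,
    masked: np.ndarray,
    cfg: PretrainConfig,
    rng: np.random.Generator | None,
) -> Tensor:
    _, patch_out, _ = model.forward(features, foreground, masked, rng=rng)
    B, n = features.shape[0], features.shape[1]
    flat_sel = (masked & foreground).reshape(B * n * n)
    idx = np.flatnonzero(flat_sel)
    outputs = patch_out.reshape(B * n * n, model.d).take(idx, axis=0)
    targets = features.reshape(B * n * n, model.d)[idx]
    return restoration_loss_t(targets, outputs, cfg.alpha, cfg.beta, cfg.tau)


def pretrain(store, model: RegionEncoder, cfg: PretrainConfig) -> PretrainResult:
    """Run the masked-restoration pretext task; fully seeded and deterministic."""
    slides = {s.slide_id: s for s in _resolve_slides(store)}
    if not slides:
        raise ValueError("empty store: nothing to pre-train on")
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    train_ids, monitor_ids = _split_slides(sorted(slides), cfg.train_fraction, rng)
    monitor_every = cfg.monitor_every or max(
        1, math.ceil(len(train_ids) * cfg.regions_per_slide / cfg.batch_size)
    )
    opt = AdamW(
        _param_groups(model, 1.0, "backbone"),
        beta1=cfg.adam_beta1,
        beta2=cfg.adam_beta2,
        weight_decay=cfg.weight_decay,
    )
    records: list[dict] = []
    skipped = 0
    best_state = model.state_dict()
    best_monitor = math.inf

    def monitor_loss(at_step: int) -> float:
        mon_rng = np.random.Generator(np.random.PCG64(cfg.seed + 999))
        batch = _sample_masked_batch(slides, monitor_ids, cfg, mon_rng)
        if batch is None:
            return math.nan
        loss = _pooled_restoration_loss(model, batch[0], batch[1], batch[2], cfg, rng=None)
        return float(loss.data)

    for step in range(1, cfg.total_steps + 1):
        batch = _sample_masked_batch(slides, train_ids, cfg, rng)
        if batch is None:
            skipped += 1
            warnings.warn("skipping degenerate batch with no masked foreground patch", stacklevel=2)
            continue
        loss = _pooled_restoration_loss(model, batch[0], batch[1], batch[2], cfg, rng=rng)
        opt.zero_grad()
        loss.backward()
        lr = lr_at(step, cfg)
        opt.step(lr)
        rec = {"step": step, "lr": lr, "train_loss": float(loss.data), "monitor_loss": math.nan}
        if step % monitor_every == 0 or step == cfg.total_steps:
            m = monitor_loss(step)
            rec["monitor_loss"] = m
            if not math.isnan(m) and m < best_monitor:
                best_monitor = m
                best_state = model.state_dict()
        records.append(rec)
    return PretrainResult(
        model=model,
        history=pd.DataFrame.from_records(records),
        best_state=best_state,
        best_monitor_loss=best_monitor,
        train_slides=train_ids,
        monitor_slides=monitor_ids,
        skipped_batches=skipped,
    )


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without strict improvement.

    ``update`` returns True when training should stop; ``best_epoch`` tracks
    the last strictly-improving epoch.  Larger monitor values are better
    (negate losses before feeding them in).
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = -math.inf
        self.best_epoch = 0
        self.stagnant = 0
        self.epoch = 0

    def update(self, monitor: float) -> bool:
        self.epoch += 1
        if monitor > self.best:
            self.best = monitor
            self.best_epoch = self.epoch
            self.stagnant = 0
            return False
        self.stagnant += 1
        return self.stagnant >= self.patience


class LinearHead(Module):
    """Slide-level linear head over the averaged class token."""

    def __init__(self, d: int, n_out: int, seed: int = 0):
        self.fc = Linear(d, n_out, np.random.Generator(np.random.PCG64(seed)))
        self.n_out = n_out

    def __call__(self, reps: Tensor) -> Tensor:
        return self.fc(reps)


def _apply_coverage(
    region: RegionSample, coverage: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Keep a uniform ``coverage`` fraction of foreground patches.

    The grid shape is preserved; dropped patches become background (zero
    vector, excluded from attention), matching the "coverage" notion of
    sampling a patch subset within each region.
    """
    fg = region.grid.foreground.copy()
    feats = region.grid.features.copy()
    if coverage >= 1.0:
        return feats, fg
    ys, xs = np.nonzero(fg)
    keep = max(1, int(round(coverage * len(ys))))
    sel = rng.choice(len(ys), size=keep, replace=False)
    mask = np.zeros_like(fg)
    mask[ys[sel], xs[sel]] = True
    feats[~mask] = 0.0
    return feats, mask


def _slide_representations(
    model: RegionEncoder,
    slides: dict[str, SlideFeatureSet],
    ids: list[str],
    n: int,
    regions_per_slide: int,
    coverage: float,
    max_overlap: float,
    rng: np.random.Generator,
    train_rng: np.random.Generator | None = None,
) -> tuple[Tensor, list[str]]:
    """Encode sampled regions and average class tokens per slide."""
    feats, fgs, owners, kept = [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # under-filled region warnings are fine here
        for sid in ids:
            try:
                regions = propose_regions(
                    slides[sid], n, regions_per_slide, max_overlap=max_overlap, rng_seed=rng
                )
            except ValueError:
                continue
            for region in regions:
                f, g = _apply_coverage(region, coverage, rng)
                if not g.any():
                    continue
                feats.append(f)
                fgs.append(g)
                owners.append(sid)
            if owners and owners[-1] == sid:
                kept.append(sid)
    if not kept:
        raise ValueError("no slide produced an admissible region")
    class_out, _, _ = model.forward(np.stack(feats), np.stack(fgs), rng=train_rng)
    group = np.zeros((len(kept), len(owners)))
    for j, sid in enumerate(owners):
        group[kept.index(sid), j] = 1.0
    group /= group.sum(axis=1, keepdims=True)
    return Tensor(group) @ class_out, kept


@dataclass
class FinetuneResult:
    model: RegionEncoder
    head: LinearHead
    history: pd.DataFrame  # epoch, train_loss, monitor metric
    best_epoch: int
    best_metric: float
    metrics: dict
    train_slides: list[str]
    val_slides: list[str]
    label_order: list | None = None


def _prepare_labels(labels: pd.DataFrame, task: str) -> pd.DataFrame:
    df = labels.copy()
    df["slide_id"] = df["slide_id"].astype(str)
    if task == "survival":
        need = {"time_years", "event"}
        if not need <= set(df.columns):
            raise ValueError("survival labels need columns time_years and event")
    elif "label" not in df.columns:
        raise ValueError("classification labels need a label column")
    return df.set_index("slide_id")


def finetune(
    store,
    labels: pd.DataFrame,
    model: RegionEncoder,
    cfg: FinetuneConfig,
) -> FinetuneResult:
    """Fit the slide-level head (and gently the backbone) with early stopping.

    The monitor metric is the validation loss for survival and the
    validation macro AUC for classification; training stops once the metric
    fails to improve strictly for ``patience`` consecutive epochs, and the
    best-epoch weights are restored.
    """
    slides = {s.slide_id: s for s in _resolve_slides(store)}
    ldf = _prepare_labels(labels, cfg.task)
    ids = sorted(set(slides) & set(ldf.index))
    if len(ids) < 4:
        raise ValueError("need at least 4 labelled slides to fine-tune")
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    train_ids, val_ids = _split_slides(ids, 1.0 - cfg.val_fraction, rng)

    label_order: list | None = None
    if cfg.task == "survival":
        if int(ldf.loc[train_ids, "event"].sum()) == 0:
            raise ValueError("no events among training slides: Cox loss undefined")
        n_out = 1
    else:
        label_order = sorted(ldf["label"].unique().tolist())
        n_out = len(label_order)
    head = LinearHead(model.d, n_out, seed=cfg.seed + 1)
    opt = AdamW(
        {
            **_param_groups(head, cfg.resolved_head_lr, "head"),
            **_param_groups(model, cfg.backbone_lr, "backbone"),
        },
        weight_decay=cfg.weight_decay,
    )

    def batch_loss(batch_ids: list[str], train_rng) -> tuple[Tensor, int]:
        reps, kept = _slide_representations(
            model,
            slides,
            batch_ids,
            cfg.region_n,
            cfg.regions_per_slide_train,
            cfg.coverage_train,
            cfg.max_overlap,
            rng,
            train_rng=train_rng,
        )
        out = head(reps)
        if cfg.task == "survival":
            sub = ldf.loc[kept]
            if int(sub["event"].sum()) == 0:
                return None, 0
            return cox_loss_t(
                out.reshape(-1), sub["time_years"].to_numpy(), sub["event"].to_numpy()
            ), len(kept)
        y = np.array([label_order.index(v) for v in ldf.loc[kept, "label"]])
        return cross_entropy_t(out, y), len(kept)

    def validation_metric() -> tuple[float, float]:
        """(monitor value with larger=better, raw metric for reporting)."""
        reps, kept = _slide_representations(
            model,
            slides,
            val_ids,
            cfg.region_n,
            cfg.regions_eval,
            cfg.coverage_eval,
            cfg.max_overlap,
            np.random.Generator(np.random.PCG64(cfg.seed + 500)),
        )
        out = head(reps).data
        if cfg.task == "survival":
            sub = ldf.loc[kept]
            from .losses import cox_loss as _cox

            try:
                val = _cox(out[:, 0], sub["time_years"].to_numpy(), sub["event"].to_numpy())
            except ValueError:
                val = math.nan
            return (-val if not math.isnan(val) else -math.inf), val
        y = np.array([label_order.index(v) for v in ldf.loc[kept, "label"]])
        try:
            auc = macro_auc(out, y)
        except ValueError:
            auc = math.nan
        return (auc if not math.isnan(auc) else -math.inf), auc

    records = []
    stopper = EarlyStopper(cfg.patience)
    best_state = (model.state_dict(), head.state_dict())
    for epoch in range(1, cfg.max_epochs + 1):
        order = list(train_ids)
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), cfg.slide_batch):
            chunk = order[start : start + cfg.slide_batch]
            loss, n_used = batch_loss(chunk, train_rng=rng)
            if loss is None or n_used < 2:
                continue
            opt.zero_grad()
            loss.backward()
            opt.step(1.0)  # group lr scales carry the actual rates
            epoch_losses.append(float(loss.data))
        monitor, raw = validation_metric()
        records.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else math.nan,
                "monitor": raw,
            }
        )
        improved = monitor > stopper.best
        stop = stopper.update(monitor)
        if improved:
            best_state = (model.state_dict(), head.state_dict())
        if stop:
            break
    best_metric = stopper.best
    best_epoch = stopper.best_epoch
    model.load_state_dict(best_state[0])
    head.load_state_dict(best_state[1])
    _, best_raw = validation_metric()
    metrics = {"val_cindex" if cfg.task == "survival" else "val_auc": None}
    if cfg.task == "survival":
        reps, kept = _slide_representations(
            model,
            slides,
            val_ids,
            cfg.region_n,
            cfg.regions_eval,
            cfg.coverage_eval,
            cfg.max_overlap,
            np.random.Generator(np.random.PCG64(cfg.seed + 500)),
        )
        sub = ldf.loc[kept]
        metrics["val_cindex"] = concordance_index(
            head(reps).data[:, 0], sub["time_years"].to_numpy(), sub["event"].to_numpy()
        )
        metrics["val_loss"] = best_raw
    else:
        metrics["val_auc"] = best_raw
    return FinetuneResult(
        model=model,
        head=head,
        history=pd.DataFrame.from_records(records),
        best_epoch=best_epoch,
        best_metric=best_metric,
        metrics=metrics,
        train_slides=train_ids,
        val_slides=val_ids,
        label_order=label_order,
    )


def evaluate(
    model: RegionEncoder,
    head: LinearHead,
    store,
    labels: pd.DataFrame,
    schema: tuple[int, float],
    task: str,
    region_n: int,
    max_overlap: float = 0.5,
    seed: int = 0,
    label_order: list | None = None,
) -> dict:
    """Score a fitted model under a (regions, coverage) sampling schema."""
    regions, coverage = schema
    slides = {s.slide_id: s for s in _resolve_slides(store)}
    ldf = _prepare_labels(labels, task)
    ids = sorted(set(slides) & set(ldf.index))
    reps, kept = _slide_representations(
        model,
        slides,
        ids,
        region_n,
        regions,
        coverage,
        max_overlap,
        np.random.Generator(np.random.PCG64(seed)),
    )
    out = head(reps).data
    if task == "survival":
        sub = ldf.loc[kept]
        return {
            "schema": f"{regions}x{int(coverage * 100)}%",
            "n_slides": len(kept),
            "cindex": concordance_index(
                out[:, 0], sub["time_years"].to_numpy(), sub["event"].to_numpy()
            ),
        }
    order = label_order or sorted(ldf["label"].unique().tolist())
    y = np.array([order.index(v) for v in ldf.loc[kept, "label"]])
    return {
        "schema": f"{regions}x{int(coverage * 100)}%",
        "n_slides": len(kept),
        "macro_auc": macro_auc(out, y),
    }
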