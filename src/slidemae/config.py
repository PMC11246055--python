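"""Configuration defaults, seeding, and run records.

A single flat key->value defaults table mirrors every stated
hyperparameter of the full-scale recipe; the "toy" profile differs only in
scale knobs (model width/depth, region side, step counts) so the full
pipeline runs on one CPU in minutes.  Config files are YAML with the same
flat keys; resolution order is defaults < file < explicit overrides, and
unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["DEFAULTS", "RunRecord", "get_rng", "load_config", "set_global_seed", "toy_profile"]

DEFAULTS: dict[str, object] = {
    "seed": 0,
    # model
    "model.d": 512,
    "model.L": 12,
    "model.H": 8,
    "model.n_max": 20,
    "model.dropout": 0.1,
    "model.pos_init_sd": 0.02,
    # region sampling
    "region.n": 20,
    "region.min_foreground": 0.25,
    "region.max_overlap": 0.5,
    # masking
    "mask.p": 0.5,
    # pre-training
    "pretrain.lr_peak": 4e-5,
    "pretrain.warmup_steps": 8000,
    "pretrain.total_steps": 400_000,
    "pretrain.batch_size": 64,
    "pretrain.regions_per_slide": 2,
    "pretrain.train_fraction": 0.8,
    "pretrain.alpha": 2.0,
    "pretrain.beta": 1.0,
    "pretrain.tau": 0.1,
    "pretrain.weight_decay": 0.05,
    # fine-tuning
    "finetune.head_lr_survival": 1e-3,
    "finetune.head_lr_classification": 3e-3,
    "finetune.backbone_lr": 1e-5,
    "finetune.patience": 5,
    "finetune.max_epochs": 30,
    "finetune.regions_per_slide_train": 2,
    "finetune.coverage_train": 1.0,
    "finetune.regions_eval": 2,
    "finetune.coverage_eval": 1.0,
    "finetune.val_fraction": 0.25,
    "finetune.slide_batch": 8,
    # preprocessing
    "preprocess.patch_size_px": 224,
    "preprocess.mask_scale": 32,
    "preprocess.min_tissue_fraction": 0.05,
}

# scale knobs for desk-size runs; everything else inherits the defaults
TOY_OVERRIDES: dict[str, object] = {
    "model.d": 32,
    "model.L": 2,
    "model.H": 4,
    "model.n_max": 8,
    "model.pos_init_sd": 1.0,
    "region.n": 8,
    "pretrain.lr_peak": 3e-3,
    "pretrain.warmup_steps": 50,
    "pretrain.total_steps": 1000,
    "pretrain.batch_size": 8,
}


def toy_profile() -> dict[str, object]:
    cfg = dict(DEFAULTS)
    cfg.update(TOY_OVERRIDES)
    return cfg


def load_config(
    path: str | Path | None = None,
    overrides: dict[str, object] | None = None,
    profile: str = "paper",
) -> dict[str, object]:
    """Resolve a flat config: defaults < profile < file < overrides."""
    if profile == "paper":
        cfg = dict(DEFAULTS)
    elif profile == "toy":
        cfg = toy_profile()
    else:
        raise ValueError(f"unknown profile {profile!r} (choose 'paper' or 'toy')")

    def apply(source: dict, origin: str) -> None:
        for key, value in source.items():
            if key not in cfg:
                valid = ", ".join(sorted(cfg))
                raise KeyError(f"unknown config key {key!r} from {origin}; valid keys: {valid}")
            default = DEFAULTS[key]
            if isinstance(default, bool):
                ok = isinstance(value, bool)
            elif isinstance(default, int):
                ok = isinstance(value, int) and not isinstance(value, bool)
            elif isinstance(default, float):
                ok = isinstance(value, (int, float)) and not isinstance(value, bool)
            else:
                ok = isinstance(value, type(default))
            if not ok:
                raise TypeError(
                    f"config key {key!r}: expected {type(default).__name__}, "
                    f"got {type(value).__name__}"
                )
            cfg[key] = float(value) if isinstance(default, float) else value

    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise TypeError(f"config file {path} must hold a key: value mapping")
        apply(loaded, str(path))
    if overrides:
        apply(overrides, "command line")
    return cfg


def config_hash(cfg: dict[str, object]) -> str:
    """Stable under key reordering."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_GLOBAL_SEED = 0


def set_global_seed(seed: int) -> None:
    """Root seed from which every stochastic component derives its stream."""
    global _GLOBAL_SEED
    if seed < 0:
        raise ValueError("seed must be non-negative")
    _GLOBAL_SEED = int(seed)


def get_rng(component: str) -> np.random.Generator:
    """Named, reproducible stream: same global seed + name -> same stream."""
    digest = hashlib.blake2b(component.encode(), digest_size=4).digest()
    child = int.from_bytes(digest, "little")
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([_GLOBAL_SEED, child])))


def component_seed(component: str) -> int:
    """Derived integer seed below 2^31 for APIs that take plain seeds."""
    digest = hashlib.blake2b(f"{_GLOBAL_SEED}:{component}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class RunRecord:
    """What a CLI run did: config, seed, metrics, artifacts."""

    command: str
    config: dict
    seed: int
    started: float = field(default_factory=time.time)
    finished: float | None = None
    metrics: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def close(self) -> None:
        self.finished = time.time()

    def to_json(self) -> str:
        payload = {
            "command": self.command,
            "config": self.config,
            "config_hash": config_hash(self.config),
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
            "metrics": self.metrics,
            "artifacts": self.artifacts,
        }
        return json.dumps(payload, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, blob: str) -> "RunRecord":
        data = json.loads(blob)
        rec = cls(
            command=data["command"],
            config=data["config"],
            seed=data["seed"],
            started=data["started"],
            finished=data["finished"],
            metrics=data["metrics"],
            artifacts=data["artifacts"],
        )
        return rec

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
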