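"""Run configuration: YAML loading, validation, and manifests.

A run config file has optional sections ``scene``, ``train``, ``model``,
``decode``, ``encoding`` and ``loss``; every key falls back to the
documented dataclass default. Incoherent combinations (expanded
allocation with the focal loss, lr drop after the last epoch, unknown
enum values) are rejected with the offending field named.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .heatmap import ConfigurationError, GaussianEncodingConfig, LossConfig
from .inference import DecodeConfig
from .model import ModelConfig
from .synthetic import SceneConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)

    def as_dict(self) -> dict:
        return {
            "scene": asdict(self.scene),
            "train": asdict(self.train),
            "model": asdict(self.model),
            "decode": asdict(self.decode),
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in section {name!r}: {sorted(unknown)}"
        )
    kwargs = dict(section)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"section {name!r}: {exc}") from exc


def load_run_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run config; missing file means defaults."""
    doc: dict = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
    for section, values in (overrides or {}).items():
        doc.setdefault(section, {}).update(values)

    train_sec = dict(doc.get("train", {}))
    enc = _build(GaussianEncodingConfig, train_sec.pop("encoding", {}), "train.encoding")
    loss = _build(LossConfig, train_sec.pop("loss", {}), "train.loss")
    train_sec["encoding"] = enc
    train_sec["loss"] = loss

    known_sections = {"scene", "train", "model", "decode"}
    unknown = set(doc) - known_sections
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")

    model_sec = dict(doc.get("model", {}))
    train_cfg = _build(TrainConfig, train_sec, "train")
    # the neck variant is owned by the training recipe unless set explicitly
    model_sec.setdefault("variant", train_cfg.neck_variant)
    cfg = RunConfig(
        scene=_build(SceneConfig, doc.get("scene", {}), "scene"),
        train=train_cfg,
        model=_build(ModelConfig, model_sec, "model"),
        decode=_build(DecodeConfig, doc.get("decode", {}), "decode"),
    )
    if cfg.model.variant != cfg.train.neck_variant:
        raise ConfigurationError(
            "model.variant and train.neck_variant disagree: "
            f"{cfg.model.variant!r} vs {cfg.train.neck_variant!r}"
        )
    return cfg


def write_manifest(path: str | Path, cfg: RunConfig, seed: int, extra: dict | None = None) -> None:
    """Record everything needed to reproduce a run."""
    from . import __version__

    doc = {
        "config": cfg.as_dict(),
        "config_hash": cfg.config_hash(),
        "seed": seed,
        "package_version": __version__,
    }
    doc.update(extra or {})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
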