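"""Run configuration: one YAML document that makes a run reproducible.

Every pipeline stage reads its parameters from a :class:`RunConfig`; the
resolved config (defaults filled in) is echoed beside each stage's
outputs, so any artifact directory is reproducible from its own contents.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from .augment import AugmentSpec
from .model_train import TrainConfig
from .segment import SegmentConfig
from .synthgen import IntensitySpec, SceneSpec, ShiftSpec

__all__ = ["DataConfig", "EvalConfig", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class DataConfig:
    """How many scenes to generate and at what class imbalance."""

    n_scenes: int = 10
    imbalance_ratio: float = 1.0  # tumor:non-tumor; pre-training emulation uses ~0.296


@dataclass(frozen=True)
class EvalConfig:
    n_train_values: tuple[int, ...] = (2, 5, 10, 20)
    n_replicates: int = 100
    conditions: tuple[str, ...] = ("transfer", "scratch", "pretrain_only")
    alpha: float = 0.05
    holm_correction: bool = False


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    scene: SceneSpec = field(default_factory=SceneSpec)
    clinical_shift: ShiftSpec = field(default_factory=ShiftSpec)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    augment_multiplier: int = 1
    pretrain_data: DataConfig = field(default_factory=DataConfig)
    clinical_data: DataConfig = field(default_factory=DataConfig)
    pretrain: TrainConfig = field(default_factory=TrainConfig)
    finetune: TrainConfig = field(
        default_factory=lambda: TrainConfig(epochs=50, sampling_mode="all_data")
    )
    eval: EvalConfig = field(default_factory=EvalConfig)

    def clinical_scene(self) -> SceneSpec:
        """The scene spec rendered in the clinical domain with the run's shift."""
        return replace(self.scene, domain="clinical", shift=self.clinical_shift)


def _to_plain(obj):
    """Recursively convert dataclass output to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _tuples(seq: Sequence | None):
    return None if seq is None else tuple(seq)


def _scene_from(d: dict) -> SceneSpec:
    d = dict(d)
    for key in ("blue_intensity", "red_intensity", "green_intensity"):
        if key in d and isinstance(d[key], (list, tuple)):
            d[key] = IntensitySpec(*d[key])
        elif key in d and isinstance(d[key], dict):
            d[key] = IntensitySpec(**d[key])
    if "shift" in d and isinstance(d["shift"], dict):
        d["shift"] = ShiftSpec(**d["shift"])
    return SceneSpec(**d)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    out: dict = {"seed": int(d.get("seed", 0)),
                 "augment_multiplier": int(d.get("augment_multiplier", 1))}
    if "scene" in d:
        out["scene"] = _scene_from(d["scene"])
    if "clinical_shift" in d:
        out["clinical_shift"] = ShiftSpec(**d["clinical_shift"])
    if "segment" in d:
        seg = dict(d["segment"])
        if "weights" in seg:
            seg["weights"] = tuple(seg["weights"])
        out["segment"] = SegmentConfig(**seg)
    if "augment" in d:
        aug = dict(d["augment"])
        for key in ("scale_range", "contrast_range"):
            if key in aug:
                aug[key] = tuple(aug[key])
        out["augment"] = AugmentSpec(**aug)
    for key in ("pretrain_data", "clinical_data"):
        if key in d:
            out[key] = DataConfig(**d[key])
    for key in ("pretrain", "finetune"):
        if key in d:
            out[key] = TrainConfig(**d[key])
    if "eval" in d:
        ev = dict(d["eval"])
        for key in ("n_train_values", "conditions"):
            if key in ev:
                ev[key] = tuple(ev[key])
        out["eval"] = EvalConfig(**ev)
    return RunConfig(**out)


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(asdict(cfg))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    try:
        return config_from_dict(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config {path}: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
    return path
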