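"""The fixed synthetic transfer-learning benchmark.

A desk-scale re-creation of the study design: pre-train on abundant
cell-line-like crops, then measure — over a grid of tiny clinical
training-set sizes and many split-train-test replicates — how transfer
learning compares with training from scratch and with using the
pre-trained model untouched.

The domain shift between the cell-line and clinical-like populations is
fixed: clinical cells are 30% larger (radius_scale 1.3), 30% dimmer
(intensity_scale 0.7), and their images noisier (extra_noise 10 on the
8-bit scale).  These knobs move absolute cell size and contrast — the
cues a classifier trained only on cell lines keys on — while leaving the
class structure intact, which is exactly the failure mode transfer
learning is meant to repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .augment import AugmentSpec
from .evaluate import CurveResult, match_classes, run_curve
from .model_train import CnnModel, TrainConfig, build_model, pretrain
from .synthgen import LabeledCrop, SceneSpec, ShiftSpec, generate_dataset

__all__ = ["BenchmarkSpec", "build_benchmark_pools", "run_transfer_benchmark"]

BENCHMARK_SHIFT = ShiftSpec(radius_scale=1.3, intensity_scale=0.7, extra_noise=10.0)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Sizes and settings of the fixed benchmark.

    Defaults: 800 crops per class for pre-training (25 epochs, balanced
    minibatches), a clinical pool of ~210 per class so the held-out test
    side keeps ~200 per class at the largest n_train, 20 replicates per
    cell over n_train in {2, 5, 10, 20}.
    """

    pretrain_per_class: int = 800
    clinical_per_class: int = 210
    n_train_values: tuple[int, ...] = (2, 5, 10, 20)
    n_replicates: int = 20
    pretrain_epochs: int = 25
    finetune_epochs: int = 50
    shift: ShiftSpec = BENCHMARK_SHIFT
    scene: SceneSpec = field(default_factory=SceneSpec)
    augment_multiplier: int = 2
    alpha: float = 0.05


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def build_benchmark_pools(
    spec: BenchmarkSpec, master_seed: int
) -> tuple[list[LabeledCrop], list[LabeledCrop]]:
    """(cell-line crops, class-matched clinical pool) for the benchmark."""
    ss_cell, ss_clin, ss_match = np.random.SeedSequence([master_seed, 101]).spawn(3)

    per_scene = spec.scene.n_tumor + spec.scene.n_leukocyte

    def pool(per_class: int, template: SceneSpec, seed: int) -> list[LabeledCrop]:
        # 15% scene head-room for placement omissions and segmentation misses
        n_scenes = int(np.ceil(2.3 * per_class / per_scene)) + 1
        crops = generate_dataset(replace(template, seed=seed), n_scenes, imbalance_ratio=1.0)
        pos = [c for c in crops if c.label == 1][:per_class]
        neg = [c for c in crops if c.label == 0][:per_class]
        if len(pos) < per_class or len(neg) < per_class:
            raise RuntimeError(
                f"benchmark pool underfilled: {len(pos)}/{len(neg)} of {per_class}"
            )
        return pos + neg

    cellline = pool(spec.pretrain_per_class, spec.scene, _derive_seed(ss_cell))
    clinical_template = replace(spec.scene, domain="clinical", shift=spec.shift)
    clinical = pool(spec.clinical_per_class, clinical_template, _derive_seed(ss_clin))
    pos = [c for c in clinical if c.label == 1]
    neg = [c for c in clinical if c.label == 0]
    return cellline, match_classes(pos, neg, seed=_derive_seed(ss_match))


def run_transfer_benchmark(
    master_seed: int,
    spec: BenchmarkSpec | None = None,
    conditions: tuple[str, ...] = ("transfer", "scratch", "pretrain_only"),
) -> tuple[CurveResult, CnnModel]:
    """Run the full benchmark; returns the accuracy curve and the pre-trained model."""
    spec = spec or BenchmarkSpec()
    cellline, clinical_pool = build_benchmark_pools(spec, master_seed)

    model_seed = _derive_seed(np.random.SeedSequence([master_seed, 202]))
    pre_cfg = TrainConfig(
        epochs=spec.pretrain_epochs,
        sampling_mode="balanced_minibatch",
        seed=model_seed,
    )
    side = cellline[0].crop.side
    model = build_model((1, side, side), seed=model_seed)
    pretrained = pretrain(model, cellline, pre_cfg)

    ft_cfg = TrainConfig(
        epochs=spec.finetune_epochs, sampling_mode="all_data", seed=model_seed
    )
    aug = AugmentSpec(
        rotation_range=360.0, flip_h=True, flip_v=True, translate_max=2,
        seed=_derive_seed(np.random.SeedSequence([master_seed, 303])),
    )
    curve = run_curve(
        clinical_pool,
        n_train_values=spec.n_train_values,
        conditions=conditions,
        n_replicates=spec.n_replicates,
        master_seed=master_seed,
        pretrained=pretrained,
        train_config=ft_cfg,
        augment_spec=aug,
        augment_multiplier=spec.augment_multiplier,
        alpha=spec.alpha,
    )
    return curve, pretrained
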