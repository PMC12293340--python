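"""Repeated-sampling evaluation of transfer learning with scarce labels.

The protocol mirrors how a scarce-label classifier is honestly assessed:
the clinical pool is first class-matched (equal positives and negatives,
negatives subsampled at random), then for each training-set size n a
replicate draws a stratified train split, trains under one of three
conditions — ``transfer`` (fine-tune a pre-trained model), ``scratch``
(train from random initialization on the same split), ``pretrain_only``
(no clinical training at all) — and measures accuracy on the held-out
remainder.  One hundred replicates per cell by default; condition pairs
are compared per n with Welch's unequal-variance t-test (two-sided,
alpha 0.05, no multiplicity correction by default, optional Holm).

Train/test disjointness is enforced on provenance ids *including
augmentation ancestors*: an augmented copy of a test image can never sit
in a training split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AugmentSpec, augment_dataset
from .model_train import (
    CnnModel,
    TrainConfig,
    accuracy,
    build_model,
    examples_to_arrays,
    fine_tune,
    predict,
)
from .synthgen import LabeledCrop

__all__ = [
    "SplitSpec",
    "TrialResult",
    "WelchResult",
    "CurveResult",
    "LeakageError",
    "match_classes",
    "run_replicate",
    "run_curve",
    "welch_t_test",
    "min_n_significant",
    "audit_disjoint",
    "report",
]

Condition = Literal["transfer", "scratch", "pretrain_only"]
CONDITIONS: tuple[Condition, ...] = ("transfer", "scratch", "pretrain_only")


class LeakageError(AssertionError):
    """A provenance id appeared on both sides of a train/test split."""


@dataclass(frozen=True)
class SplitSpec:
    """One replicate's split: n_train examples for training, rest for test."""

    n_train: int
    seed: int

    def validate(self, n_pos: int, n_neg: int) -> None:
        if self.n_train < 0:
            raise ValueError("n_train must be >= 0")
        n_pos_train, n_neg_train = stratified_counts(self.n_train)
        if n_pos_train >= n_pos or n_neg_train >= n_neg:
            raise ValueError(
                f"split n_train={self.n_train} infeasible for pool "
                f"({n_pos} positives, {n_neg} negatives): test side would lose a class"
            )


def stratified_counts(n_train: int) -> tuple[int, int]:
    """(positives, negatives) in a stratified train split of size n_train.

    Even n splits half-and-half; an odd n gives the extra example to the
    positive (tumor) class — the scarce class the protocol is about.
    """
    return math.ceil(n_train / 2), n_train // 2


@dataclass(frozen=True)
class TrialResult:
    condition: Condition
    n_train: int
    replicate: int
    accuracy: float
    n_test: int


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance t-test between two accuracy samples."""

    t: float
    df: float
    p: float
    alpha: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class CurveResult:
    """Accuracy distributions per (condition, n_train) plus comparisons."""

    accuracies: dict[str, dict[int, list[float]]]
    n_replicates: int
    alpha: float = 0.05
    tests: dict[tuple[str, str, int], WelchResult] = field(default_factory=dict)

    @property
    def n_train_values(self) -> list[int]:
        ns = {n for cond in self.accuracies.values() for n in cond}
        return sorted(ns)

    def mean(self, condition: str, n_train: int) -> float:
        return float(np.mean(self.accuracies[condition][n_train]))

    def minimum(self, condition: str, n_train: int) -> float:
        return float(np.min(self.accuracies[condition][n_train]))

    def welch(self, cond_a: str, cond_b: str, n_train: int) -> WelchResult:
        key = (cond_a, cond_b, n_train)
        if key not in self.tests:
            self.tests[key] = welch_t_test(
                self.accuracies[cond_a][n_train],
                self.accuracies[cond_b][n_train],
                alpha=self.alpha,
            )
        return self.tests[key]

    def validate(self) -> None:
        for cond, per_n in self.accuracies.items():
            for n, accs in per_n.items():
                arr = np.asarray(accs)
                if arr.size and (arr.min() < 0 or arr.max() > 1):
                    raise ValueError(f"accuracy outside [0,1] at ({cond}, {n})")


# ---------------------------------------------------------------------------


def match_classes(positives: Sequence[LabeledCrop], negatives: Sequence[LabeledCrop],
                  seed: int) -> list[LabeledCrop]:
    """Class-matched pool: all positives plus an equal random negative subsample.

    This is the imbalance guard of the protocol: with 201 identified CTCs
    and many more non-CTCs, 201 negatives are drawn so accuracy is not
    inflated by the majority class.
    """
    if len(negatives) < len(positives):
        raise ValueError(
            f"negatives ({len(negatives)}) fewer than positives ({len(positives)})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    if len(negatives) == len(positives):
        chosen = list(negatives)
    else:
        idx = rng.choice(len(negatives), size=len(positives), replace=False)
        chosen = [negatives[i] for i in sorted(idx)]
    return list(positives) + chosen


def audit_disjoint(train: Sequence[LabeledCrop], test: Sequence[LabeledCrop]) -> None:
    """Raise :class:`LeakageError` if any ancestor id crosses the split."""
    train_ids = {lc.ancestor_uid for lc in train}
    test_ids = {lc.ancestor_uid for lc in test}
    common = train_ids & test_ids
    if common:
        raise LeakageError(f"train/test leakage via ids: {sorted(common)[:5]}")


def _split(pool: Sequence[LabeledCrop], spec: SplitSpec) -> tuple[list[LabeledCrop], list[LabeledCrop]]:
    pos = [lc for lc in pool if lc.label == 1]
    neg = [lc for lc in pool if lc.label == 0]
    spec.validate(len(pos), len(neg))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed]))
    n_pos, n_neg = stratified_counts(spec.n_train)
    pos_idx = rng.permutation(len(pos))
    neg_idx = rng.permutation(len(neg))
    train = [pos[i] for i in pos_idx[:n_pos]] + [neg[i] for i in neg_idx[:n_neg]]
    test = [pos[i] for i in pos_idx[n_pos:]] + [neg[i] for i in neg_idx[n_neg:]]
    return train, test


def run_replicate(
    pool: Sequence[LabeledCrop],
    spec: SplitSpec,
    condition: Condition,
    pretrained: CnnModel | None = None,
    train_config: TrainConfig | None = None,
    augment_spec: AugmentSpec | None = None,
    augment_multiplier: int = 1,
    replicate: int = 0,
    model: CnnModel | None = None,
) -> TrialResult:
    """One full pass: split, train per condition, score on held-out test.

    Augmentation (if any) is applied to the training side only, after the
    split, and the ancestor-id audit runs on every replicate.  ``model``
    supplies a stand-in classifier for plumbing tests; it skips training.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition in ("transfer", "pretrain_only") and pretrained is None and model is None:
        raise ValueError(f"condition {condition!r} requires a pretrained model")
    cfg = train_config or TrainConfig()
    train, test = _split(pool, spec)
    if not test:
        raise ValueError("empty test side")
    if augment_spec is not None and augment_multiplier > 1 and condition != "pretrain_only":
        train = augment_dataset(train, augment_spec, augment_multiplier)
    audit_disjoint(train, test)

    if model is not None:
        trained = model
    elif condition == "transfer":
        trained = fine_tune(pretrained, train, cfg)
    elif condition == "pretrain_only":
        trained = pretrained
    else:  # scratch
        fresh = build_model((1 if cfg.input_mode == "composite" else 3,
                             train[0].crop.side if train else 32,
                             train[0].crop.side if train else 32),
                            seed=spec.seed)
        trained = fine_tune(fresh, train, cfg)

    x_test, y_test = examples_to_arrays(test, cfg.input_mode)
    labels, _ = predict(trained, x_test)
    return TrialResult(condition, spec.n_train, replicate,
                       accuracy(labels, y_test), len(test))


def replicate_seed(master_seed: int, condition: str, n_train: int, replicate: int) -> int:
    """Stable per-cell seed so any replicate is reproducible in isolation."""
    cond_idx = CONDITIONS.index(condition)  # type: ignore[arg-type]
    ss = np.random.SeedSequence([master_seed, cond_idx, n_train, replicate])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_curve(
    pool: Sequence[LabeledCrop],
    n_train_values: Sequence[int],
    conditions: Sequence[Condition] = ("transfer", "scratch"),
    n_replicates: int = 100,
    master_seed: int = 0,
    pretrained: CnnModel | None = None,
    train_config: TrainConfig | None = None,
    augment_spec: AugmentSpec | None = None,
    augment_multiplier: int = 1,
    alpha: float = 0.05,
    model: CnnModel | None = None,
) -> CurveResult:
    """Accuracy distributions over a grid of training-set sizes.

    For every (condition, n_train) cell, ``n_replicates`` independent
    split-train-test replicates are run; pairwise Welch tests between the
    requested conditions are attached per n_train.
    """
    ns = list(n_train_values)
    if ns != sorted(ns):
        raise ValueError("n_train_values must be sorted ascending")
    accs: dict[str, dict[int, list[float]]] = {c: {n: [] for n in ns} for c in conditions}
    for cond in conditions:
        for n in ns:
            for rep in range(n_replicates):
                spec = SplitSpec(n_train=n, seed=replicate_seed(master_seed, cond, n, rep))
                trial = run_replicate(
                    pool, spec, cond, pretrained=pretrained,
                    train_config=train_config, augment_spec=augment_spec,
                    augment_multiplier=augment_multiplier, replicate=rep,
                    model=model,
                )
                accs[cond][n].append(trial.accuracy)
    curve = CurveResult(accuracies=accs, n_replicates=n_replicates, alpha=alpha)
    for i, a in enumerate(conditions):
        for b in conditions[i + 1 :]:
            for n in ns:
                curve.welch(a, b, n)
    curve.validate()
    return curve


# ---------------------------------------------------------------------------


def welch_t_test(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    t = (x̄ − ȳ) / sqrt(sx²/nx + sy²/ny), with Welch–Satterthwaite degrees
    of freedom.  When both sample variances vanish: equal means give
    t = 0, p = 1; unequal means are reported as a degenerate infinite-t
    result with p = 0 (df set to nx + ny − 2 by convention).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dmean = x.mean() - y.mean()
    if vx == 0.0 and vy == 0.0:
        if dmean == 0.0:
            return WelchResult(t=0.0, df=float(nx + ny - 2), p=1.0, alpha=alpha)
        return WelchResult(
            t=math.copysign(math.inf, dmean), df=float(nx + ny - 2), p=0.0,
            alpha=alpha, degenerate=True,
        )
    se2 = vx / nx + vy / ny
    t = dmean / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=min(1.0, p), alpha=alpha)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj.tolist()


def min_n_significant(
    curve: CurveResult,
    baseline_condition: str = "pretrain_only",
    comparison_condition: str = "transfer",
    alpha: float = 0.05,
) -> int | None:
    """Smallest n_train whose comparison arm significantly beats the baseline.

    Scans n ascending; requires both a higher mean and Welch p < alpha.
    Returns None when no n qualifies.
    """
    for n in curve.n_train_values:
        if (
            n in curve.accuracies.get(comparison_condition, {})
            and n in curve.accuracies.get(baseline_condition, {})
        ):
            res = curve.welch(comparison_condition, baseline_condition, n)
            if curve.mean(comparison_condition, n) > curve.mean(baseline_condition, n) and res.p < alpha:
                return n
    return None


# ---------------------------------------------------------------------------


def curve_to_tidy(curve: CurveResult) -> pd.DataFrame:
    rows = [
        {"condition": cond, "n_train": n, "replicate": i, "accuracy": a}
        for cond, per_n in curve.accuracies.items()
        for n, accs in per_n.items()
        for i, a in enumerate(accs)
    ]
    return pd.DataFrame(rows, columns=["condition", "n_train", "replicate", "accuracy"])


def curve_to_summary(curve: CurveResult) -> pd.DataFrame:
    conds = list(curve.accuracies)
    rows = []
    for cond, per_n in curve.accuracies.items():
        others = [c for c in conds if c != cond]
        for n, accs in per_n.items():
            row = {
                "condition": cond,
                "n_train": n,
                "mean_accuracy": float(np.mean(accs)),
                "min_accuracy": float(np.min(accs)),
                "n_replicates": len(accs),
            }
            for other in others:
                if n in curve.accuracies[other]:
                    res = curve.welch(cond, other, n)
                    row[f"t_vs_{other}"] = res.t
                    row[f"df_vs_{other}"] = res.df
                    row[f"p_vs_{other}"] = res.p
                    row[f"significant_vs_{other}"] = res.significant
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["condition", "n_train"]).reset_index(drop=True)


def report(curve: CurveResult, out_dir: str | Path, make_plot: bool = True) -> dict[str, Path]:
    """Write tidy + summary CSV (and an accuracy-vs-n plot) for a curve.

    An empty curve raises before anything is written, so a failed run
    leaves no partial files behind.
    """
    if not curve.accuracies or all(
        not accs for per_n in curve.accuracies.values() for accs in per_n.values()
    ):
        raise ValueError("empty curve: nothing to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tidy = curve_to_tidy(curve)
    paths["tidy"] = out / "trials.csv"
    tidy.to_csv(paths["tidy"], index=False)
    summary = curve_to_summary(curve)
    paths["summary"] = out / "summary.csv"
    summary.to_csv(paths["summary"], index=False)
    if make_plot:
        paths["plot"] = out / "accuracy_vs_n_train.png"
        _plot_curve(curve, paths["plot"])
    return paths


def _plot_curve(curve: CurveResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, per_n in curve.accuracies.items():
        ns = sorted(per_n)
        means = [float(np.mean(per_n[n])) for n in ns]
        mins = [float(np.min(per_n[n])) for n in ns]
        ax.plot(ns, means, marker="o", label=f"{cond} (mean)")
        ax.plot(ns, mins, marker=".", linestyle="--", alpha=0.5, label=f"{cond} (min)")
    ax.set_xlabel("clinical training images (n_train)")
    ax.set_ylabel("classification accuracy")
    ax.set_ylim(0.0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
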