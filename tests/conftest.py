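"""Shared fixtures: small, seeded synthetic inputs.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import ctcvision as cv


@pytest.fixture(scope="session")
def sparse_spec() -> cv.SceneSpec:
    """Well-separated, high-SNR scene: 20 cells, spacing >= 3 nucleus radii.

    Nucleus SNR = (blue mean − background) / noise sd = 190/5 = 38.
    """
    return cv.SceneSpec(
        width=384,
        height=384,
        n_tumor=10,
        n_leukocyte=10,
        min_spacing_factor=1.5,  # distance >= 1.5*(r1+r2) = 3 radii for equal radii
        seed=11,
    )


@pytest.fixture(scope="session")
def separable_spec() -> cv.SceneSpec:
    """Strong class contrast and low noise: classes nearly separable."""
    return cv.SceneSpec(
        n_tumor=20,
        n_leukocyte=20,
        red_intensity=cv.IntensitySpec(230.0, 5.0),
        green_intensity=cv.IntensitySpec(60.0, 5.0),
        leukocyte_radius_factor=0.55,
        nucleus_radius_sd=0.5,
        noise_sd=2.0,
        seed=29,
    )


@pytest.fixture(scope="session")
def separable_crops(separable_spec) -> list[cv.LabeledCrop]:
    return cv.generate_dataset(separable_spec, n_scenes=8, imbalance_ratio=1.0)


@pytest.fixture(scope="session")
def default_crops() -> list[cv.LabeledCrop]:
    """A modest labeled pool at generator defaults (both classes)."""
    return cv.generate_dataset(cv.SceneSpec(seed=5), n_scenes=6, imbalance_ratio=1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_labeled(n_pos: int, n_neg: int, side: int = 8, seed: int = 0) -> list[cv.LabeledCrop]:
    """Tiny synthetic labeled crops for protocol plumbing tests.

    Class 1 crops get a checkerboard blue channel (normalized composite
    std 0.5), class 0 a smooth ramp (std ~0.29), so the texture StubModel
    separates them exactly; mostly they exercise ids, splits and
    bookkeeping.  ``seed`` only varies a small additive jitter.
    """
    rng = np.random.default_rng(seed)
    checker = (np.indices((side, side)).sum(axis=0) % 2) * 255
    ramp = np.tile(np.linspace(0, 255, side), (side, 1))
    zeros = np.zeros((side, side), np.uint8)
    out = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        base = checker if label else ramp
        blue = np.clip(base + rng.integers(0, 4, (side, side)), 0, 255).astype(np.uint8)
        crop = cv.CellCrop(
            blue=blue, red=zeros.copy(), green=zeros.copy(),
            centroid=(side / 2, side / 2), bbox=(0, 0, side, side),
        )
        crop.composite = cv.compose_brightness(crop)
        uid = f"stub{i:04d}"
        out.append(cv.LabeledCrop(crop=crop, label=label, uid=uid, ancestor_uid=uid))
    return out


class StubModel:
    """Training-free stand-in classifier for protocol plumbing tests.

    ``perfect`` separates make_labeled crops by composite texture;
    ``random`` flips a fair coin per example; ``flipped`` inverts perfect.
    """

    def __init__(self, mode: str = "perfect", seed: int = 0):
        self.mode = mode
        self.rng = np.random.default_rng(seed)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        n = len(x)
        if self.mode == "random":
            p = self.rng.random(n)
            return np.stack([1 - p, p], axis=1)
        p1 = (x.reshape(n, -1).std(axis=1) > 0.4).astype(float)
        if self.mode == "flipped":
            p1 = 1.0 - p1
        return np.stack([1 - p1, p1], axis=1)
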