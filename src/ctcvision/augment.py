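"""Stochastic augmentation of training crops.

Applied to training splits only — never to test data; the evaluation
protocol audits this through crop provenance.  Transforms are applied in
a fixed order (rotate → flip → scale → translate → brightness/contrast),
each drawing one parameter per crop from a seeded stream, so an augmented
crop is reproducible from (source crop, spec, draw index).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segment import CellCrop, compose_brightness
from .synthgen import LabeledCrop

__all__ = ["AugmentSpec", "augment_crop", "augment_dataset"]


@dataclass(frozen=True)
class AugmentSpec:
    """Parameters of the augmentation stack; the default is the identity.

    rotation_range: degrees, angle drawn uniformly in [0, rotation_range].
    flip_h / flip_v: each applied with probability 0.5 when enabled.
    scale_range: multiplicative zoom interval.
    brightness_delta: additive intensity shift drawn in ±brightness_delta.
    contrast_range: multiplicative contrast about the patch mean.
    translate_max: integer pixel translation drawn in ±translate_max
    ("minor" translations; default cap 3 px).
    """

    rotation_range: float = 0.0
    flip_h: bool = False
    flip_v: bool = False
    scale_range: tuple[float, float] = (1.0, 1.0)
    brightness_delta: float = 0.0
    contrast_range: tuple[float, float] = (1.0, 1.0)
    translate_max: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.rotation_range <= 360.0):
            raise ValueError("rotation_range must be in [0, 360]")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi):
            raise ValueError("scale_range must be a positive interval")
        clo, chi = self.contrast_range
        if not (0.0 < clo <= chi):
            raise ValueError("contrast_range must be a positive interval")
        if self.brightness_delta < 0 or self.translate_max < 0:
            raise ValueError("brightness_delta and translate_max must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_range == 0.0
            and not self.flip_h
            and not self.flip_v
            and self.scale_range == (1.0, 1.0)
            and self.brightness_delta == 0.0
            and self.contrast_range == (1.0, 1.0)
        )


def _rotate(img: np.ndarray, angle: float) -> np.ndarray:
    if angle % 90.0 == 0.0:
        # right-angle rotations are pure pixel permutations — keep them exact
        return np.rot90(img, k=int(angle // 90) % 4)
    return ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)

def _scale(img: np.ndarray, factor: float) -> np.ndarray:
    if factor == 1.0:
        return img
    side = img.shape[0]
    zoomed = ndimage.zoom(img, factor, order=1, mode="constant", cval=0.0)
    out = np.zeros_like(img)
    zs = zoomed.shape[0]
    if zs >= side:  # center-crop
        o = (zs - side) // 2
        out[:, :] = zoomed[o : o + side, o : o + side]
    else:  # center-pad
        o = (side - zs) // 2
        out[o : o + zs, o : o + zs] = zoomed
    return out

def _translate(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    if dx == 0 and dy == 0:
        return img
    out = np.zeros_like(img)
    h, w = img.shape
    sx0, dx0 = (0, dx) if dx >= 0 else (-dx, 0)
    sy0, dy0 = (0, dy) if dy >= 0 else (-dy, 0)
    ww, hh = w - abs(dx), h - abs(dy)
    if ww > 0 and hh > 0:
        out[dy0 : dy0 + hh, dx0 : dx0 + ww] = img[sy0 : sy0 + hh, sx0 : sx0 + ww]
    return out


def augment_crop(crop: CellCrop, spec: AugmentSpec, draw_index: int = 0) -> CellCrop:
    """One augmented copy of ``crop``; identity spec returns an equal crop.

    All three channels receive the same geometric transform (the stains
    are registered) and the same photometric adjustment; the brightness
    composite is recomputed with the crop's own weights.
    """
    spec.validate()
    if spec.is_identity:
        return dataclasses.replace(
            crop,
            blue=crop.blue.copy(),
            red=crop.red.copy(),
            green=crop.green.copy(),
            composite=None if crop.composite is None else crop.composite.copy(),
        )

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, draw_index]))
    angle = rng.uniform(0.0, spec.rotation_range) if spec.rotation_range > 0 else 0.0
    do_fh = spec.flip_h and rng.random() < 0.5
    do_fv = spec.flip_v and rng.random() < 0.5
    factor = (
        rng.uniform(*spec.scale_range) if spec.scale_range != (1.0, 1.0) else 1.0
    )
    dx = int(rng.integers(-spec.translate_max, spec.translate_max + 1)) if spec.translate_max else 0
    dy = int(rng.integers(-spec.translate_max, spec.translate_max + 1)) if spec.translate_max else 0
    delta = rng.uniform(-spec.brightness_delta, spec.brightness_delta) if spec.brightness_delta else 0.0
    contrast = (
        rng.uniform(*spec.contrast_range) if spec.contrast_range != (1.0, 1.0) else 1.0
    )

    def transform(channel: np.ndarray) -> np.ndarray:
        img = channel.astype(np.float64)
        if angle:
            img = _rotate(img, angle)
        if do_fh:
            img = img[:, ::-1]
        if do_fv:
            img = img[::-1, :]
        img = _scale(img, factor)
        img = _translate(img, dx, dy)
        if contrast != 1.0:
            m = img.mean()
            img = m + contrast * (img - m)
        if delta:
            img = img + delta
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    out = dataclasses.replace(
        crop,
        blue=transform(crop.blue),
        red=transform(crop.red),
        green=transform(crop.green),
    )
    out.composite = compose_brightness(out, out.weights)
    return out


def augment_dataset(
    crops: list[LabeledCrop], spec: AugmentSpec, multiplier: int = 1
) -> list[LabeledCrop]:
    """Expand a labeled crop collection by ``multiplier``.

    For each source crop the first copy is the original; the remaining
    multiplier−1 copies are augmentation draws.  Labels are inherited and
    each copy records its source through ``ancestor_uid``, so augmented
    descendants can never leak across a train/test split unnoticed.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    out: list[LabeledCrop] = []
    for i, lc in enumerate(crops):
        out.append(lc)
        for k in range(1, multiplier):
            draw = i * max(multiplier, 1) + k
            aug = augment_crop(lc.crop, spec, draw_index=draw)
            out.append(
                LabeledCrop(
                    crop=aug,
                    label=lc.label,
                    uid=f"{lc.uid}#aug{k}",
                    ancestor_uid=lc.ancestor_uid,
                )
            )
    return out
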