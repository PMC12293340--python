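"""Nucleus-guided segmentation of tri-channel fluorescence scenes.

The localization signal is the Hoechst (blue) channel: Otsu's method
extracts nucleus-positive pixels, connected components give cell
positions, and fixed-size windows are cut *at the same location* from all
three channels, so the cytokeratin (red) and CD45 (green) content of each
cell travels with its nucleus.  The three patches are then combined into
a single brightness composite, which is the default classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .synthgen import MultichannelImage

__all__ = [
    "BinaryMask",
    "Region",
    "CellCrop",
    "SegmentConfig",
    "otsu_threshold",
    "find_cell_positions",
    "extract_crop",
    "compose_brightness",
    "segment_scene",
]


@dataclass
class BinaryMask:
    """Foreground mask plus the scalar Otsu threshold that produced it.

    ``degenerate`` marks a constant input image, for which between-class
    variance is zero everywhere; the mask is then empty by convention.
    """

    mask: np.ndarray
    threshold: int
    degenerate: bool = False


@dataclass(frozen=True)
class Region:
    """One connected nucleus component."""

    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    area: int
    touches_border: bool


@dataclass
class CellCrop:
    """Fixed-size tri-channel patch centered on a detected nucleus."""

    blue: np.ndarray
    red: np.ndarray
    green: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    scene_id: str = "scene"
    touches_border: bool = False
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    composite: np.ndarray | None = None

    @property
    def side(self) -> int:
        return self.blue.shape[0]

    def channel_stack(self) -> np.ndarray:
        """(3, side, side) float32 stack scaled to [0, 1]."""
        return (
            np.stack([self.blue, self.red, self.green]).astype(np.float32) / 255.0
        )


@dataclass(frozen=True)
class SegmentConfig:
    """Tunable segmentation parameters.

    ``crop_side`` is the classifier patch size at the synthetic scale.
    The area gate drops debris (below) and clumps (above).  Composite
    weights default to an equal blend of the three stains.
    """

    crop_side: int = 32
    min_area: int = 20
    max_area: int = 2000
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)


def otsu_threshold(channel: np.ndarray) -> BinaryMask:
    """Otsu's threshold on the 256-bin histogram of an 8-bit channel.

    Selects the threshold t maximizing the between-class variance
    w0(t)·w1(t)·(mu0(t) − mu1(t))², where class 0 holds pixels ≤ t and
    class 1 pixels > t; the foreground mask is ``pixel > t``.  Ties are
    broken toward the lower threshold.  A constant image yields an empty
    mask with ``degenerate=True`` rather than an error.
    """
    arr = np.asarray(channel)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("values outside [0, 255]")
    arr = arr.astype(np.uint8) if arr.dtype != np.uint8 else arr

    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    omega0 = np.cumsum(hist) / total          # P(v <= t), t = 0..255
    mu_cum = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
    var_between = omega0 * omega1 * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=0.0)

    if np.all(var_between == 0.0):  # constant image
        t = int(arr.flat[0])
        return BinaryMask(np.zeros(arr.shape, dtype=bool), t, degenerate=True)
    t = int(np.argmax(var_between))  # argmax returns the first (lowest) maximizer
    return BinaryMask(arr > t, t)


def find_cell_positions(
    mask: BinaryMask, min_area: int = 20, max_area: int = 2000
) -> list[Region]:
    """Connected components (8-connectivity) of the nucleus mask.

    Components are filtered by area, sorted by centroid (y, x); components
    touching the image border are kept but flagged so downstream code can
    treat their zero-padded crops specially.
    """
    labeled = measure.label(mask.mask, connectivity=2)
    h, w = mask.mask.shape
    regions: list[Region] = []
    for props in measure.regionprops(labeled):
        if not (min_area <= props.area <= max_area):
            continue
        cy, cx = props.centroid
        y0, x0, y1, x1 = props.bbox
        touches = x0 == 0 or y0 == 0 or x1 == w or y1 == h
        regions.append(
            Region(
                centroid=(float(cx), float(cy)),
                bbox=(int(x0), int(y0), int(x1), int(y1)),
                area=int(props.area),
                touches_border=touches,
            )
        )
    regions.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return regions


def _cut(channel: np.ndarray, x0: int, y0: int, side: int) -> np.ndarray:
    """Cut a side×side window at (x0, y0), zero-padding past the borders."""
    h, w = channel.shape
    out = np.zeros((side, side), dtype=channel.dtype)
    sx0, sy0 = max(0, x0), max(0, y0)
    sx1, sy1 = min(w, x0 + side), min(h, y0 + side)
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = channel[sy0:sy1, sx0:sx1]
    return out


def extract_crop(
    image: MultichannelImage,
    region: Region,
    crop_side: int = 32,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    scene_id: str = "scene",
) -> CellCrop:
    """Cut the same fixed-size window from all three channels.

    The window is centered on the rounded component centroid; windows that
    extend past the image border are zero-padded.  The brightness
    composite is attached immediately.
    """
    cx, cy = region.centroid
    h, w = image.shape
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"centroid {region.centroid} outside image {w}x{h}")
    x0 = int(round(cx)) - crop_side // 2
    y0 = int(round(cy)) - crop_side // 2
    crop = CellCrop(
        blue=_cut(image.blue, x0, y0, crop_side),
        red=_cut(image.red, x0, y0, crop_side),
        green=_cut(image.green, x0, y0, crop_side),
        centroid=region.centroid,
        bbox=(x0, y0, x0 + crop_side, y0 + crop_side),
        scene_id=scene_id,
        touches_border=region.touches_border,
        weights=weights,
    )
    crop.composite = compose_brightness(crop, weights)
    return crop


def compose_brightness(
    crop: CellCrop,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    normalize: bool = True,
) -> np.ndarray:
    """Combine the three stain patches into one brightness image.

    composite = clip(w_b·blue + w_r·red + w_g·green, 0, 255), then min-max
    normalized to [0, 1].  A constant composite (e.g. an all-zero crop)
    maps to all zeros instead of dividing by zero.
    """
    wb, wr, wg = weights
    if wb < 0 or wr < 0 or wg < 0 or wb + wr + wg <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    comp = (
        wb * crop.blue.astype(np.float64)
        + wr * crop.red.astype(np.float64)
        + wg * crop.green.astype(np.float64)
    )
    comp = np.clip(comp, 0.0, 255.0)
    if not normalize:
        return comp.astype(np.float32)
    lo, hi = comp.min(), comp.max()
    if hi <= lo:
        return np.zeros_like(comp, dtype=np.float32)
    return ((comp - lo) / (hi - lo)).astype(np.float32)


def segment_scene(
    image: MultichannelImage,
    config: SegmentConfig | None = None,
    scene_id: str = "scene",
) -> list[CellCrop]:
    """Full localization pipeline: Otsu → components → tri-channel crops."""
    cfg = config or SegmentConfig()
    mask = otsu_threshold(image.blue)
    if mask.degenerate:
        return []
    regions = find_cell_positions(mask, cfg.min_area, cfg.max_area)
    return [
        extract_crop(image, r, cfg.crop_side, cfg.weights, scene_id=scene_id)
        for r in regions
    ]
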