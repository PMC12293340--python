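"""Seeded synthetic fluorescence scenes with per-cell ground truth.

Emulates the tri-channel staining phenotype used to identify circulating
tumor cells (CTCs) on antibody-capture chips: every cell has a
Hoechst-stained nucleus (blue), tumor cells additionally express
cytokeratin in the cytoplasm (red), and leukocytes express the CD45
surface antigen (green).  A CTC therefore renders blue+red, a leukocyte
blue+green.

Two populations can be generated: ``cellline`` (the homogeneous cultured
cells used for pre-training) and ``clinical`` (patient-derived cells),
with the clinical distribution obtained from the cell-line one through an
explicit, parameterized domain shift (:class:`ShiftSpec`).  The identity
shift makes the two distributions equal by construction.

All randomness flows from one master seed per :class:`SceneSpec`, split
into independent substreams for cell placement, per-cell intensities and
pixel noise, so a scene is bit-reproducible and stays comparable when a
single knob changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "IntensitySpec",
    "ShiftSpec",
    "SceneSpec",
    "CellRecord",
    "GroundTruth",
    "MultichannelImage",
    "generate_scene",
    "generate_dataset",
    "LabeledCrop",
]

# Placement constants: rejection sampling with a bounded retry budget and a
# minimum center spacing relative to the two nucleus radii.
MAX_PLACEMENT_RETRIES = 100
MIN_SPACING_FACTOR = 0.8


@dataclass(frozen=True)
class IntensitySpec:
    """Per-class mean/sd of a fluorescence channel on the 8-bit scale."""

    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if not (0.0 <= self.mean <= 255.0):
            raise ValueError(f"{name} mean {self.mean} outside [0, 255]")
        if self.sd < 0:
            raise ValueError(f"{name} sd must be >= 0")


@dataclass(frozen=True)
class ShiftSpec:
    """Domain shift applied when rendering the clinical population.

    The identity shift (all scales 1, additives 0) leaves the clinical
    distribution equal to the cell-line distribution.  ``radius_scale``
    multiplies nucleus radii, ``intensity_scale`` multiplies stain
    intensities, ``shape_irregularity`` bounds the ellipse eccentricity
    drawn per cell, and ``extra_noise`` adds to the Gaussian pixel noise
    standard deviation.
    """

    radius_scale: float = 1.0
    intensity_scale: float = 1.0
    shape_irregularity: float = 0.0
    extra_noise: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (
            self.radius_scale == 1.0
            and self.intensity_scale == 1.0
            and self.shape_irregularity == 0.0
            and self.extra_noise == 0.0
        )

    def validate(self) -> None:
        if self.radius_scale <= 0 or self.intensity_scale < 0:
            raise ValueError("shift scales must be positive")
        if not (0.0 <= self.shape_irregularity <= 1.0):
            raise ValueError("shape_irregularity must be in [0, 1]")
        if self.extra_noise < 0:
            raise ValueError("extra_noise must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    Defaults model a typical chip field at low magnification: bright
    Hoechst nuclei (SNR ~38 over background), cytokeratin slightly dimmer
    than the nuclear stain, CD45 dimmer still, and leukocytes smaller than
    tumor cells (``leukocyte_radius_factor``), as they are in blood.
    """

    width: int = 256
    height: int = 256
    n_tumor: int = 20
    n_leukocyte: int = 20
    nucleus_radius_mean: float = 7.0
    nucleus_radius_sd: float = 1.0
    leukocyte_radius_factor: float = 0.7
    blue_intensity: IntensitySpec = field(default_factory=lambda: IntensitySpec(200.0, 20.0))
    red_intensity: IntensitySpec = field(default_factory=lambda: IntensitySpec(200.0, 15.0))
    green_intensity: IntensitySpec = field(default_factory=lambda: IntensitySpec(120.0, 15.0))
    cytoplasm_ring_width: float = 3.0
    min_spacing_factor: float = MIN_SPACING_FACTOR  # center distance >= factor*(r1+r2)
    background_level: float = 10.0
    noise_sd: float = 5.0
    illumination_gradient: float = 0.0
    domain: Literal["cellline", "clinical"] = "cellline"
    shift: ShiftSpec = field(default_factory=ShiftSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.n_tumor < 0 or self.n_leukocyte < 0:
            raise ValueError("cell counts must be >= 0")
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd < 0:
            raise ValueError("nucleus radius parameters invalid")
        if not (0.0 < self.leukocyte_radius_factor <= 2.0):
            raise ValueError("leukocyte_radius_factor out of range")
        self.blue_intensity.validate("blue_intensity")
        self.red_intensity.validate("red_intensity")
        self.green_intensity.validate("green_intensity")
        if self.cytoplasm_ring_width < 0:
            raise ValueError("cytoplasm_ring_width must be >= 0")
        if self.min_spacing_factor <= 0:
            raise ValueError("min_spacing_factor must be > 0")
        if not (0.0 <= self.background_level <= 255.0):
            raise ValueError("background_level outside [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.illumination_gradient <= 1.0):
            raise ValueError("illumination_gradient must be in [0, 1]")
        if self.domain not in ("cellline", "clinical"):
            raise ValueError(f"unknown domain {self.domain!r}")
        self.shift.validate()


@dataclass(frozen=True)
class CellRecord:
    """Ground-truth record for one cell (rendered or omitted)."""

    cell_id: int
    x: float
    y: float
    radius: float
    label: Literal["tumor", "leukocyte"]
    omitted: bool = False


@dataclass
class GroundTruth:
    """Per-cell ground truth of one scene."""

    cells: list[CellRecord]
    scene_id: str = "scene"

    @property
    def rendered(self) -> list[CellRecord]:
        return [c for c in self.cells if not c.omitted]

    @property
    def omitted(self) -> list[CellRecord]:
        return [c for c in self.cells if c.omitted]

    def __len__(self) -> int:
        return len(self.rendered)


@dataclass
class MultichannelImage:
    """Three registered 8-bit rasters: blue (Hoechst), red (CK), green (CD45)."""

    blue: np.ndarray
    red: np.ndarray
    green: np.ndarray

    def __post_init__(self) -> None:
        if not (self.blue.shape == self.red.shape == self.green.shape):
            raise ValueError("channels must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape

    def channels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.blue, self.red, self.green


def _effective_params(spec: SceneSpec) -> tuple[float, float, float, float]:
    """(radius multiplier, intensity multiplier, eccentricity bound, noise sd)."""
    if spec.domain == "clinical":
        s = spec.shift
        return (s.radius_scale, s.intensity_scale, s.shape_irregularity,
                spec.noise_sd + s.extra_noise)
    return 1.0, 1.0, 0.0, spec.noise_sd


def _place_cells(spec: SceneSpec, rng: np.random.Generator,
                 radius_mult: float, ecc_bound: float) -> list[dict]:
    """Rejection-sample non-overlapping cell geometries.

    Cells that cannot be placed within the retry budget are returned with
    ``omitted=True`` so the caller can report them, never silently drop them.
    """
    cells: list[dict] = []
    labels = ["tumor"] * spec.n_tumor + ["leukocyte"] * spec.n_leukocyte
    for cid, label in enumerate(labels):
        base = spec.nucleus_radius_mean
        if label == "leukocyte":
            base *= spec.leukocyte_radius_factor
        radius = max(1.5, rng.normal(base, spec.nucleus_radius_sd)) * radius_mult
        ecc = rng.uniform(0.0, ecc_bound) if ecc_bound > 0 else 0.0
        theta = rng.uniform(0.0, math.pi)
        margin = radius * (1.0 + ecc) + spec.cytoplasm_ring_width + 1.0
        placed = False
        x = y = 0.0
        if spec.width > 2 * margin and spec.height > 2 * margin:
            for _ in range(MAX_PLACEMENT_RETRIES):
                x = rng.uniform(margin, spec.width - margin)
                y = rng.uniform(margin, spec.height - margin)
                ok = all(
                    math.hypot(x - c["x"], y - c["y"])
                    >= spec.min_spacing_factor * (radius + c["radius"])
                    for c in cells
                    if not c["omitted"]
                )
                if ok:
                    placed = True
                    break
        cells.append(
            dict(cell_id=cid, x=x, y=y, radius=radius, label=label,
                 ecc=ecc, theta=theta, omitted=not placed)
        )
    return cells


def _ellipse_mask(shape: tuple[int, int], x: float, y: float,
                  ra: float, rb: float, theta: float) -> tuple[slice, slice, np.ndarray]:
    """Boolean mask of a rotated ellipse, restricted to its bounding window."""
    h, w = shape
    rmax = max(ra, rb)
    x0, x1 = max(0, int(x - rmax - 1)), min(w, int(x + rmax + 2))
    y0, y1 = max(0, int(y - rmax - 1)), min(h, int(y + rmax + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    u = (dx * math.cos(theta) + dy * math.sin(theta)) / ra
    v = (-dx * math.sin(theta) + dy * math.cos(theta)) / rb
    return slice(y0, y1), slice(x0, x1), (u * u + v * v) <= 1.0


def generate_scene(spec: SceneSpec, scene_id: str = "scene") -> tuple[MultichannelImage, GroundTruth]:
    """Render one scene and its ground truth.

    Deterministic given ``spec`` (including its seed).  Tumor cells paint
    blue nucleus + red cytoplasm (nucleus footprint extended by the
    cytoplasm ring); leukocytes paint blue nucleus + green CD45 over the
    cell footprint.  Additive Gaussian noise, clipped to the 8-bit range,
    is applied last; an optional linear illumination gradient attenuates
    signal (not noise) left to right.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    place_rng, inten_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    radius_mult, inten_mult, ecc_bound, noise_sd = _effective_params(spec)
    cells = _place_cells(spec, place_rng, radius_mult, ecc_bound)

    shape = (spec.height, spec.width)
    blue = np.full(shape, float(spec.background_level), dtype=np.float64)
    red = np.full(shape, float(spec.background_level), dtype=np.float64)
    green = np.full(shape, float(spec.background_level), dtype=np.float64)

    for c in cells:
        # intensity draws happen for every cell, placed or not, so the
        # intensity stream stays aligned with the placement stream
        b_val = inten_rng.normal(spec.blue_intensity.mean, spec.blue_intensity.sd)
        s_val = inten_rng.normal(
            *(
                (spec.red_intensity.mean, spec.red_intensity.sd)
                if c["label"] == "tumor"
                else (spec.green_intensity.mean, spec.green_intensity.sd)
            )
        )
        if c["omitted"]:
            continue
        b_val = float(np.clip(b_val * inten_mult, 0.0, 255.0))
        s_val = float(np.clip(s_val * inten_mult, 0.0, 255.0))
        r = c["radius"]
        ra, rb = r * (1.0 + c["ecc"]), r / (1.0 + c["ecc"])
        ys, xs, nucleus = _ellipse_mask(shape, c["x"], c["y"], ra, rb, c["theta"])
        sub = blue[ys, xs]
        sub[nucleus] = np.maximum(sub[nucleus], b_val)
        ring = spec.cytoplasm_ring_width
        ys2, xs2, cell_fp = _ellipse_mask(shape, c["x"], c["y"], ra + ring, rb + ring, c["theta"])
        target = red if c["label"] == "tumor" else green
        sub = target[ys2, xs2]
        sub[cell_fp] = np.maximum(sub[cell_fp], s_val)

    if spec.illumination_gradient > 0:
        ramp = 1.0 - spec.illumination_gradient * (
            np.arange(spec.width, dtype=np.float64) / max(1, spec.width - 1)
        )
        for ch in (blue, red, green):
            ch *= ramp[np.newaxis, :]

    out = []
    for ch in (blue, red, green):
        noisy = ch + noise_rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else ch
        out.append(np.clip(np.rint(noisy), 0, 255).astype(np.uint8))

    truth = GroundTruth(
        cells=[
            CellRecord(c["cell_id"], c["x"], c["y"], c["radius"], c["label"], c["omitted"])
            for c in cells
        ],
        scene_id=scene_id,
    )
    return MultichannelImage(*out), truth


# ---------------------------------------------------------------------------
# Labeled crop datasets


@dataclass
class LabeledCrop:
    """A segmented cell crop with its ground-truth class and provenance.

    ``uid`` identifies the crop; ``ancestor_uid`` points at the original
    (pre-augmentation) crop and equals ``uid`` for originals.  The leakage
    audit in the evaluation protocol is keyed on ``ancestor_uid``.
    """

    crop: "object"  # segment.CellCrop; kept loose to avoid a circular import
    label: int  # 1 = tumor, 0 = leukocyte/non-tumor
    uid: str
    ancestor_uid: str


def generate_dataset(
    spec_template: SceneSpec,
    n_scenes: int,
    imbalance_ratio: float,
    segment_config: "object | None" = None,
    match_radius_factor: float = 1.0,
) -> list[LabeledCrop]:
    """Generate scenes, segment them, and label crops from the ground truth.

    ``imbalance_ratio`` is tumor:leukocyte (the pre-training condition in
    the source system was ~9106:30785 ≈ 0.296).  The per-scene total cell
    count of ``spec_template`` is kept and re-partitioned to approximate
    the ratio.  Crops are labeled by nearest ground-truth centroid within
    ``match_radius_factor`` × radius; unmatched crops are discarded.
    """
    from . import segment as _segment

    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    if imbalance_ratio <= 0:
        raise ValueError("imbalance_ratio must be > 0")
    total = spec_template.n_tumor + spec_template.n_leukocyte
    n_tum = int(round(total * imbalance_ratio / (1.0 + imbalance_ratio)))
    n_leu = total - n_tum
    if total > 0 and (n_tum == 0 or n_leu == 0):
        raise ValueError(
            f"imbalance_ratio {imbalance_ratio} unattainable with "
            f"{total} cells per scene"
        )
    cfg = segment_config if segment_config is not None else _segment.SegmentConfig()

    crops: list[LabeledCrop] = []
    child_seeds = np.random.SeedSequence(spec_template.seed).spawn(n_scenes)
    for i, child in enumerate(child_seeds):
        seed_i = int(child.generate_state(1, dtype=np.uint32)[0])
        spec = replace(spec_template, n_tumor=n_tum, n_leukocyte=n_leu, seed=seed_i)
        scene_id = f"scene{i:04d}"
        image, truth = generate_scene(spec, scene_id=scene_id)
        for j, crop in enumerate(_segment.segment_scene(image, cfg, scene_id=scene_id)):
            rec = _match_truth(crop.centroid, truth, match_radius_factor)
            if rec is None:
                continue
            uid = f"{scene_id}/crop{j:04d}"
            crops.append(
                LabeledCrop(
                    crop=crop,
                    label=1 if rec.label == "tumor" else 0,
                    uid=uid,
                    ancestor_uid=uid,
                )
            )
    return _trim_to_ratio(crops, imbalance_ratio)


def _trim_to_ratio(crops: list[LabeledCrop], ratio: float) -> list[LabeledCrop]:
    """Drop trailing crops of the overrepresented class to hit the ratio.

    Segmentation recovers the two classes at slightly different rates
    (small leukocytes merge into neighboring components more often), so
    the placed ratio drifts; trimming restores the requested ratio without
    touching crop content.  Deterministic: always drops from the end.
    """
    n_tum = sum(1 for c in crops if c.label == 1)
    n_non = len(crops) - n_tum
    if n_tum == 0 or n_non == 0:
        return crops
    want_tum = min(n_tum, int(round(n_non * ratio)))
    want_non = min(n_non, int(round(n_tum / ratio)))
    kept, seen_tum, seen_non = [], 0, 0
    for c in crops:
        if c.label == 1:
            if seen_tum >= want_tum:
                continue
            seen_tum += 1
        else:
            if seen_non >= want_non:
                continue
            seen_non += 1
        kept.append(c)
    return kept


def _match_truth(centroid: tuple[float, float], truth: GroundTruth,
                 radius_factor: float) -> CellRecord | None:
    """Nearest rendered truth cell within radius_factor×radius, or None."""
    cx, cy = centroid
    best, best_d = None, np.inf
    for rec in truth.rendered:
        d = math.hypot(cx - rec.x, cy - rec.y)
        if d < best_d:
            best, best_d = rec, d
    if best is not None and best_d <= radius_factor * best.radius:
        return best
    return None


def class_counts(crops: Sequence[LabeledCrop]) -> tuple[int, int]:
    """(n_tumor, n_non_tumor) of a labeled crop collection."""
    n_tum = sum(1 for c in crops if c.label == 1)
    return n_tum, len(crops) - n_tum
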