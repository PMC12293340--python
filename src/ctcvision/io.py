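"""File formats: scenes (PNG/TIFF), truth and results CSV, model checkpoints.

Round-trip fidelity is a contract: writing then reading a scene
reproduces the 8-bit channels bit-exactly, CSV tables conserve rows, and
a checkpoint restores a model that predicts identically.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .model_train import CnnModel
from .synthgen import CellRecord, GroundTruth, MultichannelImage

__all__ = [
    "write_scene",
    "read_scene",
    "write_truth",
    "read_truth",
    "write_results",
    "read_results",
    "save_model",
    "load_model",
]

_SUFFIXES = ("_b", "_r", "_g")  # blue, red, green single-channel PNGs


def write_scene(image: MultichannelImage, path: str | Path, fmt: str = "tiff") -> list[Path]:
    """Write a scene as one 3-page TIFF or three suffixed PNGs."""
    path = Path(path)
    if fmt == "tiff":
        out = path if path.suffix else path.with_suffix(".tiff")
        tifffile.imwrite(out, np.stack(image.channels()), photometric="minisblack")
        return [out]
    if fmt == "png":
        stem = path.with_suffix("")
        paths = []
        for suffix, channel in zip(_SUFFIXES, image.channels()):
            p = stem.parent / f"{stem.name}{suffix}.png"
            iio.imwrite(p, channel)
            paths.append(p)
        return paths
    raise ValueError(f"unknown scene format {fmt!r}")


def read_scene(path: str | Path) -> MultichannelImage:
    """Read a scene written by :func:`write_scene` (TIFF stack or PNG trio)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError(f"{path}: expected a 3-page TIFF, got shape {stack.shape}")
        return MultichannelImage(*(np.asarray(p, dtype=np.uint8) for p in stack))
    stem = path.with_suffix("")
    name = stem.name
    for suffix in _SUFFIXES:  # accept any of the three files as the anchor
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    channels = []
    for suffix in _SUFFIXES:
        p = stem.parent / f"{name}{suffix}.png"
        if not p.exists():
            raise FileNotFoundError(f"missing channel file {p}")
        channels.append(np.asarray(iio.imread(p), dtype=np.uint8))
    return MultichannelImage(*channels)


_TRUTH_COLUMNS = ["scene_id", "cell_id", "x", "y", "radius", "class", "omitted"]


def write_truth(truths: GroundTruth | list[GroundTruth], path: str | Path) -> Path:
    if isinstance(truths, GroundTruth):
        truths = [truths]
    rows = [
        {
            "scene_id": t.scene_id,
            "cell_id": c.cell_id,
            "x": c.x,
            "y": c.y,
            "radius": c.radius,
            "class": c.label,
            "omitted": c.omitted,
        }
        for t in truths
        for c in t.cells
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, index=False)
    return path


def read_truth(path: str | Path, width: int | None = None,
               height: int | None = None) -> list[GroundTruth]:
    """Read ground truth CSV; validates centroid bounds when dims are given."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    truths: dict[str, GroundTruth] = {}
    for i, row in df.iterrows():
        line = i + 2  # header + 1-based
        if not bool(row["omitted"]) and width is not None and height is not None:
            if not (0 <= row["x"] < width and 0 <= row["y"] < height):
                raise ValueError(
                    f"{path}:{line}: centroid ({row['x']}, {row['y']}) outside {width}x{height}"
                )
        if row["class"] not in ("tumor", "leukocyte"):
            raise ValueError(f"{path}:{line}: unknown class {row['class']!r}")
        rec = CellRecord(
            cell_id=int(row["cell_id"]), x=float(row["x"]), y=float(row["y"]),
            radius=float(row["radius"]), label=row["class"],
            omitted=bool(row["omitted"]),
        )
        sid = row["scene_id"]
        truths.setdefault(sid, GroundTruth([], scene_id=sid)).cells.append(rec)
    return list(truths.values())


def write_results(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path)
    except Exception as exc:  # surface the offending file
        raise ValueError(f"malformed results file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Model checkpoints: NPZ weights + YAML architecture sidecar


def save_model(model: CnnModel, path_prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    npz_path = prefix.with_suffix(".npz")
    yaml_path = prefix.with_suffix(".yaml")
    weights = model.get_weights()
    np.savez(npz_path, **{f"w{i}": w for i, w in enumerate(weights)})
    meta = {
        "input_shape": list(model.input_shape),
        "arch": model.arch,
        "seed": model.seed,
        "history": model.history,
        "n_weights": len(weights),
    }
    yaml_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return npz_path, yaml_path


def load_model(path_prefix: str | Path) -> CnnModel:
    prefix = Path(path_prefix)
    yaml_path = prefix.with_suffix(".yaml")
    npz_path = prefix.with_suffix(".npz")
    if not yaml_path.exists() or not npz_path.exists():
        raise FileNotFoundError(f"missing checkpoint files {npz_path} / {yaml_path}")
    meta = yaml.safe_load(yaml_path.read_text())
    model = CnnModel(tuple(meta["input_shape"]), meta["arch"], seed=meta["seed"])
    model.history = meta.get("history", [])
    with np.load(npz_path) as data:
        weights = [data[f"w{i}"] for i in range(meta["n_weights"])]
    model.set_weights(weights)
    return model
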