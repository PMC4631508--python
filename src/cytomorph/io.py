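"""File formats: TIFF movies, seed-point CSVs, trace CSVs, YAML configs.

Axis conventions for all TIFF I/O: page = Z, row = Y, column = X; a movie
is either one file per time point (``frame_0000.tif`` ...) or a single
4-D stack with a leading T axis.  TIFF does not standardize 4-D layout or
physical spacing, so every movie directory carries a YAML sidecar
(``movie_meta.yaml``) recording the axis order, voxel spacing and all
generation parameters.
"""

from __future__ import annotations

import dataclasses
import glob
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import LabelVolume, SeedVolume
from .trace import TRACE_COLUMNS, GeometryTrace

__all__ = [
    "write_movie",
    "read_movie",
    "write_labels",
    "read_labels",
    "write_sidecar",
    "read_sidecar",
    "read_seed_csv",
    "write_trace_csv",
    "read_trace_csv",
]

SIDECAR_NAME = "movie_meta.yaml"


def write_movie(movie: np.ndarray, outdir, prefix: str = "frame",
                dtype=np.float32) -> list[Path]:
    """Write a (T, Z, Y, X) movie as one ZYX multi-page TIFF per frame."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in range(movie.shape[0]):
        p = outdir / f"{prefix}_{f:04d}.tif"
        tifffile.imwrite(p, np.asarray(movie[f], dtype=dtype))
        paths.append(p)
    return paths


def read_movie(path) -> np.ndarray:
    """Read a movie from a directory of per-frame TIFFs or one 4-D TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(glob.glob(str(path / "*.tif"))) + \
            sorted(glob.glob(str(path / "*.tiff")))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        frames = []
        for f in files:
            try:
                frames.append(tifffile.imread(f))
            except Exception as e:
                raise ValueError(f"corrupt or unreadable TIFF {f}: {e}") from e
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {shapes}")
        return np.stack(frames)
    try:
        arr = tifffile.imread(path)
    except Exception as e:
        raise ValueError(f"corrupt or unreadable TIFF {path}: {e}") from e
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise ValueError(f"expected a 3-D or 4-D TIFF, got shape {arr.shape}")
    return arr


def write_labels(labels: list[LabelVolume], outdir,
                 prefix: str = "labels") -> list[Path]:
    """Write a label movie as 16-bit per-frame TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for lv in labels:
        if lv.labels.max() > np.iinfo(np.uint16).max:
            raise ValueError("label ids exceed 16-bit range")
        p = outdir / f"{prefix}_{lv.frame_index:04d}.tif"
        tifffile.imwrite(p, lv.labels.astype(np.uint16))
        paths.append(p)
    return paths


def read_labels(outdir, spacing, prefix: str = "labels",
                background_label: int = 1) -> list[LabelVolume]:
    files = sorted(glob.glob(str(Path(outdir) / f"{prefix}_*.tif")))
    if not files:
        raise FileNotFoundError(f"no label TIFFs under {outdir}")
    out = []
    for f in files:
        frame = int(Path(f).stem.rsplit("_", 1)[1])
        out.append(LabelVolume(tifffile.imread(f).astype(np.int32), spacing,
                               frame_index=frame,
                               background_label=background_label))
    return out


def write_sidecar(outdir, spacing, extra: dict | None = None) -> Path:
    """Write the movie metadata sidecar (axis order, spacing, parameters)."""
    meta = {
        "axis_order": "TZYX (page=Z, row=Y, column=X)",
        "voxel_spacing_um_zyx": [float(s) for s in spacing],
        "coordinate_origin": "0-based voxel indices",
    }
    if extra:
        meta.update(_plain(extra))
    p = Path(outdir) / SIDECAR_NAME
    with open(p, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return p


def read_sidecar(outdir) -> dict:
    with open(Path(outdir) / SIDECAR_NAME) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert dataclasses/arrays/tuples to YAML-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_seed_csv(path, shape, background_label: int = 1,
                  frame: int = 0) -> SeedVolume:
    """Build frame-0 seeds from a CSV of seed points.

    Columns: ``frame, label, z, y, x`` (0-based voxel indices).  Every
    listed voxel of a label becomes seed; one point per Z-layer per label
    suffices.  The background seed may be given as points, or omitted, in
    which case the whole volume border becomes the background seed.
    """
    df = pd.read_csv(path)
    required = {"frame", "label", "z", "y", "x"}
    if not required.issubset(df.columns):
        raise ValueError(f"seed CSV must have columns {sorted(required)}")
    df = df[df["frame"] == frame]
    seeds = np.zeros(shape, dtype=np.int32)
    for _, row in df.iterrows():
        z, y, x = int(row["z"]), int(row["y"]), int(row["x"])
        if not (0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]):
            raise ValueError(f"seed point {(z, y, x)} outside volume {shape}")
        seeds[z, y, x] = int(row["label"])
    if background_label not in np.unique(seeds):
        border = np.zeros(shape, dtype=bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            for idx in (0, -1):
                sl[ax] = idx
                border[tuple(sl)] = True
        seeds[border & (seeds == 0)] = background_label
    return SeedVolume(seeds, background_label=background_label)


def write_trace_csv(trace_or_df, path) -> Path:
    """Write a trace (or ground-truth table) with the canonical schema."""
    df = (trace_or_df.data if isinstance(trace_or_df, GeometryTrace)
          else trace_or_df)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns {missing}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path, frame_interval: float = 60.0,
                   genotype_tag: str = "") -> list[GeometryTrace]:
    """Read a trace CSV into one :class:`GeometryTrace` per cell id."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for cid, sub in df.groupby("cell_id"):
        sub = sub.sort_values("frame").reset_index(drop=True)
        times = sub["frame"].to_numpy(dtype=float) * frame_interval
        out.append(GeometryTrace(int(cid), times, sub, genotype_tag))
    return out
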