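"""Reading and writing stacks, sidecar metadata and result tables.

Stacks are stored as multi-page TIFF in CZYX plane order, 16-bit container
holding the 12-bit data, with a JSON sidecar (same stem, ``.json``) carrying
channel order, voxel spacing and bit depth. All tables are UTF-8 CSV with
stable column order and deterministic row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack

SIDECAR_SCHEMA = "vesiq-stack-1"
SIDECAR_KEYS = ("channel_names", "voxel_size_zyx_um", "bit_depth")


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(stack.voxels, dtype=np.uint16))
    meta = {
        "schema": SIDECAR_SCHEMA,
        "stack_id": stack.stack_id or path.stem,
        "channel_names": list(stack.channel_names),
        "voxel_size_zyx_um": list(stack.voxel_size_zyx),
        "bit_depth": stack.bit_depth,
        "shape_czyx": list(stack.voxels.shape),
        "plane_order": "CZYX",
    }
    with open(sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    Raises with an explicit list of expected metadata keys when the sidecar
    is missing or incomplete — voxel spacing is never silently assumed.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar {side}; expected a JSON file with keys {SIDECAR_KEYS}"
        )
    with open(side, encoding="utf-8") as fh:
        meta = json.load(fh)
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar {side} is missing keys {missing}; expected {SIDECAR_KEYS}")
    voxels = tifffile.imread(path)
    n_chan = len(meta["channel_names"])
    if voxels.ndim == 3:  # pages flattened: (c*z, y, x)
        if voxels.shape[0] % n_chan:
            raise ValueError(
                f"{voxels.shape[0]} pages are not divisible by {n_chan} channels in {path}"
            )
        voxels = voxels.reshape(n_chan, -1, *voxels.shape[1:])
    if voxels.ndim != 4 or voxels.shape[0] != n_chan:
        raise ValueError(f"inconsistent stack shape {voxels.shape} for {n_chan} channels")
    return ImageStack(
        voxels=voxels,
        voxel_size_zyx=tuple(meta["voxel_size_zyx_um"]),
        channel_names=tuple(meta["channel_names"]),
        bit_depth=int(meta["bit_depth"]),
        stack_id=str(meta.get("stack_id", path.stem)),
    )


def write_table(frame: pd.DataFrame, path, sort_by=None) -> Path:
    """Write a DataFrame as deterministic CSV (UTF-8, stable row order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if sort_by:
        frame = frame.sort_values(list(sort_by), kind="mergesort").reset_index(drop=True)
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def write_tables(named_frames: dict, out_dir) -> list[Path]:
    """Write ``{name: frame}`` as ``<out_dir>/<name>.csv``."""
    out_dir = Path(out_dir)
    return [write_table(frame, out_dir / f"{name}.csv") for name, frame in named_frames.items()]
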