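"""TIFF / CSV / JSON input-output with pixel-size and timing metadata.

Images and stacks travel as TIFF with a JSON ImageDescription tag
carrying ``pixel_um`` and (for stacks) ``frame_interval`` plus its
unit; traces and curves travel as CSV; ground truth and fit results as
sidecar JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["write_stack", "read_stack", "write_paths_csv", "read_paths_csv"]


def write_stack(
    path: str | Path,
    data: np.ndarray,
    pixel_um: float,
    frame_interval: float | None = None,
    frame_interval_unit: str = "min",
) -> None:
    """Write an image or stack as TIFF with metadata in the description tag."""
    meta = {"pixel_um": pixel_um}
    if frame_interval is not None:
        meta["frame_interval"] = frame_interval
        meta["frame_interval_unit"] = frame_interval_unit
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32), description=json.dumps(meta))


def read_stack(
    path: str | Path, metadata_overrides: dict | None = None
) -> tuple[np.ndarray, dict]:
    """Read a TIFF image/stack and resolve its metadata.

    Metadata precedence: ``metadata_overrides`` > file description tag.
    Raises with the name of the missing field if ``pixel_um`` cannot be
    resolved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:
        raise ValueError(f"unreadable TIFF file {path}: {exc}") from exc
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    if metadata_overrides:
        meta.update(metadata_overrides)
    if "pixel_um" not in meta:
        raise ValueError(f"missing metadata field 'pixel_um' for {path}; pass an override")
    return np.asarray(data, dtype=float), meta


def write_paths_csv(path: str | Path, filament_paths) -> None:
    """One row per point: path_id, point_index, x_um, y_um (plus a summary)."""
    rows = []
    for pid, fp in enumerate(filament_paths):
        for j, (x, y) in enumerate(fp.points):
            rows.append({"path_id": pid, "point_index": j, "x_um": x, "y_um": y,
                         "pixel_um": fp.pixel_um, "source_id": fp.source_id})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_paths_csv(path: str | Path):
    """Inverse of :func:`write_paths_csv`."""
    from .tracing import FilamentPath

    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("path_id"):
        grp = grp.sort_values("point_index")
        out.append(
            FilamentPath(
                points=grp[["x_um", "y_um"]].to_numpy(),
                pixel_um=float(grp["pixel_um"].iloc[0]),
                source_id=str(grp["source_id"].iloc[0]),
            )
        )
    return out
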