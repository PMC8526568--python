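"""File I/O: TIFF stacks with JSON sidecar manifests, masks, CSV tables.

Stacks are written as multi-page 32-bit float TIFF in frame-major order
(page = frame × channel, channel fastest) with a JSON sidecar documenting
the channel order, frame interval and any seed/config metadata.  Masks go
out as 0/255 uint8 TIFF; per-frame correlation series, per-cell summaries
and coupling maps as CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .coevolution.dca import CouplingMap
from .stack import CHANNEL_ROLES, MaskStack, RawStack
from .stats import CellCorrelationRecord

__all__ = [
    "write_stack",
    "read_stack",
    "write_masks",
    "read_masks",
    "write_records_csv",
    "write_coupling_csv",
    "write_json",
    "sha256_of",
]


def write_stack(stack: RawStack, path: str | Path, metadata: Optional[dict] = None) -> Path:
    """Write a stack as multi-page float32 TIFF + JSON sidecar manifest."""
    path = Path(path)
    t, c, h, w = stack.shape
    pages = stack.data.astype(np.float32).reshape(t * c, h, w)
    tifffile.imwrite(path, pages)
    sidecar = {
        "shape": [t, c, h, w],
        "page_order": "frame-major (channel fastest)",
        "channel_roles": list(stack.channel_roles),
        "frame_interval_min": stack.frame_interval,
    }
    if metadata:
        sidecar.update(metadata)
    write_json(sidecar, path.with_suffix(path.suffix + ".json"))
    return path


def read_stack(path: str | Path) -> RawStack:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    t, c, h, w = sidecar["shape"]
    data = tifffile.imread(path).reshape(t, c, h, w).astype(float)
    return RawStack(
        data,
        tuple(sidecar.get("channel_roles", CHANNEL_ROLES)),
        float(sidecar.get("frame_interval_min", 1.0)),
    )


def write_masks(masks: MaskStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (masks.masks.astype(np.uint8)) * 255)
    pd.DataFrame({"frame": np.arange(masks.n_frames), "threshold": masks.thresholds}).to_csv(
        path.with_suffix(".thresholds.csv"), index=False
    )
    return path


def read_masks(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def write_records_csv(records: list[CellCorrelationRecord], path: str | Path) -> Path:
    """Per-cell bar-and-whiskers summaries as one CSV row per cell."""
    rows = []
    for i, rec in enumerate(records):
        rows.append(
            {
                "cell": i,
                "mean_r": rec.mean,
                "median_r": rec.median,
                "q1": rec.q1,
                "q3": rec.q3,
                "r_min": rec.r_min,
                "r_max": rec.r_max,
                "n_frames_retained": rec.n_frames_retained,
                "insufficient": rec.insufficient,
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_coupling_csv(cmap: CouplingMap, path: str | Path) -> Path:
    """Coupling map as long-form CSV: column_a, column_b, raw, convolved."""
    ra, cb = np.meshgrid(cmap.cols_a, cmap.cols_b, indexing="ij")
    df = pd.DataFrame(
        {
            "column_a": ra.ravel(),
            "column_b": cb.ravel(),
            "raw": cmap.raw.ravel(),
            "convolved": (cmap.convolved.ravel() if cmap.convolved is not None
                          else np.full(cmap.raw.size, np.nan)),
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
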