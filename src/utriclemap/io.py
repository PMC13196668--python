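"""File I/O: cell tables (CSV), images (TIFF), configs and results (JSON).

Conventions: CSV is comma-separated UTF-8 with a header row; coordinates
are in pixels before normalization (x = image column, y = image row,
0-based) and unitless after; angles are always degrees.  Label images are
integer-labeled with background 0; channel stacks are saved as 16-bit
multi-page TIFF.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

REQUIRED_CELL_COLUMNS = ["cell_id", "x", "y"]


def load_cell_table(path, required_channels=("ch1_mean", "ch2_mean")) -> pd.DataFrame:
    """Read and validate a per-cell CSV table."""
    table = pd.read_csv(path)
    missing = [
        c for c in (*REQUIRED_CELL_COLUMNS, *required_channels) if c not in table.columns
    ]
    if missing:
        raise ValueError(f"{path}: cell table is missing columns {missing}")
    if table["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell_id values")
    return table


def save_cell_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def load_images(label_path, channels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an integer label image and an aligned multichannel stack."""
    labels = tifffile.imread(label_path)
    channels = tifffile.imread(channels_path)
    if channels.ndim == 2:
        channels = channels[None]
    if labels.ndim != 2:
        raise ValueError(f"{label_path}: label image must be 2D")
    if channels.shape[-2:] != labels.shape:
        raise ValueError(
            f"shape mismatch: labels {labels.shape} vs channels {channels.shape[-2:]}"
        )
    if labels.min() < 0:
        raise ValueError("label image has negative labels")
    return labels.astype(np.int32), channels.astype(float)


def save_images(labels: np.ndarray, channels: np.ndarray, label_path, channels_path) -> None:
    """Write label image (int32) and channel stack (clipped to uint16)."""
    Path(label_path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(label_path, np.asarray(labels, dtype=np.int32))
    ch = np.clip(np.asarray(channels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(channels_path, ch)


def load_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def save_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True, default=_json_default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def make_manifest(config: dict, inputs: list, outputs: dict, seed: int | None) -> dict:
    from utriclemap import __version__

    return {
        "software": f"utriclemap {__version__}",
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_hash": config_hash(config),
        "seed": seed,
        "inputs": [str(p) for p in inputs],
        "outputs": {k: str(v) for k, v in outputs.items()},
        "coordinate_convention": "x = image column, y = image row, 0-based; angles in degrees",
    }
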