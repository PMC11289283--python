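"""File I/O helpers: TIFF volumes with voxel-size sidecars, CSV traces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def save_volume(volume: np.ndarray, path, voxel_size_um) -> None:
    """Write a volume as multi-page TIFF plus a JSON voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.astype(np.uint8) if volume.dtype == bool else volume)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"voxel_size_um": list(np.asarray(voxel_size_um, dtype=float))}))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a TIFF volume and its voxel size; returns (volume, voxel_size_um)."""
    path = Path(path)
    volume = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        voxel = np.asarray(json.loads(sidecar.read_text())["voxel_size_um"], dtype=float)
    else:
        voxel = np.ones(3)
    return volume, voxel


def save_trace_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_ledger(ledger, path) -> None:
    Path(path).write_text(json.dumps(ledger.to_dict(), indent=1))
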