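"""Raster and table I/O.

Rasters are stored as multi-band float32 TIFFs with the grid specification,
band names and optional class table serialized as JSON in the TIFF image
description, which keeps the files self-describing and round-trippable on
any TIFF reader. Occurrence sets travel as plain CSV with the header
``species,lon,lat``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic_landscape import EnvStack, GridSpec, OccurrenceSet

__all__ = [
    "write_stack",
    "read_stack",
    "write_grid",
    "read_grid",
    "write_occurrences",
    "read_occurrences",
]


def _grid_meta(grid: GridSpec) -> dict:
    return {
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "lat_min": grid.lat_min,
        "lat_max": grid.lat_max,
        "lon_min": grid.lon_min,
        "lon_max": grid.lon_max,
    }


def write_stack(path, env: EnvStack) -> None:
    """Write an EnvStack as a multi-band float32 TIFF (NaN marks missing)."""
    data = np.stack([env.layers[n] for n in env.layer_names]).astype(np.float32)
    data[:, env.mask] = np.nan
    meta = {"grid": _grid_meta(env.grid), "bands": env.layer_names}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_stack(path) -> EnvStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        grid = GridSpec(**meta["grid"])
        bands = meta["bands"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing or malformed raster metadata: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(bands):
        raise ValueError(f"{path}: {data.shape[0]} bands but {len(bands)} band names")
    layers = {name: data[i].astype(float) for i, name in enumerate(bands)}
    mask = np.isnan(data[0])
    return EnvStack(grid=grid, layers=layers, mask=mask)


def write_grid(path, grid_arr: np.ndarray, grid: GridSpec, name: str = "band",
               class_table: dict | None = None) -> None:
    """Single-band raster; an optional class table (code -> label) is preserved."""
    meta = {"grid": _grid_meta(grid), "bands": [name]}
    if class_table is not None:
        meta["classes"] = {str(k): v for k, v in class_table.items()}
    tifffile.imwrite(path, grid_arr.astype(np.float32), description=json.dumps(meta))


def read_grid(path):
    """Returns (array, GridSpec, name, class_table-or-None)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        grid = GridSpec(**meta["grid"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing or malformed raster metadata: {exc}") from exc
    classes = meta.get("classes")
    if classes is not None:
        classes = {int(k): v for k, v in classes.items()}
    return data.astype(float), grid, meta["bands"][0], classes


def write_occurrences(path, occ: OccurrenceSet) -> None:
    pd.DataFrame({"species": occ.species, "lon": occ.lon, "lat": occ.lat}).to_csv(
        path, index=False
    )


def read_occurrences(path, provenance: str = "file") -> OccurrenceSet:
    df = pd.read_csv(path)
    required = {"species", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: occurrence CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return OccurrenceSet(
        species=df["species"].to_numpy(dtype=object),
        lon=df["lon"].to_numpy(dtype=float),
        lat=df["lat"].to_numpy(dtype=float),
        provenance=provenance,
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
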