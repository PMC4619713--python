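"""Raster and table I/O in plain-text formats.

Rasters are exchanged as ESRI ASCII grids (.asc) — a six-line header
(ncols/nrows/xllcorner/yllcorner/cellsize/nodata_value) followed by
whitespace-separated rows, top row first.  Because the .asc format has no
comment syntax, run provenance (seed, config hash) is written to a JSON
sidecar next to each raster; CSV outputs carry it as '#' header comment
lines instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_esri_ascii",
    "read_esri_ascii",
    "write_csv_with_header",
    "read_csv_with_header",
]


def write_esri_ascii(
    path,
    grid: np.ndarray,
    cell_size: float,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999.0,
    meta: dict | None = None,
) -> None:
    """Write a 2-D array (row 0 = southernmost) as an ESRI ASCII grid.

    Rows are flipped on write so the file's first row is the northern edge,
    as the format requires.  ``meta`` is written to ``<path>.meta.json``.
    """
    grid = np.asarray(grid)
    path = Path(path)
    ny, nx = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, np.flipud(grid), fmt="%.6g")
    if meta:
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def read_esri_ascii(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (grid with row 0 = south, header)."""
    header: dict = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape {grid.shape} does not match header in {path}")
    return np.flipud(grid), header


def write_csv_with_header(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a CSV preceded by '#'-prefixed provenance comment lines."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_csv_with_header(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
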