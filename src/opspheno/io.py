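"""On-disk formats: CSV / Parquet cell tables, TSV libraries and hit
tables, single-channel TIFF images, and JSON parameter sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_cell_table",
    "read_cell_table",
    "write_library",
    "read_library",
    "write_tsv",
    "read_tsv",
    "write_image",
    "read_image",
    "write_params",
    "read_params",
]


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> Path:
    """Write a cell table as CSV (``.csv``) or Parquet (anything else)."""
    path = Path(path)
    if path.suffix == ".csv":
        cells.to_csv(path, index=False)
    else:
        cells.to_parquet(path, index=False)
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    return pd.read_parquet(path)


def write_library(library: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    library.to_csv(path, sep="\t", index=False)
    return path


def read_library(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_ntc"] = df["is_ntc"].astype(bool)
    return df


def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_params(params: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(params, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_params(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
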