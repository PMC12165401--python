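"""Reading and writing timeseries, matrices and result records.

Series files are single-column text/CSV; matrices are CSV/TSV with rows as
time (or image rows) and columns as variables.  A header row is optional
and detected by attempting to parse the first row numerically.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import as_matrix, as_series

__all__ = [
    "read_series",
    "read_matrix",
    "write_series",
    "write_record_json",
    "write_record_csv",
    "format_float",
]

# 17 significant digits round-trip any IEEE double exactly
_FLOAT_FMT = ".17g"


def format_float(v: float) -> str:
    return format(float(v), _FLOAT_FMT)


def _read_frame(path) -> pd.DataFrame:
    with open(path) as fh:
        first = ""
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                first = line
                break
    if not first:
        raise ValueError(f"{path}: no data rows")
    sep = "," if "," in first else "\t" if "\t" in first else r"\s+"
    kwargs = dict(sep=sep, comment="#", skip_blank_lines=True,
                  float_precision="round_trip")
    df = pd.read_csv(path, header=None, **kwargs)
    # optional header row: re-read if the first row is not numeric
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        df = pd.read_csv(path, header=0, **kwargs)
    return df


def read_series(path) -> np.ndarray:
    """Read a univariate series from a single-column text/CSV file."""
    df = _read_frame(path)
    if df.shape[1] != 1:
        raise ValueError(
            f"{path}: expected a single-column series, found {df.shape[1]} columns "
            "(use read_matrix for multivariate input)"
        )
    return as_series(df.iloc[:, 0].to_numpy(dtype=float))


def read_matrix(path) -> np.ndarray:
    """Read a 2-D numeric array (multivariate series or image) from CSV/TSV."""
    df = _read_frame(path)
    return as_matrix(df.to_numpy(dtype=float))


def write_series(path, x) -> None:
    np.savetxt(path, np.asarray(x, dtype=float), fmt=f"%{_FLOAT_FMT}")


def _jsonable(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (np.floating, float)):
        return float(v)
    if isinstance(v, (np.integer, int)):
        return int(v)
    if isinstance(v, np.ndarray):
        return [_jsonable(u) for u in v.tolist()]
    if isinstance(v, (list, tuple)):
        return [_jsonable(u) for u in v]
    if isinstance(v, dict):
        return {str(k): _jsonable(u) for k, u in v.items()}
    if v is None or isinstance(v, (str, bool)):
        return v
    return str(v)


def write_record_json(record: dict, path=None) -> str:
    """Serialize a result record to JSON (returned; also written if path)."""
    text = json.dumps(_jsonable(record), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_record_csv(record: dict, path=None) -> str:
    """Flat key,value CSV serialization of a result record."""
    flat = _jsonable(record)
    rows = []
    for k, v in flat.items():
        if isinstance(v, dict):
            for kk, vv in v.items():
                rows.append((f"{k}.{kk}", vv))
        else:
            rows.append((k, v))
    lines = ["key,value"]
    for k, v in rows:
        if isinstance(v, float):
            v = format_float(v)
        elif isinstance(v, list):
            v = ";".join(format_float(u) if isinstance(u, float) else str(u)
                         for u in v)
        out = str(v)
        if "," in out or '"' in out:
            out = '"' + out.replace('"', '""') + '"'
        lines.append(f"{k},{out}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
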