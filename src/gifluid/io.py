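"""CSV/JSON readers and writers for the loop-record and report schemas."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import RECORD_COLUMNS
from .exceptions import SchemaError
from .volumes import MARKER_FD4, MARKER_TRACER

__all__ = [
    "read_records",
    "write_records",
    "write_volumes",
    "write_summary",
    "write_trajectory",
    "write_report",
    "config_hash",
]

_NUMERIC = ["time_min", "dose", "v0_ml", "x_out", "c_out", "recovery"]
_FLAGS = ["flag_blood", "flag_loop", "flag_low_recovery"]
_MARKERS = {MARKER_FD4, MARKER_TRACER}


def read_records(path) -> pd.DataFrame:
    """Read and validate a loop-record CSV.

    Enforces the canonical schema (comma-separated, header required, UTF-8):
    all columns present, numeric fields parseable and in-range, markers one
    of the two known labels.  Violations raise :class:`SchemaError` naming
    the offending row (1-based data row) and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}", column=missing[0])
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 1
            raise SchemaError(f"{path}: missing value", row=row, column=col)
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise SchemaError(f"{path}: non-numeric value", row=row, column=col)
        df[col] = coerced
    bad_marker = ~df["marker"].isin(_MARKERS)
    if bad_marker.any():
        row = int(df.index[bad_marker][0]) + 1
        raise SchemaError(
            f"{path}: marker must be one of {sorted(_MARKERS)}",
            row=row, column="marker",
        )
    for col, cond in (
        ("time_min", df["time_min"] <= 0),
        ("x_out", df["x_out"] < 0),
        ("c_out", df["c_out"] <= 0),
        ("v0_ml", df["v0_ml"] <= 0),
        ("dose", df["dose"] <= 0),
    ):
        if cond.any():
            row = int(df.index[cond][0]) + 1
            raise SchemaError(f"{path}: value out of range", row=row, column=col)
    for col in _FLAGS:
        df[col] = (
            df[col]
            .map(lambda v: str(v).strip().lower() in {"true", "1", "yes"})
            .astype(bool)
        )
    return df[RECORD_COLUMNS]


def write_records(records: pd.DataFrame, path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


def write_volumes(volumes: pd.DataFrame, path) -> None:
    volumes.to_csv(path, index=False)


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


def write_trajectory(trajectory, path) -> None:
    trajectory.to_csv(path)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def write_report(report: dict, path) -> None:
    """Write a report dict as deterministic JSON (sorted keys, no timestamps)."""
    Path(path).write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a configuration mapping (for report provenance)."""
    canon = json.dumps(_jsonify(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]
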