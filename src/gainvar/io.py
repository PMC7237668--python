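"""Readers and writers for spike-count tables and result records.

Spike-count tables are plain comma-separated text with the header columns
``neuron_id, family_id, condition_id, trial, window_ms, count`` plus optional
metadata columns; fitted and summary results are JSON with a versioned schema
and embedded provenance (config and seed).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .modulated_poisson import REQUIRED_COLUMNS

__all__ = [
    "FORMAT_VERSION",
    "validate_spike_table",
    "read_spike_table",
    "write_spike_table",
    "write_json_result",
    "read_json_result",
]

FORMAT_VERSION = "1.0"


def validate_spike_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate columns, counts and window structure of a spike-count table.

    Counts must be non-negative integers (violations are reported with their
    row number). If the declared window sizes do not all tile the longest
    window a warning is issued; dynamics analyses refuse such tables.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spike-count table is missing columns: {missing}")
    counts = table["count"]
    bad = counts.isna() | (pd.to_numeric(counts, errors="coerce") != counts.astype(float))
    numeric = pd.to_numeric(counts, errors="coerce")
    bad = numeric.isna() | (numeric < 0) | (np.mod(numeric, 1) != 0)
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"invalid spike count at row {row}: {counts.iloc[row]!r} "
            "(counts must be non-negative integers)"
        )
    table = table.copy()
    table["count"] = numeric.astype(int)
    table["window_ms"] = pd.to_numeric(table["window_ms"])
    windows = np.sort(table["window_ms"].unique())
    if len(windows) > 1:
        longest = windows[-1]
        untiled = [float(w) for w in windows if not np.isclose((longest / w) % 1.0, 0.0)
                   and not np.isclose((longest / w) % 1.0, 1.0)]
        if untiled:
            warnings.warn(
                f"window sizes {untiled} do not tile the longest window ({longest} ms); "
                "gain-dynamics analyses will refuse this table"
            )
    return table


def read_spike_table(path) -> pd.DataFrame:
    """Read and validate a comma-separated spike-count table (UTF-8)."""
    table = pd.read_csv(path, encoding="utf-8")
    return validate_spike_table(table)


def write_spike_table(table: pd.DataFrame, path, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    validate_spike_table(table).to_csv(path, index=False, encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def write_json_result(result: dict, path, config: dict | None = None, seed=None,
                      force: bool = False) -> None:
    """Write a result record with format version and provenance embedded."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    record = {"format_version": FORMAT_VERSION, "seed": seed, "config": _jsonable(config or {})}
    record.update(_jsonable(result))
    path.write_text(json.dumps(record, indent=2) + "\n", encoding="utf-8")


def read_json_result(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
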