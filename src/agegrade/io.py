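"""File-format contracts: CSV/TSV readers and writers plus run manifests.

All files are UTF-8, header row, '.' decimal separator.  Missing age is an
empty field.  Gene/sample identifiers are opaque strings (Vectorbase-style
ids pass through unmodified).
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

FLOAT_FORMAT = "%.12g"


def _read_csv(path: str | Path, sep: str = ",") -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed CSV ({exc})") from exc


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s): {', '.join(missing)}")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, ["sample_id", "gene_id", "replicate", "ct"], path)
    try:
        df["replicate"] = df["replicate"].astype(int)
        df["ct"] = df["ct"].astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric replicate/ct value ({exc})") from exc
    return df


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Sample metadata: sample_id, sex, age_days (empty = unknown → NaN)."""
    df = _read_csv(path)
    _require(df, ["sample_id", "sex", "age_days"], path)
    ages = df["age_days"].astype(object)
    ages[ages == ""] = np.nan
    df["age_days"] = pd.to_numeric(ages)
    bad = ~df["sex"].isin(["F", "M"])
    if bad.any():
        raise InputError(f"{path}: sex must be F or M (row {int(bad.idxmax()) + 2})")
    return df


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out["age_days"] = out["age_days"].map(
        lambda v: "" if pd.isna(v) else f"{int(v)}" if float(v).is_integer() else repr(v)
    )
    out.to_csv(path, index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Raw fluorescence matrix: first column gene_id, one column per array."""
    df = _read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise InputError(f"{path}: first column must be 'gene_id'")
    df = df.set_index("gene_id")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric expression value ({exc})") from exc
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT)


def read_array_meta(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, ["array_id", "age_days", "sex"], path)
    df["age_days"] = df["age_days"].astype(float)
    return df


def write_array_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)


def write_logcontrast(x: pd.DataFrame, path: str | Path) -> None:
    x.to_csv(path, index_label="sample_id", float_format=FLOAT_FORMAT)


def read_logcontrast(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, ["sample_id"], path)
    df = df.set_index("sample_id")
    return df.astype(float)


def write_screen_result(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, index_label="gene_id", float_format=FLOAT_FORMAT)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_manifest(
    out_path: str | Path,
    command: str,
    inputs: dict[str, str | Path],
    config: dict,
    seed: int | None,
) -> Path:
    """Write a JSON run manifest next to ``out_path``.

    Records the command, input paths with SHA-256 digests, the full config,
    the seed, and library versions — enough to re-run the stage bit-identically
    (deterministic stages) or distribution-identically (stochastic stages).
    """
    digests = {}
    for name, p in inputs.items():
        p = Path(p)
        digests[name] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None,
        }
    manifest = {
        "command": command,
        "inputs": digests,
        "config": {k: str(v) for k, v in config.items()},
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
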