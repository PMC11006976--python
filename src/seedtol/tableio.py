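"""Validated CSV table input/output.

Schemas are plain {column: dtype} dicts; reading coerces columns and
collects row-level violations (with 1-based data row numbers) into a
single :class:`~seedtol.errors.SchemaError` so a bad file fails loudly and
specifically.  All tables are UTF-8 CSV with '.' decimals and a header row
in stable column order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

TRIALS_SCHEMA = {
    "population_id": str,
    "experiment": str,
    "level_index": int,
    "level_value": float,
    "replicate": int,
    "day": int,
    "n_germinated": int,
}
TRAITS_SCHEMA = {
    "population_id": str,
    "replicate": int,
    "length": float,
    "width": float,
    "LWR": float,
    "TGW": float,
    "CSP": float,
    "CSS": float,
    "CS": float,
    "CCF": float,
}
SITES_SCHEMA = {
    "population_id": str,
    "latitude": float,
    "longitude": float,
    "altitude": float,
    "MAT": float,
    "MAP": float,
    "SOC": float,
    "AN": float,
    "AP": float,
    "pH": float,
}

#: column -> lower bound (exclusive unless 0-inclusive noted via >=)
_NONNEGATIVE = {"n_germinated", "MAP"}
_POSITIVE = {"length", "width", "LWR", "TGW", "CSP", "CSS", "CS", "altitude"}


def read_table(path, schema: dict, extra_ok: bool = True) -> pd.DataFrame:
    """Read and validate a CSV against a {column: dtype} schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    raw = pd.read_csv(path)
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    problems: list[str] = []
    out = raw.copy()
    for col, dtype in schema.items():
        if dtype is str:
            out[col] = raw[col].astype(str)
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        for i in np.flatnonzero(bad.to_numpy()):
            problems.append(f"row {i + 1}, column {col!r}: unparseable value {raw[col].iloc[i]!r}")
        if coerced.isna().any() and not bad.any():
            problems.extend(
                f"row {i + 1}, column {col!r}: missing value"
                for i in np.flatnonzero(coerced.isna().to_numpy())
            )
        if col in _NONNEGATIVE:
            for i in np.flatnonzero((coerced < 0).to_numpy()):
                problems.append(f"row {i + 1}, column {col!r}: negative value {coerced.iloc[i]}")
        if col in _POSITIVE:
            for i in np.flatnonzero((coerced <= 0).to_numpy()):
                problems.append(
                    f"row {i + 1}, column {col!r}: non-positive value {coerced.iloc[i]}"
                )
        out[col] = coerced.astype(dtype, errors="ignore")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    if not extra_ok:
        extras = [c for c in out.columns if c not in schema]
        if extras:
            raise SchemaError(f"{path}: unexpected columns {extras}")
    return out


def write_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
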