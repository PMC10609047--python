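"""Dataset readers/writers.

A dataset is a table of (id, smiles, endpoint) records; the endpoint is any
scalar molecular property — canonically pHLC, the negative decimal
logarithm of a Henry's law constant in atm·m³/mol.  Supported formats:
CSV/TSV with a header, and the whitespace-separated SMI dialect
``SMILES id endpoint``.  All files are UTF-8 with '.' decimal separators.
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["read_dataset", "write_dataset"]

_ENDPOINT_ALIASES = ("endpoint", "phlc", "value", "property", "y")


def _infer_format(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return {".csv": "csv", ".tsv": "tsv", ".smi": "smi"}.get(ext, "csv")


def read_dataset(path, fmt: Optional[str] = None) -> pd.DataFrame:
    """Read a dataset into a DataFrame with columns id, smiles, endpoint.

    Rejects duplicate ids and non-numeric or missing endpoints, reporting
    the offending id or line.
    """
    fmt = fmt or _infer_format(path)
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        if "id" not in df.columns or "smiles" not in df.columns:
            raise ValueError(f"{path}: need 'id' and 'smiles' columns, got {list(df.columns)}")
        endpoint_col = next((c for c in _ENDPOINT_ALIASES if c in df.columns), None)
        if endpoint_col is None:
            raise ValueError(
                f"{path}: no endpoint column (looked for {', '.join(_ENDPOINT_ALIASES)})"
            )
        out = df[["id", "smiles", endpoint_col]].rename(columns={endpoint_col: "endpoint"})
    elif fmt == "smi":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'SMILES id endpoint', got {len(parts)} fields"
                    )
                rows.append((parts[1], parts[0], parts[2]))
        out = pd.DataFrame(rows, columns=["id", "smiles", "endpoint"])
    else:
        raise ValueError(f"unknown format {fmt!r}")

    dup = out["id"][out["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate id {dup.iloc[0]!r}")
    try:
        out["endpoint"] = out["endpoint"].astype(float)
    except (TypeError, ValueError):
        bad = out[pd.to_numeric(out["endpoint"], errors="coerce").isna()]
        raise ValueError(
            f"{path}: non-numeric endpoint for id {bad['id'].iloc[0]!r} "
            f"(row {bad.index[0] + 1})"
        ) from None
    if not np.all(np.isfinite(out["endpoint"])):
        bad_id = out.loc[~np.isfinite(out["endpoint"]), "id"].iloc[0]
        raise ValueError(f"{path}: non-finite endpoint for id {bad_id!r}")
    return out.reset_index(drop=True)


def write_dataset(df: pd.DataFrame, path, fmt: Optional[str] = None) -> None:
    """Write an (id, smiles, endpoint) table in csv, tsv or smi format."""
    fmt = fmt or _infer_format(path)
    cols = df[["id", "smiles", "endpoint"]]
    if fmt == "csv":
        cols.to_csv(path, index=False)
    elif fmt == "tsv":
        cols.to_csv(path, sep="\t", index=False)
    elif fmt == "smi":
        with open(path, "w", encoding="utf-8") as fh:
            for _, row in cols.iterrows():
                fh.write(f"{row['smiles']} {row['id']} {row['endpoint']!r}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
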