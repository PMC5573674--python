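"""TSV table dialects shared by all pipeline stages.

Tab-separated, mandatory header row, UTF-8, '.' decimal separator. Unknown
columns are preserved on round-trip; schema violations are reported with
the 1-based file line number (header is line 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table", "SCHEMAS"]

# required (and numeric) columns per table kind
SCHEMAS: dict[str, dict[str, list[str]]] = {
    "fluctuation": {
        "required": ["strain_id", "medium", "culture_id", "mutant_count"],
        "numeric": ["mutant_count"],
    },
    "plates": {
        "required": [
            "strain_id",
            "medium",
            "plate_id",
            "colony_count",
            "dilution_factor",
            "plated_volume_ml",
        ],
        "numeric": ["colony_count", "dilution_factor", "plated_volume_ml"],
    },
    "od": {
        "required": ["strain_id", "medium", "replicate", "time_h", "od600"],
        "numeric": ["time_h", "od600"],
    },
    "observations": {
        "required": [
            "strain_id",
            "medium",
            "genome_size_mb",
            "mutation_rate",
            "growth_rate",
        ],
        "numeric": ["genome_size_mb", "mutation_rate", "growth_rate"],
    },
    "deletions": {
        "required": ["strain_id", "gene_id", "category"],
        "numeric": [],
    },
}


class SchemaError(ValueError):
    pass


def read_table(
    path: str | Path,
    schema: str | None = None,
    required: list[str] | None = None,
    numeric: list[str] | None = None,
) -> pd.DataFrame:
    """Read a TSV table, validating required and numeric columns.

    ``schema`` names a predefined dialect from ``SCHEMAS``; ``required`` /
    ``numeric`` extend or replace it. Extra columns are kept untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    if schema is not None:
        spec = SCHEMAS[schema]
        required = required or spec["required"]
        numeric = numeric or spec["numeric"]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric or []:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: malformed numeric cell in column {col!r} at line "
                f"{row + 2}: {df[col].iloc[row]!r}"
            )
        df[col] = converted
    return df


def write_table(df: pd.DataFrame, path: str | Path, rate_columns: tuple[str, ...] = ()) -> None:
    """Write a TSV with %.10g floats; rate columns in scientific notation."""
    out = df.copy()
    for col in rate_columns:
        if col in out.columns:
            out[col] = [f"{v:.9e}" if pd.notna(v) else "" for v in out[col]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
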