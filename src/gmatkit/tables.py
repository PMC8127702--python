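"""Phenotype tables: the exchange format shared by every stage.

A phenotype table is a plain :class:`pandas.DataFrame` with five design
columns (``population``, ``block``, ``sire``, ``dam``, ``individual``,
all strings) followed by one numeric column per trait.  Missing trait
values are ``NaN`` and are written to CSV as empty fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ["population", "block", "sire", "dam", "individual"]

#: The six traits scored in the common-garden experiment the package models.
#: Units are documentation only; no conversion logic exists.
TRAITS = [
    "early_height",          # cm, at two weeks
    "final_height",          # cm
    "branch_number",         # count
    "flowering_date",        # days to first flower
    "inflorescence_length",  # cm; male-fitness proxy
    "seed_mass",             # g; female-fitness proxy
]

#: Fitness proxies, excluded from selection-response predictions.
FITNESS_TRAITS = ["inflorescence_length", "seed_mass"]

#: The four size/phenology traits entering selection gradients.
FOCAL_TRAITS = [t for t in TRAITS if t not in FITNESS_TRAITS]


class TableFormatError(ValueError):
    """Raised when a phenotype CSV violates the exchange format."""


def trait_columns(table: pd.DataFrame) -> list[str]:
    """Trait columns present in *table*, in canonical order first."""
    known = [t for t in TRAITS if t in table.columns]
    extra = [
        c for c in table.columns
        if c not in DESIGN_COLUMNS and c not in known
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    return known + extra


def validate_phenotypes(table: pd.DataFrame, traits: list[str] | None = None) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in table.columns]
    if missing:
        raise TableFormatError(f"missing design columns: {missing}")
    for t in traits or trait_columns(table):
        if t not in table.columns:
            raise TableFormatError(f"missing trait column: {t}")
        if not pd.api.types.is_numeric_dtype(table[t]):
            raise TableFormatError(f"trait column {t!r} is not numeric")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype table from CSV.

    Design columns are read as strings; trait columns as floats with empty
    fields decoded as missing.  Unknown extra columns are preserved
    (numeric if they parse, otherwise as strings).  Malformed trait cells
    are reported with their row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DESIGN_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing design columns {missing}")
    out = raw[DESIGN_COLUMNS].copy()
    for col in raw.columns:
        if col in DESIGN_COLUMNS:
            continue
        cells = raw[col].replace("", np.nan)
        values = pd.to_numeric(cells, errors="coerce")
        bad = values.isna() & cells.notna()
        if bad.any():
            if col in TRAITS:
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TableFormatError(
                    f"{path}: non-numeric value {cells.iloc[row]!r} in trait "
                    f"column {col!r}, data row {row}"
                )
            out[col] = cells  # unknown non-numeric column: pass through
        else:
            out[col] = values.astype(float)
    return out


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table as UTF-8 CSV (missing values -> empty fields)."""
    validate_phenotypes(table)
    cols = DESIGN_COLUMNS + [c for c in table.columns if c not in DESIGN_COLUMNS]
    table[cols].to_csv(path, index=False, na_rep="")
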