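"""Reading and writing quarterly-extract-style ``$``-delimited ASCII tables.

The spontaneous-report database is exchanged as six flat tables named after
the FAERS quarter files (DEMO, DRUG, REAC, THER, INDI, OUTC), one header
line then one ``$``-delimited record per line.  Dates are 8-digit
``yyyymmdd`` integers; missing values are empty fields.  A field that
itself contains the ``$`` delimiter is rejected at write time (the dialect
has no quoting), which is the documented rule for this writer.
"""

from __future__ import annotations

import os

import pandas as pd

__all__ = ["SCHEMAS", "TABLE_NAMES", "write_faers_dialect", "read_faers_dialect"]

SCHEMAS: dict[str, dict[str, str]] = {
    "demo": {
        "primaryid": "int64", "caseid": "int64", "caseversion": "int64",
        "event_dt": "Int64", "age": "float64", "sex": "string",
        "wt": "float64", "reporter_country": "string", "occp_cod": "string",
    },
    "drug": {
        "primaryid": "int64", "caseid": "int64", "drug_seq": "int64",
        "drugname": "string", "route": "string",
    },
    "reac": {"primaryid": "int64", "caseid": "int64", "pt": "string"},
    "ther": {
        "primaryid": "int64", "caseid": "int64", "dsg_drug_seq": "int64",
        "start_dt": "Int64",
    },
    "indi": {
        "primaryid": "int64", "caseid": "int64", "indi_drug_seq": "int64",
        "indi_pt": "string",
    },
    "outc": {"primaryid": "int64", "caseid": "int64", "outc_cod": "string"},
}

TABLE_NAMES = tuple(SCHEMAS)

DELIM = "$"


def apply_schema(df: pd.DataFrame, name: str) -> pd.DataFrame:
    """Coerce a table's columns to the canonical dtypes for ``name``."""
    schema = SCHEMAS[name]
    out = df.copy()
    for col, dtype in schema.items():
        if col not in out.columns:
            raise ValueError(f"table {name!r} is missing column {col!r}")
        out[col] = out[col].astype(dtype)
    return out[list(schema)]


def write_faers_dialect(tables: dict[str, pd.DataFrame], directory) -> dict[str, str]:
    """Write each table as ``<NAME>.txt`` under ``directory``.

    Returns the mapping of table name to file path.  Raises ``ValueError``
    if any text field contains the ``$`` delimiter.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        if name not in SCHEMAS:
            raise ValueError(f"unknown table {name!r}; expected one of {TABLE_NAMES}")
        df = apply_schema(df, name)
        for col in df.columns:
            if pd.api.types.is_string_dtype(df[col]):
                bad = df[col].dropna().str.contains(DELIM, regex=False)
                if bad.any():
                    raise ValueError(
                        f"table {name!r} column {col!r} contains the {DELIM!r} "
                        "delimiter; the dialect has no quoting")
        path = os.path.join(directory, f"{name.upper()}.txt")
        df.to_csv(path, sep=DELIM, index=False, na_rep="")
        paths[name] = path
    return paths


def read_faers_dialect(directory, names=TABLE_NAMES) -> dict[str, pd.DataFrame]:
    """Read ``<NAME>.txt`` tables back into typed DataFrames."""
    tables = {}
    for name in names:
        path = os.path.join(directory, f"{name.upper()}.txt")
        raw = pd.read_csv(path, sep=DELIM, dtype="string", keep_default_na=False,
                          na_values=[""])
        tables[name] = apply_schema(raw, name)
    return tables
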