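"""CSV schema contracts shared by the pipeline commands.

All canonical files are comma-delimited UTF-8 with a header row, preceded by
one comment line declaring the schema name and version, e.g.::

    # semiquant-schema: measurements v1

Readers skip ``#`` comment lines, so the files remain plain CSV.
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError

SCHEMA_VERSION = 1

SCHEMAS = {
    "measurements": ["sample_id", "molecule_id", "smiles", "concentration_mg_per_kg", "area", "istd_area"],
    "molecules": ["molecule_id", "smiles", "target"],
    "beta": ["molecule_id", "mean_alpha", "beta", "n_kept", "n_flagged"],
    "rejects": ["molecule_id", "sample_id", "reason"],
    "predictions": ["molecule_id", "target_true", "target_pred"],
    "estimates": ["molecule_id", "s_bar", "beta_pred", "conc_estimate_mg_per_kg"],
    "ground_truth": ["molecule_id", "beta_true"],
    "injected_outliers": ["row_id"],
}


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    cols = SCHEMAS[schema]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {schema} table, missing columns {missing}")
    with open(path, "w", newline="") as fh:
        fh.write(f"# semiquant-schema: {schema} v{SCHEMA_VERSION}\n")
        df[cols].to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {schema} table is missing columns {missing}")
    return df
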