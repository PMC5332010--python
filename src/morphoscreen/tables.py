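"""Tab-delimited feature-table I/O.

One file per replicate plate (1A, 1B, 2A, 2B), mirroring the deposited
spreadsheets: a ``well`` column, a ``gene`` column that carries the number
of cells plated (as a bare number) for density-dilution wells, then named
feature columns.  Missing values are written as ``NA``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

NA_TOKEN = "NA"


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_feature_table(path, registry_names=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=True)
    if registry_names is not None:
        unknown = [
            c
            for c in df.columns
            if c not in registry_names
            and c not in ("well", "gene", "plate", "role", "n_cells", "cell")
        ]
        if unknown:
            warnings.warn(f"unknown columns preserved: {unknown[:5]}...")
    meta_cols = {"well", "gene", "plate", "role"}
    for c in df.columns:
        if c not in meta_cols and df[c].dtype == object:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            if bad.any():
                warnings.warn(
                    f"{path}: {int(bad.sum())} non-numeric cells in column "
                    f"{c!r} set to missing"
                )
            df[c] = coerced
    return df


def dilution_cells_plated(df: pd.DataFrame) -> pd.Series:
    """Parse cells-plated from the gene column of dilution wells.

    The deposited convention stores the plated cell number in the gene-name
    column for the density-dilution wells on columns 1, 2, 23 and 24.
    """
    return pd.to_numeric(df["gene"], errors="coerce")


def check_table(df: pd.DataFrame, registry_names) -> None:
    missing = [n for n in registry_names if n not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks registry columns: {missing[:5]}...")
    if df["well"].duplicated().any():
        dupes = df.loc[df["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate wells: {dupes[:5]}")


def is_number(x) -> bool:
    try:
        return np.isfinite(float(x))
    except (TypeError, ValueError):
        return False
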