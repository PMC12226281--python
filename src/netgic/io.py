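"""Delimited-text ingestion and emission.

Expression matrices travel as TSV/CSV with a header row; modulators as a
two-column table (sample id, value); edge lists as three-column TSV.  All
output is deterministic: fixed row order and 6-significant-digit weights.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import NetgicError
from .network import EdgeTable
from .weighted_model import ExpressionDataset, ModulatorProfile

__all__ = ["read_expression", "read_modulator", "write_edge_list", "read_edge_list"]


def _read_table(path):
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_expression(path, *, genes_as="cols", center=True, scale=True) -> ExpressionDataset:
    """Read an expression matrix from delimited text.

    With ``genes_as='cols'`` (default) rows are samples and columns genes;
    ``genes_as='rows'`` reads the transposed layout.  Missing or non-numeric
    cells are rejected with their location.
    """
    if genes_as not in ("cols", "rows"):
        raise NetgicError(f"genes_as must be 'cols' or 'rows', got {genes_as!r}")
    df = _read_table(path)
    if genes_as == "rows":
        df = df.T
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise NetgicError(
                f"non-numeric or missing value at (row {bad[0]!r}, column {col!r}) in {path}")
        df[col] = vals
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise NetgicError(f"duplicate sample or gene identifiers in {path}")
    return ExpressionDataset(df.to_numpy(dtype=float),
                             gene_ids=list(df.columns.astype(str)),
                             sample_ids=list(df.index.astype(str)),
                             center=center, scale=scale)


def read_modulator(path, dataset: ExpressionDataset | None = None) -> ModulatorProfile:
    """Read a two-column (sample id, value) modulator table.

    When ``dataset`` is given the values are reordered to its sample order
    and checked for completeness.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["sample", "value"], comment="#")
    if df["sample"].astype(str).iloc[0].lower() in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        row = df.index[values.isna()][0]
        raise NetgicError(f"non-numeric modulator value at row {row} in {path}")
    lookup = dict(zip(df["sample"].astype(str), values.astype(float)))
    if dataset is not None:
        missing = [s for s in dataset.sample_ids if s not in lookup]
        if missing:
            raise NetgicError(f"modulator file lacks samples {missing[:5]}")
        m = np.array([lookup[s] for s in dataset.sample_ids])
    else:
        m = values.to_numpy(dtype=float)
    return ModulatorProfile(m=m)


def write_edge_list(t: EdgeTable, path) -> None:
    """Write a TSV edge list with deterministic ordering.

    Rows sort by target, then |weight| descending, then regulator; weights
    are printed with 6 significant digits.
    """
    df = t.df.copy()
    df["_mag"] = -df["weight"].abs()
    df = df.sort_values(["target", "_mag", "regulator"]).drop(columns="_mag")
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tweight\n")
        for _, row in df.iterrows():
            fh.write(f"{row['regulator']}\t{row['target']}\t{row['weight']:.6g}\n")


def read_edge_list(path) -> EdgeTable:
    df = pd.read_csv(path, sep="\t")
    return EdgeTable(df[["regulator", "target", "weight"]])
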