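"""Adapter for pre-downloaded GEO series-matrix files.

Consumes an (uncompressed) series-matrix text file — ``!``-prefixed
metadata lines framing a probe x sample table between
``!series_matrix_table_begin`` and ``!series_matrix_table_end`` — together
with an explicit probe -> gene-symbol mapping supplied by the caller
(platform annotations differ too much to guess). Probes mapping to the
same symbol are collapsed by their median. No downloading happens here;
the validation recipe operates strictly on local files.
"""

from __future__ import annotations

import gzip

import pandas as pd

from .matrix import ExpressionMatrix, MatrixError


def read_probe_map(path) -> pd.Series:
    """Two-column TSV probe_id -> gene symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MatrixError(f"probe map {path} needs probe and symbol columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_series_matrix(
    path,
    probe_map: pd.Series,
    stage: str = "log2",
    collapse: str = "median",
    groups: pd.Series | None = None,
) -> ExpressionMatrix:
    """Parse a series-matrix file into a gene-symbol ExpressionMatrix.

    Unmapped probes are dropped; ``collapse`` ('median' or 'mean') resolves
    multiple probes per symbol. ``stage`` declares the scale the deposited
    values are on (most deposited arrays are already log2).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = fh.readlines()
    try:
        start = next(
            i for i, ln in enumerate(lines)
            if ln.startswith("!series_matrix_table_begin")
        )
        end = next(
            i for i, ln in enumerate(lines)
            if ln.startswith("!series_matrix_table_end")
        )
    except StopIteration as exc:
        raise MatrixError(
            f"{path}: no series_matrix_table_begin/end markers"
        ) from exc
    from io import StringIO

    table = pd.read_csv(
        StringIO("".join(lines[start + 1 : end])), sep="\t", index_col=0
    )
    table.index = table.index.astype(str).str.strip('"')
    table.columns = table.columns.astype(str).str.strip('"')
    mapped = table.loc[table.index.isin(probe_map.index)].copy()
    if mapped.empty:
        raise MatrixError("no probes matched the probe map")
    mapped.index = probe_map.loc[mapped.index].values
    if collapse not in ("median", "mean"):
        raise MatrixError(f"unknown collapse {collapse!r}")
    collapsed = getattr(mapped.groupby(level=0), collapse)()
    return ExpressionMatrix(values=collapsed, stage=stage, groups=groups)
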