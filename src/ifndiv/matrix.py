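"""Gene x sample expression container and plain-text readers/writers.

The whole pipeline operates on one substrate: a genes-in-rows,
samples-in-columns matrix of relative expression values, carrying a *stage*
tag that records which scale the numbers are on:

``linear``
    relative quantities from qPCR standard-curve quantification
    (housekeeping-normalized, strictly positive).
``log2``
    log2 of the linear relative quantities.
``hc_relative_log2``
    log2 values re-expressed relative to the per-gene median over healthy
    controls — the scale on which IFN scores, cluster scores and the
    GC-A/GC-B log-ratio are defined.

Sample group labels (healthy control, SLE, IFNbeta-treated MS, ...) ride
along as an optional sample -> group mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("linear", "log2", "hc_relative_log2")


class MatrixError(ValueError):
    """Malformed expression matrix or metadata."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag and group labels.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    stage
        One of :data:`STAGES`; records the scale of ``values``.
    groups
        Optional Series mapping sample id -> group label. May cover a
        superset of the matrix's samples (e.g. a full cohort sheet).
    """

    values: pd.DataFrame
    stage: str
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise MatrixError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise MatrixError(f"duplicate gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise MatrixError(f"duplicate sample ids: {dupes}")
        if self.groups is not None:
            missing = cols.difference(self.groups.index)
            if len(missing):
                raise MatrixError(
                    f"samples without a group label: {sorted(missing)}"
                )

    # -- convenience -------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise MatrixError("matrix carries no group labels")
        hits = self.groups[self.groups == group].index
        return [s for s in self.samples if s in set(hits)]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise MatrixError(f"unknown samples: {missing}")
        return replace(self, values=self.values[list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise MatrixError(f"unknown genes: {missing}")
        return replace(self, values=self.values.loc[list(gene_ids)])

    def with_stage(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, stage=stage, groups=self.groups)


def read_expression_tsv(
    path, stage: str = "hc_relative_log2", groups: pd.Series | None = None
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    dup_pos = np.flatnonzero(df.index.duplicated())
    if dup_pos.size:
        gene = df.index[dup_pos[0]]
        # +2: one for the header line, one for 1-based numbering
        raise MatrixError(
            f"duplicate gene id {gene!r} (line {int(dup_pos[0]) + 2}) in {path}"
        )
    non_numeric = df.columns[
        ~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))
    ]
    if len(non_numeric):
        raise MatrixError(
            f"non-numeric values in columns {list(non_numeric)} of {path}"
        )
    return ExpressionMatrix(values=df.astype(float), stage=stage, groups=groups)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_metadata_tsv(path) -> pd.Series:
    """Read a two-column sample metadata TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MatrixError(f"metadata {path} needs sample_id and group columns")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dupes = sorted(df.loc[df[sample_col].duplicated(), sample_col])
        raise MatrixError(f"duplicate sample ids in metadata: {dupes}")
    return pd.Series(
        df[group_col].values, index=df[sample_col].values, name="group"
    )


def write_metadata_tsv(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )
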