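"""qPCR preprocessing: Ct -> relative quantity -> log2 -> HC-relative.

Quantification follows the standard-curve method. A per-assay calibration
line ``Ct = intercept + slope * log10(quantity)`` maps cycle-threshold
values to quantities; each gene's quantity is divided by the housekeeping
gene's quantity (GAPDH in the assay this models) in the same sample,
yielding a relative quantity (RQ). RQs are log2-transformed, and finally
each gene is expressed relative to its median log2 value over healthy
controls, which removes inter-experimental level shifts.

Nonpositive quantities are never silently patched: a value that cannot be
log-transformed raises, and undetected Ct values are governed by an explicit
missing policy. Silent imputation would leak into every downstream score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError


class CurveError(ValueError):
    """Invalid standard-curve parameters."""


class PreprocessError(ValueError):
    """Unusable input to a preprocessing step."""


#: slope of an ideal 100 %-efficiency assay, -1/log10(2) cycles per log10 unit
IDEAL_SLOPE = -1.0 / math.log10(2.0)


@dataclass(frozen=True)
class StandardCurve:
    """Calibration line Ct = intercept + slope * log10(quantity).

    ``slope`` is in cycles per log10 quantity (about -3.32 for a perfectly
    efficient assay), ``intercept`` the Ct at unit quantity.
    """

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise CurveError("curve slope and intercept must be finite")
        if self.slope == 0:
            raise CurveError("curve slope must be nonzero")

    def quantity(self, ct):
        """Invert the calibration line: quantity = 10**((Ct - intercept)/slope)."""
        return 10.0 ** ((np.asarray(ct, dtype=float) - self.intercept) / self.slope)

    def ct(self, quantity):
        """Forward map: Ct = intercept + slope * log10(quantity)."""
        return self.intercept + self.slope * np.log10(np.asarray(quantity, dtype=float))


@dataclass
class CtTable:
    """Gene x sample cycle-threshold values plus the housekeeping gene id.

    NaN marks an undetected reaction. The housekeeping row must be present
    and detected for every sample, otherwise per-sample normalization is
    undefined.
    """

    values: pd.DataFrame
    housekeeping: str

    def __post_init__(self) -> None:
        if self.housekeeping not in self.values.index:
            raise PreprocessError(
                f"housekeeping gene {self.housekeeping!r} not in Ct table"
            )
        hk = self.values.loc[self.housekeeping]
        bad = hk.index[~np.isfinite(hk.values.astype(float))]
        if len(bad):
            raise PreprocessError(
                f"housekeeping Ct missing for samples: {sorted(bad)}"
            )


def read_ct_tsv(path, housekeeping: str) -> CtTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CtTable(values=df.astype(float), housekeeping=housekeeping)


def write_ct_tsv(table: CtTable, path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene")


def ct_to_relative_quantity(
    table: CtTable,
    curve: StandardCurve,
    missing_policy: str = "error",
    groups: pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert Ct values to housekeeping-normalized relative quantities.

    Per sample, RQ_gene = Q_gene / Q_housekeeping with Q from the standard
    curve. The housekeeping row is consumed and removed from the output.

    ``missing_policy`` controls undetected (NaN) gene Ct values:

    - ``error``: raise, naming gene and sample;
    - ``drop-gene``: remove genes with any undetected value;
    - ``drop-sample``: remove samples with any undetected value.
    """
    if missing_policy not in ("error", "drop-gene", "drop-sample"):
        raise PreprocessError(f"unknown missing policy {missing_policy!r}")
    ct = table.values.drop(index=table.housekeeping)
    undetected = ~np.isfinite(ct.values)
    if undetected.any():
        rows, cols = np.nonzero(undetected)
        where = [(ct.index[r], ct.columns[c]) for r, c in zip(rows, cols)]
        if missing_policy == "error":
            raise PreprocessError(f"undetected Ct values at (gene, sample): {where}")
        if missing_policy == "drop-gene":
            ct = ct.loc[~undetected.any(axis=1)]
        else:
            ct = ct.loc[:, ~undetected.any(axis=0)]
    hk_q = curve.quantity(table.values.loc[table.housekeeping, ct.columns])
    gene_q = curve.quantity(ct)
    rq = pd.DataFrame(
        gene_q / np.asarray(hk_q)[None, :], index=ct.index, columns=ct.columns
    )
    return ExpressionMatrix(values=rq, stage="linear", groups=groups)


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2 of linear relative quantities. Nonpositive values raise."""
    if matrix.stage != "linear":
        raise PreprocessError(f"expected a linear-stage matrix, got {matrix.stage!r}")
    vals = matrix.values.values
    finite = np.isfinite(vals)
    bad = finite & (vals <= 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise PreprocessError(
            f"nonpositive quantity for gene {matrix.genes[r]!r}, "
            f"sample {matrix.samples[c]!r}: log2 undefined"
        )
    return matrix.with_stage(np.log2(matrix.values), "log2")


def normalize_to_hc_median(
    matrix: ExpressionMatrix, hc_sample_ids
) -> ExpressionMatrix:
    """Subtract each gene's median log2 value over healthy-control samples.

    HC samples stay in the output; after this step the per-gene HC median is
    exactly 0 for an odd HC count (mean-of-middle-two convention otherwise).
    """
    if matrix.stage != "log2":
        raise PreprocessError(f"expected a log2-stage matrix, got {matrix.stage!r}")
    hc_ids = list(hc_sample_ids)
    if not hc_ids:
        raise PreprocessError("empty healthy-control sample set")
    missing = [s for s in hc_ids if s not in matrix.values.columns]
    if missing:
        raise MatrixError(f"unknown samples: {missing}")
    hc = matrix.values[hc_ids]
    all_missing = hc.isna().all(axis=1)
    if all_missing.any():
        raise PreprocessError(
            f"genes with no HC values: {list(hc.index[all_missing])}"
        )
    medians = hc.median(axis=1)
    return matrix.with_stage(matrix.values.sub(medians, axis=0), "hc_relative_log2")
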