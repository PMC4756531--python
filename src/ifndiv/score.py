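"""IFN scores, the IFN-high cutoff, cohort selection, panel correlation.

The IFN score of a sample is the mean, over a fixed panel of interferon
response genes, of its HC-relative log2 expression. Averaging is justified
by the panel's strong pairwise correlation, which
:func:`panel_correlation_summary` quantifies. A sample is IFN-high when its
score exceeds the healthy-control mean + k*SD (k = 2 by default); IFN-high
samples inside a configurable score window form the *initial* analysis
cohort and the remainder the *additional* (verification) cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix


class ScoreError(ValueError):
    pass


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene symbols making up the signature panel."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ScoreError("empty gene panel")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ScoreError(f"duplicate panel genes: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def read(cls, path) -> "GenePanel":
        """Read a panel file: one symbol per line (or a YAML list)."""
        with open(path) as fh:
            text = fh.read()
        lines = [ln.strip().lstrip("- ") for ln in text.splitlines()]
        return cls(tuple(ln for ln in lines if ln and not ln.startswith("#")))


def compute_ifn_scores(
    matrix: ExpressionMatrix,
    panel: GenePanel,
    missing_gene_policy: str = "error",
) -> pd.Series:
    """Per-sample mean HC-relative log2 expression over the panel genes.

    ``missing_gene_policy='drop'`` scores over the intersection when panel
    genes are absent from the matrix (a warning lists them), mirroring
    panels applied to platforms that lack a member gene.
    """
    if matrix.stage != "hc_relative_log2":
        raise ScoreError(
            f"IFN scores are defined on hc_relative_log2 values, got {matrix.stage!r}"
        )
    present = [g for g in panel.genes if g in matrix.values.index]
    absent = [g for g in panel.genes if g not in matrix.values.index]
    if absent:
        if missing_gene_policy == "error":
            raise ScoreError(f"panel genes missing from matrix: {absent}")
        if missing_gene_policy != "drop":
            raise ScoreError(f"unknown missing-gene policy {missing_gene_policy!r}")
        if not present:
            raise ScoreError("no panel genes present in matrix")
        warnings.warn(
            f"scoring over {len(present)} of {len(panel)} panel genes; "
            f"absent: {absent}",
            stacklevel=2,
        )
    scores = matrix.values.loc[present].mean(axis=0)
    scores.name = "ifn_score"
    return scores


def derive_cutoff(hc_scores, k: float = 2.0) -> float:
    """IFN-high cutoff: mean + k * sample SD (ddof=1) of HC scores."""
    hc = np.asarray(pd.Series(hc_scores).dropna(), dtype=float)
    if hc.size < 2:
        raise ScoreError("need at least 2 HC scores to derive a cutoff")
    return float(hc.mean() + k * hc.std(ddof=1))


@dataclass
class IFNScoreResult:
    """Per-sample scores, IFN-high flags and cohort assignment.

    ``table`` columns: score, ifn_high, cohort with cohort in
    {initial, additional, not_ifn_high, excluded_baseline}.
    """

    table: pd.DataFrame
    cutoff: float
    cutoff_k: float = 2.0
    window: tuple[float, float] = (2.5, 4.0)

    def samples_in_cohort(self, cohort: str) -> list[str]:
        return list(self.table.index[self.table["cohort"] == cohort])


def select_cohorts(
    scores: pd.Series,
    cutoff: float,
    window: tuple[float, float] = (2.5, 4.0),
    baseline_scores: pd.Series | None = None,
    cutoff_k: float = 2.0,
) -> IFNScoreResult:
    """Flag IFN-high samples and split them into initial/additional cohorts.

    IFN-high means score strictly above ``cutoff``; the initial cohort is
    the closed window ``[low, high]`` of comparable score magnitude, the
    additional cohort every other IFN-high sample. When ``baseline_scores``
    are given (e.g. pre-treatment scores), samples already above the cutoff
    at baseline are excluded outright, so that an on-treatment signature
    can be attributed to the treatment.
    """
    low, high = window
    if low > high:
        raise ScoreError(f"window low {low} > high {high}")
    if baseline_scores is not None:
        unmatched = baseline_scores.index.difference(scores.index)
        if len(unmatched):
            raise ScoreError(
                f"baseline scores for unknown samples: {sorted(unmatched)}"
            )
    ifn_high = scores > cutoff
    cohort = pd.Series("not_ifn_high", index=scores.index, dtype=object)
    cohort[ifn_high & (scores >= low) & (scores <= high)] = "initial"
    cohort[ifn_high & ((scores < low) | (scores > high))] = "additional"
    if baseline_scores is not None:
        excluded = baseline_scores.index[baseline_scores > cutoff]
        cohort[cohort.index.isin(excluded)] = "excluded_baseline"
        ifn_high = ifn_high & ~cohort.eq("excluded_baseline")
    table = pd.DataFrame(
        {"score": scores, "ifn_high": ifn_high, "cohort": cohort}
    )
    return IFNScoreResult(table=table, cutoff=float(cutoff), cutoff_k=cutoff_k,
                          window=(low, high))


@dataclass
class CorrelationSummary:
    """Pairwise Pearson correlation of the panel genes across samples."""

    r: pd.DataFrame
    pvalues: pd.DataFrame
    fraction_above: float
    r_threshold: float
    n_pairs: int
    n_undefined_pairs: int = 0
    undefined_genes: list[str] = field(default_factory=list)


def panel_correlation_summary(
    matrix: ExpressionMatrix,
    panel: GenePanel | None = None,
    r_threshold: float = 0.7,
) -> CorrelationSummary:
    """All pairwise Pearson r among panel genes, with two-sided p-values.

    p-values come from the t-transform of r with n-2 degrees of freedom.
    Zero-variance genes make r undefined; their pairs are excluded from the
    fraction's denominator and the genes reported.
    """
    sub = matrix if panel is None else matrix.subset_genes(list(panel.genes))
    n = sub.n_samples
    if n < 3:
        raise ScoreError("need at least 3 samples for correlation p-values")
    if sub.n_genes < 2:
        raise ScoreError("need at least 2 genes for pairwise correlation")
    vals = sub.values
    undefined = list(vals.index[vals.std(axis=1, ddof=0) == 0])
    r = vals.T.corr(method="pearson")
    with np.errstate(divide="ignore", invalid="ignore"):
        rv = r.values.copy()
        np.fill_diagonal(rv, np.nan)
        t = rv * np.sqrt((n - 2) / np.clip(1.0 - rv**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvalues = pd.DataFrame(p, index=r.index, columns=r.columns)
    iu = np.triu_indices(len(r), k=1)
    pair_r = r.values[iu]
    defined = np.isfinite(pair_r)
    n_def = int(defined.sum())
    if n_def == 0:
        raise ScoreError("no defined gene pairs (all genes zero-variance?)")
    fraction = float((pair_r[defined] > r_threshold).sum() / n_def)
    if undefined:
        warnings.warn(
            f"zero-variance genes excluded from correlation fraction: {undefined}",
            stacklevel=2,
        )
    return CorrelationSummary(
        r=r,
        pvalues=pvalues,
        fraction_above=fraction,
        r_threshold=r_threshold,
        n_pairs=n_def,
        n_undefined_pairs=int(len(pair_r) - n_def),
        undefined_genes=undefined,
    )
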