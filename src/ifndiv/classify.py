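"""GC-A/GC-B scores, the dominance log-ratio, and within-group paired tests.

Each sample gets a GC-A score and a GC-B score (mean HC-relative log2
expression of the respective gene set) and their difference

    delta = GC-A score - GC-B score,

which equals the log2 ratio of the geometric means of the underlying
relative quantities. delta > 0 reads as IFNalpha-program dominance,
delta < 0 as IFNbeta-program dominance; an optional half-width epsilon
around zero labels near-zero ratios ``balanced``. Because delta is a
difference of per-sample means it is invariant to adding any per-sample
constant to all genes, so global level shifts (and the IFN score itself)
cancel out of the classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import GCDefinition
from .matrix import ExpressionMatrix


class ClassifyError(ValueError):
    pass


def cluster_scores(
    matrix: ExpressionMatrix,
    gc: GCDefinition,
    missing_gene_policy: str = "error",
) -> pd.DataFrame:
    """Per-sample mean expression of the GC-A and GC-B gene sets.

    Returns a DataFrame indexed by sample with columns gc_a_score and
    gc_b_score. ``missing_gene_policy='drop'`` tolerates absent genes
    (warning emitted) as long as neither set empties out.
    """
    if matrix.stage != "hc_relative_log2":
        raise ClassifyError(
            f"cluster scores are defined on hc_relative_log2 values, "
            f"got {matrix.stage!r}"
        )
    cols = {}
    for name, genes in (("gc_a_score", gc.gc_a), ("gc_b_score", gc.gc_b)):
        present = [g for g in genes if g in matrix.values.index]
        absent = [g for g in genes if g not in matrix.values.index]
        if absent:
            if missing_gene_policy == "error":
                raise ClassifyError(f"{name}: genes missing from matrix: {absent}")
            if missing_gene_policy != "drop":
                raise ClassifyError(
                    f"unknown missing-gene policy {missing_gene_policy!r}"
                )
            if not present:
                raise ClassifyError(f"{name}: no genes left after dropping {absent}")
            warnings.warn(f"{name} over {len(present)} genes; absent: {absent}",
                          stacklevel=2)
        cols[name] = matrix.values.loc[present].mean(axis=0)
    return pd.DataFrame(cols)


@dataclass
class DominanceResult:
    """Per-sample program dominance.

    ``table`` columns: gc_a_score, gc_b_score, delta, label with label in
    {A_dominant, B_dominant, balanced}; delta = gc_a_score - gc_b_score.
    """

    table: pd.DataFrame
    epsilon: float = 0.0

    def fraction(self, label: str) -> float:
        return float((self.table["label"] == label).mean())


def dominance(scores: pd.DataFrame, epsilon: float = 0.0) -> DominanceResult:
    """Classify each sample by the sign of delta = GC-A - GC-B score.

    delta > epsilon -> A_dominant, delta < -epsilon -> B_dominant, otherwise
    balanced. epsilon defaults to 0 (pure sign rule).
    """
    if epsilon < 0:
        raise ClassifyError("epsilon must be >= 0")
    if not np.all(np.isfinite(scores[["gc_a_score", "gc_b_score"]].values)):
        raise ClassifyError("non-finite cluster scores")
    delta = scores["gc_a_score"] - scores["gc_b_score"]
    label = pd.Series("balanced", index=scores.index, dtype=object)
    label[delta > epsilon] = "A_dominant"
    label[delta < -epsilon] = "B_dominant"
    table = scores.copy()
    table["delta"] = delta
    table["label"] = label
    return DominanceResult(table=table, epsilon=epsilon)


def paired_cluster_test(
    scores: pd.DataFrame, sample_groups: pd.Series
) -> pd.DataFrame:
    """Two-sided paired t-test of GC-A vs GC-B score within each group.

    Returns a DataFrame indexed by group with columns n, mean_delta, t, df,
    p and degenerate. Zero-variance differences give p = 1 (zero mean) or
    p = 0 with the degenerate flag (nonzero mean).
    """
    rows = {}
    present = list(dict.fromkeys(sample_groups.get(s) for s in scores.index))
    for group in present:
        ids = [s for s in scores.index if sample_groups.get(s) == group]
        if len(ids) < 2:
            raise ClassifyError(f"group {group!r} has fewer than 2 samples")
        a = scores.loc[ids, "gc_a_score"].values
        b = scores.loc[ids, "gc_b_score"].values
        diff = a - b
        degenerate = bool(np.isclose(diff.std(ddof=1), 0.0))
        if degenerate:
            t = 0.0
            p = 1.0 if np.isclose(diff.mean(), 0.0) else 0.0
        else:
            res = stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        rows[group] = {
            "n": len(ids),
            "mean_delta": float(diff.mean()),
            "t": t,
            "df": len(ids) - 1,
            "p": p,
            "degenerate": degenerate,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_summary(result: DominanceResult, sample_groups: pd.Series) -> pd.DataFrame:
    """Per-group dominance composition: n and fractions of each label."""
    tbl = result.table.copy()
    tbl["group"] = [sample_groups.get(s) for s in tbl.index]
    rows = {}
    for group, sub in tbl.groupby("group", sort=False):
        rows[group] = {
            "n": len(sub),
            "frac_a_dominant": float((sub["label"] == "A_dominant").mean()),
            "frac_b_dominant": float((sub["label"] == "B_dominant").mean()),
            "frac_balanced": float((sub["label"] == "balanced").mean()),
            "mean_delta": float(sub["delta"].mean()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
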