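"""Per-gene two-group t-tests, FDR control, and GC-A/GC-B refinement.

The two unsupervised gene clusters are refined into the interpretable gene
sets GC-A and GC-B by differential expression between the two reference
patient groups (SLE-like vs IFNbeta-treated-MS-like): a gene enters GC-A if
it sits in the upper cluster and is significantly *up* in group 1, GC-B if
it sits in the lower cluster and is significantly up in group 2. Genes that
are significant in the wrong direction, or not significant after
Benjamini-Hochberg correction, are left out — which is why the clusters'
sizes shrink (e.g. 7 -> 5 and 16 -> 13 in a two-program cohort with a few
balanced genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import GeneClusterPartition
from .matrix import ExpressionMatrix


class DiffError(ValueError):
    pass


def per_gene_ttest(
    matrix: ExpressionMatrix,
    group1_ids,
    group2_ids,
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired two-sided t-test per gene, group 1 minus group 2.

    Student's pooled-variance test by default (df = n1 + n2 - 2);
    ``welch=True`` switches to the unequal-variance form. Degenerate genes
    (zero variance in both groups) get p = 1 when the means agree and p = 0
    with ``degenerate=True`` otherwise.

    Returns a DataFrame indexed by gene with columns mean_diff, t, df, p,
    direction (up_in_1/up_in_2/none) and degenerate.
    """
    g1 = matrix.subset_samples(list(group1_ids)).values
    g2 = matrix.subset_samples(list(group2_ids)).values
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DiffError(f"need >= 2 samples per group, got {n1} and {n2}")
    res = stats.ttest_ind(g1.values, g2.values, axis=1, equal_var=not welch)
    mean_diff = g1.values.mean(axis=1) - g2.values.mean(axis=1)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(getattr(res, "df", np.full_like(t, n1 + n2 - 2)), dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        zero_diff = np.isclose(mean_diff, 0.0)
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, np.where(zero_diff, 1.0, 0.0), p)
    direction = np.where(
        mean_diff > 0, "up_in_1", np.where(mean_diff < 0, "up_in_2", "none")
    )
    return pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t": t,
            "df": df,
            "p": p,
            "direction": direction,
            "degenerate": degenerate,
        },
        index=g1.index,
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up FDR-adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DiffError("pvalues must be a nonempty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DiffError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_pvalues(de: pd.DataFrame) -> pd.DataFrame:
    """Append a BH-adjusted p column to a per-gene test table."""
    out = de.copy()
    out["p_adj"] = benjamini_hochberg(out["p"].values)
    return out


@dataclass
class GCDefinition:
    """The refined gene sets behind the GC-A and GC-B scores."""

    gc_a: tuple[str, ...]
    gc_b: tuple[str, ...]
    alpha: float = 0.05
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.gc_a) & set(self.gc_b)
        if overlap:
            raise DiffError(f"genes in both GC-A and GC-B: {sorted(overlap)}")
        if not self.gc_a or not self.gc_b:
            raise DiffError(
                "GC-A and GC-B must both be nonempty; an empty cluster makes "
                "the log-ratio undefined — inspect the partition and DE results"
            )

    def to_dict(self) -> dict:
        return {
            "gc_a": list(self.gc_a),
            "gc_b": list(self.gc_b),
            "alpha": self.alpha,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GCDefinition":
        return cls(
            gc_a=tuple(d["gc_a"]),
            gc_b=tuple(d["gc_b"]),
            alpha=float(d.get("alpha", 0.05)),
            provenance=dict(d.get("provenance", {})),
        )


def define_gc_sets(
    partition: GeneClusterPartition,
    de: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    upper_label: str = "upper",
    lower_label: str = "lower",
) -> GCDefinition:
    """Refine a two-cluster gene partition into GC-A / GC-B by DE filtering.

    ``de`` must carry p (and p_adj unless ``use_adjusted=False``) plus
    direction, with group 1 the IFNalpha-driven reference (SLE-like) and
    group 2 the IFNbeta-driven one.
    """
    covered = set(partition.labels.index)
    if not covered <= set(de.index):
        raise DiffError(
            f"DE results missing for genes: {sorted(covered - set(de.index))}"
        )
    col = "p_adj" if use_adjusted else "p"
    if col not in de.columns:
        raise DiffError(f"DE table lacks a {col!r} column")
    sig = de[col] < alpha
    gc_a = [
        g
        for g in partition.members(upper_label)
        if sig[g] and de.loc[g, "direction"] == "up_in_1"
    ]
    gc_b = [
        g
        for g in partition.members(lower_label)
        if sig[g] and de.loc[g, "direction"] == "up_in_2"
    ]
    return GCDefinition(
        gc_a=tuple(gc_a),
        gc_b=tuple(gc_b),
        alpha=alpha,
        provenance={
            "upper_size": len(partition.members(upper_label)),
            "lower_size": len(partition.members(lower_label)),
            "p_column": col,
        },
    )
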