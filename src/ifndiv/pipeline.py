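"""End-to-end orchestration: score -> select -> cluster -> test -> classify.

:func:`run_all` wires the stages together in the order the analysis runs
on a real cohort:

1. normalize log2 expression to the healthy-control median per gene;
2. compute per-sample IFN scores over the gene panel, derive the IFN-high
   cutoff from HC scores, and assign every sample to the initial
   (comparable-score window) or additional cohort;
3. cluster the panel genes (1 - Pearson r, average linkage) on the initial
   cohort of the two reference groups and cut into two clusters;
4. refine the clusters into GC-A / GC-B by per-gene t-tests with
   Benjamini-Hochberg correction;
5. score all IFN-high samples of every group on GC-A and GC-B, classify by
   the delta log-ratio, and run the within-group paired tests.

The report is a plain JSON-serializable dict (schema-versioned) recording
every pinned default actually used, so a run is auditable from its output
alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import classify as _classify
from . import cluster as _cluster
from . import differential as _diff
from . import score as _score
from .matrix import ExpressionMatrix, write_expression_tsv

REPORT_SCHEMA_VERSION = 1

#: keys every report must carry; validated on write
REPORT_REQUIRED_KEYS = (
    "schema_version",
    "parameters",
    "cutoff",
    "cohort_counts",
    "partition_sizes",
    "gc_a",
    "gc_b",
    "group_dominance",
    "paired_tests",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of a full run.

    ``group1`` is the IFNalpha-driven reference group (SLE-like) and
    ``group2`` the IFNbeta-driven one; GC-A/GC-B directionality follows
    this convention.
    """

    hc_group: str = "HC"
    group1: str = "SLE"
    group2: str = "MS_IFNB"
    panel: tuple[str, ...] | None = None  # None = all genes in the matrix
    window: tuple[float, float] = (2.5, 4.0)
    cutoff_k: float = 2.0
    k: int = 2
    alpha: float = 0.05
    use_adjusted: bool = True
    epsilon: float = 0.0
    linkage: str = "average"
    missing_gene_policy: str = "error"
    welch: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)


def run_all(
    matrix: ExpressionMatrix,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis on a log2 (or already HC-relative) matrix.

    Returns the report dict; when ``out_dir`` is given, also writes every
    stage output (TSVs, GC definition, Newick dendrogram, report JSON)
    under it.
    """
    if matrix.groups is None:
        raise PipelineError("input: matrix carries no sample group labels")

    def fail(stage: str, exc: Exception) -> PipelineError:
        return PipelineError(f"stage {stage!r} failed: {exc}")

    # -- normalization -----------------------------------------------------
    try:
        hc_ids = matrix.samples_in_group(config.hc_group)
        if matrix.stage == "log2":
            from .preprocess import normalize_to_hc_median

            if not hc_ids:
                raise PipelineError(
                    f"no samples in healthy-control group {config.hc_group!r}"
                )
            norm = normalize_to_hc_median(matrix, hc_ids)
        elif matrix.stage == "hc_relative_log2":
            norm = matrix
        else:
            raise PipelineError(
                f"matrix stage {matrix.stage!r}: run preprocessing first"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise fail("normalize", exc) from exc

    panel = _score.GenePanel(
        tuple(config.panel) if config.panel else tuple(norm.genes)
    )

    # -- scoring and cohort selection --------------------------------------
    try:
        scores = _score.compute_ifn_scores(
            norm, panel, missing_gene_policy=config.missing_gene_policy
        )
        cutoff = _score.derive_cutoff(scores[hc_ids], k=config.cutoff_k)
        selection = _score.select_cohorts(
            scores, cutoff, window=config.window, cutoff_k=config.cutoff_k
        )
        corr = _score.panel_correlation_summary(norm, panel)
    except Exception as exc:
        raise fail("score", exc) from exc

    initial = set(selection.samples_in_cohort("initial"))
    g1_initial = [s for s in norm.samples_in_group(config.group1) if s in initial]
    g2_initial = [s for s in norm.samples_in_group(config.group2) if s in initial]

    # -- gene clustering on the initial two-group cohort --------------------
    try:
        ref = norm.subset_genes(panel.genes).subset_samples(g1_initial + g2_initial)
        dist = _cluster.correlation_distance(ref, axis="genes")
        dendro = _cluster.linkage_tree(dist, method=config.linkage)
        partition = _cluster.cut_k_clusters(
            dendro, k=config.k, matrix=ref, reference_samples=g1_initial
        )
        sample_dendro = _cluster.linkage_tree(
            _cluster.correlation_distance(ref, axis="samples"),
            method=config.linkage,
        )
        sample_partition = _cluster.cut_k_clusters(sample_dendro, k=2)
        true_groups = [norm.groups[s] for s in sample_partition.labels.index]
        sample_ari = float(
            adjusted_rand_score(true_groups, list(sample_partition.labels.values))
        )
    except Exception as exc:
        raise fail("cluster", exc) from exc

    # -- differential expression and GC refinement --------------------------
    try:
        de = _diff.adjust_pvalues(
            _diff.per_gene_ttest(ref, g1_initial, g2_initial, welch=config.welch)
        )
        gc = _diff.define_gc_sets(
            partition, de, alpha=config.alpha, use_adjusted=config.use_adjusted
        )
    except Exception as exc:
        raise fail("differential", exc) from exc

    # -- dominance classification over all IFN-high samples ------------------
    try:
        ifn_high = list(selection.table.index[selection.table["ifn_high"]])
        cls_scores = _classify.cluster_scores(
            norm.subset_samples(ifn_high), gc,
            missing_gene_policy=config.missing_gene_policy,
        )
        dom = _classify.dominance(cls_scores, epsilon=config.epsilon)
        summary = _classify.group_summary(dom, norm.groups)
        # paired test only where a group has >= 2 IFN-high samples
        counts = pd.Series([norm.groups.get(s) for s in cls_scores.index]).value_counts()
        testable = set(counts.index[counts >= 2])
        paired = _classify.paired_cluster_test(
            cls_scores.loc[[s for s in cls_scores.index if norm.groups.get(s) in testable]],
            norm.groups,
        )
    except Exception as exc:
        raise fail("classify", exc) from exc

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
                if k != "extra"
            },
            "panel_size": len(panel),
            "metric": "1 - pearson r",
        },
        "cutoff": float(cutoff),
        "cohort_counts": selection.table["cohort"].value_counts().to_dict(),
        "correlation_fraction_above_0_7": corr.fraction_above,
        "partition_sizes": partition.sizes,
        "sample_cluster_group_ari": sample_ari,
        "gc_a": list(gc.gc_a),
        "gc_b": list(gc.gc_b),
        "gc_a_size": len(gc.gc_a),
        "gc_b_size": len(gc.gc_b),
        "group_dominance": {
            str(g): row.to_dict() for g, row in summary.iterrows()
        },
        "paired_tests": {str(g): row.to_dict() for g, row in paired.iterrows()},
    }

    if out_dir is not None:
        _write_outputs(
            out_dir, norm, selection, partition, dendro, de, gc, dom, summary, report
        )
    return report


def validate_report(report: dict) -> None:
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise PipelineError(f"report missing keys: {missing}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise PipelineError(
            f"report schema {report['schema_version']} != {REPORT_SCHEMA_VERSION}"
        )


def write_report(report: dict, path) -> None:
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _write_outputs(
    out_dir, norm, selection, partition, dendro, de, gc, dom, summary, report
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_tsv(norm, out / "expression_hc_relative.tsv")
    selection.table.to_csv(out / "ifn_scores.tsv", sep="\t", index_label="sample_id")
    partition.labels.rename("cluster").to_csv(
        out / "gene_partition.tsv", sep="\t", index_label="gene"
    )
    (out / "gene_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    de.to_csv(out / "differential.tsv", sep="\t", index_label="gene")
    import yaml

    (out / "gc_definition.yaml").write_text(yaml.safe_dump(gc.to_dict()))
    dom.table.to_csv(out / "dominance.tsv", sep="\t", index_label="sample_id")
    summary.to_csv(out / "group_summary.tsv", sep="\t", index_label="group")
    write_report(report, out / "report.json")
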