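# ifndiv

Dissecting IFNα- versus IFNβ-driven type I interferon signatures in
peripheral-blood gene expression.

## The problem

Many autoimmune diseases — systemic lupus erythematosus (SLE), multiple
sclerosis (MS), myositis (IIM), rheumatoid arthritis (RA) — show a *type I
IFN signature*: coordinated upregulation of interferon response genes
(IRGs) in blood. Yet IFNα drives SLE pathology while IFNβ is a *therapy*
for MS, so "an IFN signature" is not one thing. This package implements an
analysis that splits the signature into two data-driven gene clusters — an
IFNα-associated cluster (**GC-A**) and an IFNβ-associated cluster
(**GC-B**) — and classifies each patient by which program dominates. It is
aimed at researchers analysing targeted (qPCR-panel) or summarized
microarray expression of IRG panels in patient cohorts.

## The method

Starting from a genes × samples table of log2 expression relative to the
healthy-control (HC) median per gene:

1. **IFN score** — per sample *i*, the panel mean
   `score_i = (1/|P|) Σ_{g∈P} x_{g,i}`; averaging is justified by strong
   pairwise IRG correlation (Pearson r > 0.7 for the large majority of
   pairs). A sample is **IFN-high** when `score > mean_HC + 2·SD_HC`;
   IFN-high samples with scores in a comparable window ([2.5, 4.0]) form
   the initial analysis cohort.
2. **Gene-module discovery** — hierarchical clustering of the panel genes
   with correlation distance `d = 1 − r` and average linkage (UPGMA) on the
   initial SLE-like vs IFNβ-treated-MS-like cohort; the dendrogram is cut
   into two clusters.
3. **GC refinement** — per-gene unpaired t-tests (SLE vs MS-IFNβ) with
   Benjamini–Hochberg correction; GC-A = upper-cluster genes significantly
   up in SLE, GC-B = lower-cluster genes significantly up in MS-IFNβ.
4. **Dominance classification** — per sample,
   `Δ = GC-A score − GC-B score = log2(GC-A/GC-B)`;
   Δ > 0 means IFNα-program dominance, Δ < 0 IFNβ-program dominance.
   Within-group paired t-tests compare the two cluster scores.

A synthetic-cohort generator
(`x_{g,i} = baseline_g + w_{g,A}·a_i + w_{g,B}·b_i + ε`, with per-group
latent program activities `a, b` and Gaussian log-scale noise) plants this
exact two-program structure with known ground truth, so every stage of the
pipeline is verifiable without patient data. A qPCR front-end converts raw
Ct tables to log2 relative quantities by the standard-curve method
(`Ct = intercept + slope·log10 Q`, normalized to GAPDH).

## Worked example

```python
import ifndiv as iv

matrix, truth = iv.generate_cohort(iv.default_config(seed=0))
report = iv.run_all(matrix, iv.PipelineConfig())
print(report["gc_a"])        # ['IFITM1', 'IFI27', 'LY6E', 'SIGLEC1', 'EPSTI1']
print(report["gc_b_size"])   # 13
for g, row in report["group_dominance"].items():
    print(g, round(row["frac_a_dominant"], 2), round(row["mean_delta"], 2))
```

prints (seed 0):

```
HC 1.0 0.13
SLE 1.0 3.79
MS_IFNB 0.0 -2.17
IIM 1.0 3.89
RA 0.42 -0.03
MS_UNTREATED 0.42 0.37
```

Every SLE-like and IIM-like sample is A-dominant (Δ > 0), every
IFNβ-treated-MS-like sample B-dominant (Δ < 0); the RA-like group hovers
near Δ = 0 and the untreated-MS-like mixture splits roughly half and half —
the heterogeneity pattern the two-program model predicts. The refined gene
sets match the planted 5 A-genes and 13 B-genes exactly.

The scripts in `examples/` walk through each capability (simulation, Ct
preprocessing, scoring and selection, cluster discovery, dominance
classification); each prints its numbers with a note on what they mean.
There is also a thin CLI: `ifndiv simulate|preprocess|score|cluster|diff|
classify|run-all --help`.

## Layout

- `src/ifndiv/` — `simulate`, `preprocess`, `score`, `cluster`,
  `differential`, `classify`, `pipeline`, `matrix`, `geo` (series-matrix
  adapter), `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, assumptions, parameter choices, limitations
- `tests/` — unit, property and end-to-end suites
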