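# Methods

## The analysis model

The pipeline treats blood IRG expression as driven by two latent type I IFN
response programs per sample: an IFNα-associated activity *a* and an
IFNβ-associated activity *b*. On the log2 relative-expression scale each
panel gene *g* responds linearly,

    x[g, i] = baseline_g + w_gA · a_i + w_gB · b_i + ε,   ε ~ N(0, σ²),

and the analysis asks, per sample, which program dominates. All stages
operate on *HC-relative* log2 values: each gene is first expressed relative
to its median over healthy controls, which removes assay-level shifts and
makes 0 the "healthy typical" point of every gene.

Stage order and decision rules:

1. **IFN score** = panel mean of HC-relative log2 values. **IFN-high** is
   `score > mean_HC + k·SD_HC` with k = 2 and the *sample* SD (n−1
   denominator); the inequality is strict. IFN-high samples with scores in
   the closed window [2.5, 4.0] form the *initial* cohort (comparable
   signature magnitude, so that cluster differences are qualitative, not
   quantitative); other IFN-high samples are the *additional* cohort. When
   pre-treatment baseline scores are supplied, samples already IFN-high at
   baseline are excluded outright — an on-treatment signature can then be
   attributed to the treatment. Window bounds are pinned inclusive;
   boundary behaviour is a convention, not an empirical claim.
2. **Gene clustering** uses distance d = 1 − Pearson r and average linkage
   (UPGMA). Neither choice is forced by the data model; they are the
   defaults of the classic two-way hierarchical clustering framework for
   expression matrices and both are exposed as options (`linkage` also
   accepts complete/single). The dendrogram is cut into k = 2 clusters by
   removing the highest merge; for display, the cluster with higher mean
   expression in the SLE-like reference samples is called "upper".
3. **GC refinement**: per-gene two-sided unpaired t-tests between the two
   reference groups. Student's pooled-variance form is the default (the
   classical reading of "unpaired t test"); Welch is a flag. p-values are
   Benjamini–Hochberg adjusted across the whole panel as one family, and
   membership requires adjusted p < 0.05 (correction and test are part of
   the same procedure; a raw-p switch exists) *and* the right direction:
   GC-A genes must be up in the SLE-like group, GC-B genes up in the
   IFNβ-treated group. Significant but wrong-direction genes are excluded.
   An empty GC-A or GC-B is a hard error because the log-ratio downstream
   would be undefined.
4. **Dominance**: Δ = GC-A score − GC-B score, the difference of the two
   gene-set means. Because the scores are means of log2 quantities, Δ is
   the log2 ratio of geometric-mean relative quantities, and 0 is the
   natural decision boundary. Δ is invariant to adding any per-sample
   constant to all genes (normalization shifts cancel), and swapping the
   two gene sets negates it exactly. A half-width ε around 0 labels
   samples "balanced"; ε defaults to 0 (pure sign rule) and is a reporting
   device, not a fitted threshold. Within-group comparison of the two
   cluster scores uses a two-sided paired t-test.

## qPCR front-end

Relative quantities come from the standard-curve method: a per-assay
calibration line Ct = intercept + slope·log10(Q) (slope in cycles per
log10 unit, ≈ −3.32 at 100 % efficiency), with each gene's quantity
divided by the GAPDH quantity of the same sample. One shared curve is the
default since assay-specific curves are rarely published; per-assay curves
can be applied by preprocessing per assay. Log2 transform refuses
nonpositive quantities rather than imputing: undetected Ct values are
handled only by an explicit policy (`error`, `drop-gene`, `drop-sample`),
because silent pseudocounts would propagate into every score. With an even
number of HCs the median is the mean of the two middle values.

## The synthetic-data generator

`generate_cohort` draws per-group activities a, b ~ N(group mean,
activity_sd²), truncated at 0 by clipping (negative IFN activity is
meaningless; at the default activity_sd = 0.3 and patient means ≥ 1.4 the
clipping probability is < 1e-5, so moments are unaffected at test
tolerance — only the quiescent HC group is visibly clipped, which is
intended). A group may draw its activities from a two-component mixture to
model heterogeneous cohorts. Noise is i.i.d. Gaussian on the log2 scale
(noise_sd = 0.5 by default, a typical residual spread for preamplified
panel qPCR after housekeeping normalization). Randomness comes from one
seed; each group consumes its own deterministically spawned substream, so
output is bit-reproducible and group-order stable.

The default configuration plants 23 genes — 5 A-responsive,
13 B-responsive, 5 balanced — across HC (n = 54) and five patient-like
groups: SLE-like (a, b) = (3.0, 0.5), IFNβ-treated-MS-like (0.5, 3.0),
IIM-like (3.0, 0.5), RA-like (1.4, 2.1), and an untreated-MS-like 50/50
mixture of the SLE-like and MS-like components (n = 30, 63, 26, 26, 12).
Activity magnitudes put patient IFN scores in the 2.5–4.0 band; sizes
follow the IFN-high selections of the cohorts the analysis models.

Gene loadings are A-genes (w_A, w_B) = (2.0, 0.3), B-genes (0.55, 1.25),
balanced genes (0.9, 0.9). Two deliberate choices:

- **Equal total panel loading on both programs.** The 5 A-genes respond
  more steeply than the 13 B-genes so that Σ_g w_gA = Σ_g w_gB. Then the
  IFN score (the panel mean) responds identically to A- and B-activity,
  both reference groups have the same score distribution, and selecting
  the comparable-score window truncates both groups identically. With
  unequal totals the window selection is asymmetric, which induces a real
  mean difference in the *balanced* genes between selected groups and
  contaminates GC-A with genes that are not program-specific. Steep
  A-loadings are also biologically reasonable — the canonical
  IFNα-program markers (e.g. IFI27, SIGLEC1) are among the highest
  fold-change IRGs in lupus blood — and keep the 5-gene GC-A score as
  informative as the 13-gene GC-B score.
- **RA-like means sit at the balance point** (1.45·a ≈ 0.95·b under these
  loadings), so the RA-like group's log-ratios straddle zero, emulating a
  cohort where both programs contribute.

Only eight of the default panel's symbols carry program assignments
motivated by IFNα/IFNβ stimulation data (IFITM1 in GC-A; EIF2AK2, IFIT1,
IFIT2, MX1, OAS2, PLSCR1 in GC-B; SAMD9L panel membership); the remaining
15 are canonical blood IRGs serving as placeholders in a fully
configurable panel.

What the generator does **not** emulate: probe-level microarray noise,
cell-type composition effects, count-based RNA-seq variance, batch or
plate effects, or correlated (gene–gene residual) noise. Passing tests
therefore demonstrate that the pipeline recovers a planted two-program
structure under clean Gaussian conditions — the mechanism, not the
biology. With real data the cluster assignments and dominance calls
additionally depend on panel choice, platform and cohort composition.

## Numerical choices and degenerate inputs

- Correlation p-values use the t-transform of r with n − 2 df, two-sided,
  uncorrected (the summary reports a single fraction-above-threshold).
  Zero-variance genes make r undefined; their pairs leave the fraction's
  denominator and the genes are reported.
- Zero-variance genes are an error in distance computation (d undefined)
  rather than silently assigned d = 1.
- Degenerate t-tests (zero variance): p = 1 when means agree, p = 0 with a
  `degenerate` flag when they differ.
- UPGMA heights are validated non-decreasing on construction (average
  linkage cannot invert); dendrogram ties are resolved deterministically
  by the linkage implementation, and on continuous correlation distances
  ties have probability zero.
- The end-to-end report is schema-versioned JSON recording every pinned
  parameter actually used, so a run is auditable from its outputs.

## Problem sizes

The shipped default cohorts (211 samples × 23 genes; 20 simulation
replicates for the separation and recovery summaries; 1,000 random
instances for the linkage and BH oracle comparisons) were chosen so the
complete test suite and the acceptance script each finish in seconds while
keeping binomial/Monte-Carlo margins comfortable.

## Known limitations

- The GC refinement inherits the multiple-testing family from the panel
  (one BH family across all panel genes); panels much larger than ~23
  genes may warrant per-cluster families.
- The dominance rule is a hard sign classifier; no uncertainty is attached
  to Δ per sample (a bootstrap over genes would be the natural extension).
- The GEO series-matrix adapter requires an explicit probe→symbol map and
  assumes the deposited values are already summarized per probe; it does
  no normalization of its own.
- With a single shared standard curve, assay-efficiency differences fold
  into per-gene baselines; they cancel in HC-relative values but not in
  raw relative quantities.
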