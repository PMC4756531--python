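"""Discover GC-A and GC-B: cluster the panel genes, refine by DE testing.

Genes are clustered by 1 - Pearson r with average linkage on the initial
cohort (SLE-like vs IFNbeta-treated-MS-like samples of comparable IFN
score); the two-cluster cut is refined into GC-A (significantly up in the
SLE-like group) and GC-B (up in the MS-like group) by per-gene t-tests with
Benjamini-Hochberg correction.
"""

import ifndiv as iv

matrix, truth = iv.generate_cohort(iv.default_config(seed=0))
norm = iv.normalize_to_hc_median(matrix, matrix.samples_in_group("HC"))
sle = norm.samples_in_group("SLE")
ms = norm.samples_in_group("MS_IFNB")
sub = norm.subset_samples(sle + ms)

dendro = iv.average_linkage(iv.correlation_distance(sub, axis="genes"))
partition = iv.cut_k_clusters(dendro, k=2, matrix=sub, reference_samples=sle)
print("two-cluster cut:", partition.sizes)

de = iv.adjust_pvalues(iv.per_gene_ttest(sub, sle, ms))
gc = iv.define_gc_sets(partition, de, alpha=0.05)
print(f"GC-A ({len(gc.gc_a)} genes): {sorted(gc.gc_a)}")
print(f"GC-B ({len(gc.gc_b)} genes): {sorted(gc.gc_b)}")

planted = truth.program_labels()
print("planted A genes recovered:",
      set(gc.gc_a) == set(planted.index[planted == "A"]))
# The balanced filler genes land in one of the two clusters but fail the
# significance+direction filter, so the refined sets match the planted 5/13.
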