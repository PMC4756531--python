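"""Classify samples by the GC-A/GC-B log-ratio and summarize per group.

delta = GC-A score - GC-B score is a log2 ratio: positive means the
IFNalpha-associated program dominates, negative the IFNbeta-associated one.
"""

import ifndiv as iv

report = iv.run_all(
    iv.generate_cohort(iv.default_config(seed=0))[0], iv.PipelineConfig()
)

print(f"{'group':>14} {'n':>4} {'%A-dom':>7} {'%B-dom':>7} {'mean delta':>11}")
for group, row in report["group_dominance"].items():
    print(f"{group:>14} {row['n']:>4.0f} {row['frac_a_dominant']:>7.0%} "
          f"{row['frac_b_dominant']:>7.0%} {row['mean_delta']:>11.2f}")

print("\npaired GC-A vs GC-B test p-values per group:")
for group, row in report["paired_tests"].items():
    print(f"  {group:>14}: p = {row['p']:.2e}")
# SLE-like and IIM-like cohorts are uniformly A-dominant, the IFNbeta-treated
# MS-like cohort B-dominant; the RA-like group hovers near delta = 0 and the
# untreated-MS-like mixture splits roughly half and half.
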