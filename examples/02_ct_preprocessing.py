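"""From raw qPCR Ct values to HC-relative log2 expression.

Quantities come from the standard-curve method (Ct = intercept +
slope*log10(Q)), normalized to the GAPDH housekeeping gene, log2-transformed
and finally expressed relative to each gene's healthy-control median.
"""

import ifndiv as iv

curve = iv.StandardCurve(slope=-3.3219, intercept=40.0)  # ~100 % efficiency

config = iv.SimConfig(
    groups=(iv.GroupSpec("HC", 5, 0.0, 0.0), iv.GroupSpec("SLE", 3, 3.0, 0.5)),
    genes=tuple(iv.GeneSpec(g, 2.0, 0.3) for g in ("IFITM1", "IFI27", "LY6E")),
    noise_sd=0.3,
    seed=7,
)
ct_table, truth = iv.generate_ct_table(config, curve, housekeeping_ct=20.0)
print("raw Ct values (GAPDH row is the per-sample reference):")
print(ct_table.values.round(2))

import pandas as pd

groups = pd.Series(truth.samples["group"].values,
                   index=truth.samples["sample_id"].values)
linear = iv.ct_to_relative_quantity(ct_table, curve, groups=groups)
log2 = iv.log2_transform(linear)
relative = iv.normalize_to_hc_median(log2, log2.samples_in_group("HC"))
print("\nHC-relative log2 expression (HC medians are 0 by construction):")
print(relative.values.round(2))
# SLE-like samples sit several log2 units above the HC median: each unit is
# a doubling of relative transcript abundance.
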