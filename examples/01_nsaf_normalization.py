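"""NSAF-normalize a small synthetic spectral-count matrix.

Builds a 300-protein, 7-genotype experiment, adds the 0.05 spectral
fraction so zeros survive log transformation, and converts exclusive
spectral counts to length-corrected NSAF abundances (ppm scale).
"""

import nonzein as nz

cfg = nz.SimulationConfig(n_proteins=300, seed=7)
counts, catalog, _ = nz.simulate_experiment(cfg)

corrected = nz.add_spectral_fraction(counts, 0.05)
table = nz.nsaf(corrected, catalog, scale=1e6)

print("samples:", len(table.values.columns), "| proteins:", len(table.values))
print("column sums (all equal the 1e6 ppm scale):")
print(table.values.sum(axis=0).head(4).to_string())
print("\nfirst NSAF values (ppm):")
print(table.values.iloc[:4, :3].round(1).to_string())
# Each column sums to exactly 1e6: within a sample, NSAF values are
# relative abundances corrected for protein length and sampling depth.
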