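"""Parental genetic distance from SSR band sharing and SNP identity-by-state.

GD_SSR = 1 - 2*N_ab/(N_a + N_b) counts shared fragment-length bands over the
markers scored in both accessions; GD_SNP = 1 - IBS averages per-site allele
sharing.  Both lie in [0, 1]: 0 for identical genotypes, 1 for completely
disjoint ones.
"""

import numpy as np

from hetgd import SimConfig, cross_gd, gd_population_summary, gd_snp_matrix, \
    gd_ssr_matrix, make_ncii_design, simulate_parents

cfg = SimConfig(n_males=2, n_females=30, n_snps=300, n_ssr=24, seed=11)
ssr, snp, meta, truth = simulate_parents(cfg)

ssr_dm = gd_ssr_matrix(ssr)
snp_dm = gd_snp_matrix(snp)
print(f"GD_SSR panel mean: {np.nanmean(ssr_dm.values[np.triu_indices(32, 1)]):.3f}")
print(f"GD_SNP panel mean: {np.nanmean(snp_dm.values[np.triu_indices(32, 1)]):.3f}")

males = [s for s in snp.samples if meta.table.loc[s, "role"] == "male"]
females = [s for s in snp.samples if meta.table.loc[s, "role"] == "female"]
design = make_ncii_design(males, females)
table = cross_gd(design, ssr_dm, snp_dm)
print("\nper-male-population GD summary (min/max/mean per marker system,")
print("plus the SSR~SNP correlation within the male's crosses):")
print(gd_population_summary(table).round(3).to_string(index=False))

# A positive r says the two marker systems rank the same crosses as
# genetically distant -- the agreement the analysis relies on before using
# GD to predict which crosses show heterosis.
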