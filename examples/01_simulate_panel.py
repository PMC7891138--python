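"""Simulate a structured inbred panel with its NC II factorial and phenotypes.

Builds a small version of a hybrid-cotton study: inbred parents drawn from
three origin subpopulations, every male crossed to every female, and ten
traits with additive + dominance architecture phenotyped in 2 years x 2
sites.
"""

from hetgd import SimConfig, simulate_study

cfg = SimConfig(n_males=2, n_females=30, n_snps=300, n_ssr=24, seed=11)
ssr, snp, f1, design, pheno, meta, truth = simulate_study(cfg)

print(f"parents: {snp.n_samples} ({cfg.n_males} males x {cfg.n_females} females)")
print("origin classes:", meta.table["origin"].value_counts().to_dict())
print(f"crosses: {len(design)} (complete factorial)")
print(f"SNP sites: {snp.n_sites}, missing fraction {(snp.dosage == -1).mean():.3f}")
print(f"F1 mean heterozygosity: {(f1.dosage == 1).mean():.3f}")
print(f"phenotype records: {len(pheno)} "
      f"({len(pheno) // (4 * len(cfg.traits))} entities x "
      f"{len(cfg.traits)} traits x 4 environments)")

# The origin counts follow the 136/103/47 elite/historic/exotic reference
# composition, scaled to the panel size; F1 heterozygosity reflects how far
# apart the parental subpopulations are (Fst). Everything is reproducible
# from the seed.
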