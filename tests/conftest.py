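import numpy as np
import pandas as pd
import pytest

from hetgd import SimConfig, simulate_study
from hetgd.genotypes import SNPGenotypes, SSRGenotypes


@pytest.fixture(scope="session")
def small_study():
    """A small but structured simulated study shared across tests."""
    cfg = SimConfig(
        n_males=2,
        n_females=18,
        n_subpops=3,
        fst=0.3,
        n_snps=120,
        n_ssr=15,
        snp_missing_rate=0.05,
        ssr_missing_rate=0.05,
        n_qtl_per_trait=8,
        seed=42,
    )
    ssr, snp, f1, design, pheno, meta, truth = simulate_study(cfg)
    return {
        "config": cfg,
        "ssr": ssr,
        "snp": snp,
        "f1": f1,
        "design": design,
        "pheno": pheno,
        "meta": meta,
        "truth": truth,
    }


def random_snp_panel(rng, n_samples=6, n_sites=20, missing=0.15):
    """A random SNP panel (possibly heterozygous) for oracle comparisons."""
    dosage = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    mask = rng.random((n_samples, n_sites)) < missing
    dosage[mask] = -1
    sites = pd.DataFrame(
        {
            "chrom": ["Chr01"] * n_sites,
            "pos": np.arange(1, n_sites + 1) * 100,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    samples = [f"S{i}" for i in range(n_samples)]
    return SNPGenotypes(samples=samples, sites=sites, dosage=dosage)


def random_ssr_panel(rng, n_samples=6, n_markers=20, missing=0.15):
    """A random SSR panel with 1-4 alleles per profile-pool per marker."""
    samples = [f"S{i}" for i in range(n_samples)]
    calls = np.empty((n_markers, n_samples), dtype=object)
    for m in range(n_markers):
        n_alleles = rng.integers(2, 5)
        codes = 100 + 2 * np.arange(n_alleles)
        for i in range(n_samples):
            if rng.random() < missing:
                calls[m, i] = None
            else:
                k = rng.integers(1, 3)
                calls[m, i] = frozenset(
                    int(c) for c in rng.choice(codes, size=k, replace=False)
                )
    markers = pd.DataFrame(
        {
            "marker": [f"SSR{m}" for m in range(n_markers)],
            "chrom": ["Chr01"] * n_markers,
        }
    )
    return SSRGenotypes(samples=samples, markers=markers, calls=calls)
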