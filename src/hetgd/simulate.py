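"""Synthetic inbred-panel generator with known genetic ground truth.

The generator emulates the statistical structure of an upland-cotton hybrid
study: a panel of fully inbred parents drawn from a few origin
subpopulations (elite / historic / exotic cultivar groups), genotyped with
multi-allelic SSR markers and biallelic SNPs, crossed in a complete NC II
factorial (every male with every female), and phenotyped for quantitative
traits across year x site environments.

Genetic model
-------------
SNP allele frequencies follow the Balding-Nichols construction: a shared
ancestral frequency ``p`` per site, and per-subpopulation frequencies drawn
from ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with divergence ``F`` (``fst``).  SSR
allele frequencies use the Dirichlet analogue.  Parents are fully homozygous,
so an F1 genotype is the unordered pair of its parents' single alleles, and
F1 heterozygosity at a site is exactly "the parents differ there" -- the
mechanism that ties identity-by-state distance to dominance-driven heterosis.

Phenotypes follow an additive + dominance architecture: for entity *i* and
trait *t*,

    y_it(env) = mu_t + sum_l a_l x_il + sum_l d_l h_il + eps,

with ``x in {-1, 0, +1}`` coding the two homozygotes (0 for a heterozygote),
``h in {0, 1}`` flagging heterozygosity at QTL *l*, and i.i.d. Gaussian
environment noise per year x site.  With all ``d_l = 0`` the F1 equals its
mid-parent value in expectation, so mid-parent heterosis is pure noise; with
``d_l > 0`` the F1's advantage grows with the number of heterozygous QTLs,
which in turn tracks parental genetic distance.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, ParentMeta, SNPGenotypes, SSRGenotypes

__all__ = [
    "TRAITS",
    "TRAIT_MEANS",
    "PANEL_COMPOSITION",
    "SimConfig",
    "SimTruth",
    "ConfigurationError",
    "DesignError",
    "simulate_parents",
    "make_ncii_design",
    "derive_f1_genotypes",
    "simulate_phenotypes",
    "simulate_study",
]

#: The ten yield and fiber-quality trait codes carried through the pipeline.
TRAITS = ("PH", "BW", "LP", "BN", "FL", "FS", "MIC", "FU", "FE", "SCI")

#: Baseline trait means in conventional units (cm, g, %, count, mm, cN/tex...).
TRAIT_MEANS: dict[str, float] = {
    "PH": 95.0,
    "BW": 5.2,
    "LP": 39.0,
    "BN": 16.0,
    "FL": 29.0,
    "FS": 29.0,
    "MIC": 4.5,
    "FU": 84.0,
    "FE": 6.5,
    "SCI": 145.0,
}

#: Default panel composition by cultivar origin class (sums to 286 parents).
PANEL_COMPOSITION: dict[str, int] = {"elite": 136, "historic": 103, "exotic": 47}

# Relative default effect scales (fraction of the trait mean).  Chosen by
# closed form so the default architecture reproduces the qualitative
# heterosis profile of elite-by-diverse cotton factorials: with 20 QTL and
# mean QTL heterozygosity ~1/3, dominance 0.006*mu gives mean MPH ~ 4%,
# while additive 0.02*mu per QTL puts the best-parent margin (~E|P1-P2|/2)
# near the dominance gain, so best-parent heterosis straddles zero.
_ADDITIVE_REL = 0.020
_DOMINANCE_MEAN_REL = 0.006
_DOMINANCE_SD_REL = 0.004
_ENV_SD_REL = 0.030


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class DesignError(ValueError):
    """Invalid NC II cross design."""


def _per_trait(
    value: float | Mapping[str, float] | None,
    traits: Sequence[str],
    means: Mapping[str, float],
    rel_default: float,
) -> dict[str, float]:
    """Broadcast a scalar (or fill a default relative to trait means) per trait."""
    if value is None:
        return {t: rel_default * means[t] for t in traits}
    if isinstance(value, Mapping):
        return {t: float(value[t]) for t in traits}
    return {t: float(value) for t in traits}


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults reproduce the reference design: 4 male x 282 female inbred
    parents from 3 origin subpopulations (136 elite, 103 historic, 47
    exotic), 198 SSR markers carrying 1-10 alleles each, a desk-scale SNP
    set, ten traits with 20 QTL each, and 2 years x 2 sites of phenotyping.
    Effect-size fields accept a scalar (applied to every trait), a per-trait
    mapping, or ``None`` for defaults scaled to each trait mean (additive sd
    2%, dominance mean 0.6%, dominance sd 0.4%, environment sd 3% of the
    mean per QTL/record).
    """

    n_males: int = 4
    n_females: int = 282
    n_subpops: int = 3
    fst: float = 0.15
    n_snps: int = 1000
    n_ssr: int = 198
    ssr_allele_range: tuple[int, int] = (1, 10)
    snp_missing_rate: float = 0.02
    ssr_missing_rate: float = 0.02
    n_qtl_per_trait: int = 20
    additive_sd: float | Mapping[str, float] | None = None
    dominance_mean: float | Mapping[str, float] | None = None
    dominance_sd: float | Mapping[str, float] | None = None
    env_sd: float | Mapping[str, float] | None = None
    n_years: int = 2
    n_sites: int = 2
    traits: tuple[str, ...] = TRAITS
    trait_means: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_males", "n_females", "n_subpops", "n_snps", "n_ssr",
                     "n_qtl_per_trait", "n_years", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 <= self.fst < 1:
            raise ConfigurationError("fst must lie in [0, 1)")
        for name in ("snp_missing_rate", "ssr_missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        lo, hi = self.ssr_allele_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("ssr_allele_range must satisfy 1 <= min <= max")
        if self.n_qtl_per_trait > self.n_snps:
            raise ConfigurationError("n_qtl_per_trait cannot exceed n_snps")
        if not self.traits:
            raise ConfigurationError("at least one trait required")

    @property
    def n_parents(self) -> int:
        return self.n_males + self.n_females

    def means(self) -> dict[str, float]:
        base = dict(TRAIT_MEANS) if self.trait_means is None else dict(self.trait_means)
        missing = [t for t in self.traits if t not in base]
        if missing:
            raise ConfigurationError(f"no trait mean for {missing}")
        return {t: float(base[t]) for t in self.traits}

    def effect_scales(self) -> dict[str, dict[str, float]]:
        means = self.means()
        return {
            "additive_sd": _per_trait(self.additive_sd, self.traits, means, _ADDITIVE_REL),
            "dominance_mean": _per_trait(self.dominance_mean, self.traits, means, _DOMINANCE_MEAN_REL),
            "dominance_sd": _per_trait(self.dominance_sd, self.traits, means, _DOMINANCE_SD_REL),
            "env_sd": _per_trait(self.env_sd, self.traits, means, _ENV_SD_REL),
        }


@dataclasses.dataclass
class SimTruth:
    """Ground truth behind a simulated panel, for downstream verification."""

    subpop_of_parent: pd.Series  # accession id -> subpopulation label
    qtl_sites: dict[str, np.ndarray]  # trait -> SNP site indices
    additive_effects: dict[str, np.ndarray]
    dominance_effects: dict[str, np.ndarray]
    trait_means: dict[str, float]

    def __post_init__(self) -> None:
        for t, sites in self.qtl_sites.items():
            n = len(sites)
            if len(self.additive_effects[t]) != n or len(self.dominance_effects[t]) != n:
                raise ValueError(f"effect lists for {t} must match QTL count")


def _origin_counts(n_parents: int) -> dict[str, int]:
    """Allocate origin classes proportionally to the default composition.

    Largest-remainder apportionment of the 136/103/47 reference fractions.
    """
    total = sum(PANEL_COMPOSITION.values())
    quotas = {k: n_parents * v / total for k, v in PANEL_COMPOSITION.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    rem = n_parents - sum(counts.values())
    order = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:rem]:
        counts[k] += 1
    return counts


_CHROMS = [f"Chr{i:02d}" for i in range(1, 27)]
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
_SNP_SPACING = 50_000


def _parent_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    width = max(3, len(str(config.n_females)))
    males = [f"M{i+1}" for i in range(config.n_males)]
    females = [f"F{str(i+1).zfill(width)}" for i in range(config.n_females)]
    return males, females


def simulate_parents(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SSRGenotypes, SNPGenotypes, ParentMeta, SimTruth]:
    """Simulate a structured panel of fully inbred parents.

    The RNG stream is consumed in a fixed, documented order: (1) SNP ancestral
    frequencies, (2) per-subpopulation SNP frequencies, (3) parent SNP
    alleles, (4) SNP missingness, (5) SSR allele counts, (6) SSR ancestral
    frequencies, (7) per-subpopulation SSR frequencies, (8) parent SSR
    alleles, (9) SSR missingness, (10) QTL positions and effects per trait.

    Returns the SSR panel, SNP panel, parent metadata (origin class, role,
    subpopulation) and the :class:`SimTruth` ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _simulate_parents(config, rng, inject_missing=True)


def _simulate_parents(
    config: SimConfig, rng: np.random.Generator, inject_missing: bool
) -> tuple[SSRGenotypes, SNPGenotypes, ParentMeta, SimTruth]:
    males, females = _parent_ids(config)
    parents = males + females
    n, k = config.n_parents, config.n_subpops

    # Origin classes: males are elite by construction; females fill the
    # remaining quota in blocks (elite, historic, exotic).
    counts = _origin_counts(n)
    female_origins = (
        ["elite"] * max(0, counts["elite"] - config.n_males)
        + ["historic"] * counts["historic"]
        + ["exotic"] * counts["exotic"]
    )
    female_origins = (female_origins + ["exotic"] * n)[: config.n_females]
    origins = ["elite"] * config.n_males + female_origins

    # Subpopulations: with 3 subpopulations they coincide with origin class;
    # otherwise females cycle through subpopulations (males join subpop 1).
    origin_index = {"elite": 0, "historic": 1, "exotic": 2}
    if k == 3:
        subpop_idx = np.array([origin_index[o] for o in origins])
    else:
        subpop_idx = np.array(
            [0] * config.n_males + [i % k for i in range(config.n_females)]
        )
    subpop_labels = [f"subpop{i+1}" for i in subpop_idx]

    # --- SNPs (Balding-Nichols) ---
    p_anc = rng.uniform(0.05, 0.95, size=config.n_snps)
    if config.fst == 0:
        p_sub = np.tile(p_anc, (k, 1))
    else:
        ratio = (1 - config.fst) / config.fst
        p_sub = rng.beta(p_anc * ratio, (1 - p_anc) * ratio, size=(k, config.n_snps))
    carries_alt = rng.random((n, config.n_snps)) < p_sub[subpop_idx, :]
    dosage = np.where(carries_alt, 2, 0).astype(np.int8)
    if inject_missing and config.snp_missing_rate > 0:
        miss = rng.random((n, config.n_snps)) < config.snp_missing_rate
        dosage[miss] = MISSING

    chrom_blocks = np.array_split(np.arange(config.n_snps), min(26, config.n_snps))
    chroms, positions = [], []
    for b, block in enumerate(chrom_blocks):
        if len(block) == 0:
            continue
        chroms.extend([_CHROMS[b]] * len(block))
        positions.extend(((np.arange(len(block)) + 1) * _SNP_SPACING).tolist())
    refs = [_ALLELE_PAIRS[j % 4][0] for j in range(config.n_snps)]
    alts = [_ALLELE_PAIRS[j % 4][1] for j in range(config.n_snps)]
    snp = SNPGenotypes(
        samples=parents,
        sites=pd.DataFrame(
            {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
        ),
        dosage=dosage,
    )

    # --- SSRs (Dirichlet analogue of Balding-Nichols) ---
    lo, hi = config.ssr_allele_range
    n_alleles = rng.integers(lo, hi + 1, size=config.n_ssr)
    calls = np.empty((config.n_ssr, n), dtype=object)
    for m in range(config.n_ssr):
        ka = int(n_alleles[m])
        codes = 150 + 2 * np.arange(ka)  # fragment-length style allele codes
        f_anc = rng.dirichlet(np.ones(ka))
        if config.fst == 0 or ka == 1:
            f_sub = np.tile(f_anc, (k, 1))
        else:
            ratio = (1 - config.fst) / config.fst
            f_sub = np.vstack(
                [rng.dirichlet(np.maximum(f_anc * ratio, 1e-6)) for _ in range(k)]
            )
        for i in range(n):
            a = rng.choice(ka, p=f_sub[subpop_idx[i]])
            calls[m, i] = frozenset({int(codes[a])})
    if inject_missing and config.ssr_missing_rate > 0:
        miss = rng.random((config.n_ssr, n)) < config.ssr_missing_rate
        calls[miss] = None
    ssr = SSRGenotypes(
        samples=parents,
        markers=pd.DataFrame(
            {
                "marker": [f"SSR{m+1:03d}" for m in range(config.n_ssr)],
                "chrom": [_CHROMS[m % 26] for m in range(config.n_ssr)],
            }
        ),
        calls=calls,
    )

    # --- trait architecture ---
    scales = config.effect_scales()
    means = config.means()
    qtl_sites, a_eff, d_eff = {}, {}, {}
    for t in config.traits:
        qtl_sites[t] = np.sort(
            rng.choice(config.n_snps, size=config.n_qtl_per_trait, replace=False)
        )
        a_eff[t] = rng.normal(0.0, scales["additive_sd"][t], config.n_qtl_per_trait)
        d_eff[t] = rng.normal(
            scales["dominance_mean"][t], scales["dominance_sd"][t],
            config.n_qtl_per_trait,
        )

    meta = ParentMeta(
        table=pd.DataFrame(
            {
                "origin": origins,
                "role": ["male"] * config.n_males + ["female"] * config.n_females,
                "subpop": subpop_labels,
            },
            index=pd.Index(parents, name="accession"),
        )
    )
    truth = SimTruth(
        subpop_of_parent=pd.Series(subpop_labels, index=parents, name="subpop"),
        qtl_sites=qtl_sites,
        additive_effects=a_eff,
        dominance_effects=d_eff,
        trait_means=means,
    )
    return ssr, snp, meta, truth


def make_ncii_design(
    male_ids: Sequence[str], female_ids: Sequence[str]
) -> pd.DataFrame:
    """Enumerate the complete NC II factorial: one cross per (male, female).

    Crosses are ordered female-major within male and carry deterministic ids
    ``"{male}x{female}"``.  Male and female id sets must be disjoint, each
    non-empty and duplicate-free.
    """
    males, females = list(male_ids), list(female_ids)
    if not males or not females:
        raise DesignError("male and female id lists must be non-empty")
    if len(set(males)) != len(males) or len(set(females)) != len(females):
        raise DesignError("duplicate parent ids in design")
    overlap = set(males) & set(females)
    if overlap:
        raise DesignError(f"ids used as both male and female: {sorted(overlap)}")
    rows = [
        {"cross": f"{m}x{f}", "male": m, "female": f}
        for m in males
        for f in females
    ]
    return pd.DataFrame(rows, columns=["cross", "male", "female"])


def derive_f1_genotypes(parents: SNPGenotypes, design: pd.DataFrame) -> SNPGenotypes:
    """Derive F1 SNP genotypes from homozygous parents by the Mendelian rule.

    At each site the F1 carries one allele from each (inbred) parent, so its
    dosage is the parental mean; the site is missing iff missing in either
    parent.  A heterozygous parent call is an error: the generator guarantees
    inbred parents, and the rule below is only valid for them.
    """
    lookup = {s: i for i, s in enumerate(parents.samples)}
    try:
        mi = np.array([lookup[m] for m in design["male"]])
        fi = np.array([lookup[f] for f in design["female"]])
    except KeyError as e:
        raise KeyError(f"design parent {e.args[0]!r} not genotyped") from None
    het = np.flatnonzero((parents.dosage == 1).any(axis=1))
    if het.size:
        bad = [parents.samples[i] for i in np.flatnonzero((parents.dosage == 1).any(axis=1))]
        raise ValueError(f"heterozygous parent calls found in: {bad[:5]}")
    d1 = parents.dosage[mi, :].astype(np.int16)
    d2 = parents.dosage[fi, :].astype(np.int16)
    f1 = ((d1 + d2) // 2).astype(np.int8)
    f1[(d1 == MISSING) | (d2 == MISSING)] = MISSING
    return SNPGenotypes(
        samples=design["cross"].tolist(),
        sites=parents.sites.copy(),
        dosage=f1,
    )


def simulate_phenotypes(
    parents: SNPGenotypes,
    f1s: SNPGenotypes,
    design: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate entity x trait x year x site phenotype records.

    Each entity (parent or F1) gets, per trait and environment,
    ``mu_t + sum a_l x + sum d_l h + Normal(0, env_sd)``; an entity with a
    missing genotype at any QTL of a trait has that trait flagged missing
    (NaN) in every environment.  Environment noise is drawn trait-major, then
    year-major, then site-major.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    entities = list(parents.samples) + list(f1s.samples)
    dosage = np.vstack([parents.dosage, f1s.dosage]).astype(np.int16)
    scales = config.effect_scales()
    records: list[pd.DataFrame] = []
    n_ent = len(entities)
    for t in config.traits:
        q = truth.qtl_sites[t]
        d_q = dosage[:, q]
        missing_any = (d_q == MISSING).any(axis=1)
        x = np.where(d_q == 1, 0, d_q - 1)  # -1 / 0 / +1 coding
        h = (d_q == 1).astype(np.int16)
        g = (
            truth.trait_means[t]
            + x @ truth.additive_effects[t]
            + h @ truth.dominance_effects[t]
        )
        g = np.where(missing_any, np.nan, g)
        sd = scales["env_sd"][t]
        for year in range(1, config.n_years + 1):
            for site in range(1, config.n_sites + 1):
                eps = rng.normal(0.0, sd, n_ent) if sd > 0 else np.zeros(n_ent)
                records.append(
                    pd.DataFrame(
                        {
                            "entity": entities,
                            "trait": t,
                            "year": year,
                            "site": site,
                            "value": g + eps,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


def simulate_study(
    config: SimConfig,
) -> tuple[SSRGenotypes, SNPGenotypes, SNPGenotypes, pd.DataFrame, pd.DataFrame, ParentMeta, SimTruth]:
    """Run the full generator with one shared RNG stream.

    Returns ``(ssr, snp, f1_snp, design, phenotypes, meta, truth)``.
    Phenotypes are simulated from the *complete* genotypes -- in the field a
    plant's phenotype does not depend on whether its genotype call succeeded
    -- and missingness is injected afterwards into the released genotype
    panels (F1 genotypes inherit missingness from their parents).  Stage
    (and hence RNG consumption) order: complete parents -> design -> F1 ->
    phenotypes -> SNP missingness -> SSR missingness.
    """
    rng = np.random.default_rng(config.seed)
    ssr, snp, meta, truth = _simulate_parents(config, rng, inject_missing=False)
    males = [s for s in snp.samples if meta.table.loc[s, "role"] == "male"]
    females = [s for s in snp.samples if meta.table.loc[s, "role"] == "female"]
    design = make_ncii_design(males, females)
    f1_complete = derive_f1_genotypes(snp, design)
    pheno = simulate_phenotypes(snp, f1_complete, design, truth, config, rng=rng)
    if config.snp_missing_rate > 0:
        miss = rng.random(snp.dosage.shape) < config.snp_missing_rate
        snp.dosage[miss] = MISSING
    if config.ssr_missing_rate > 0:
        miss = rng.random(ssr.calls.shape) < config.ssr_missing_rate
        ssr.calls[miss] = None
    f1 = derive_f1_genotypes(snp, design)
    return ssr, snp, f1, design, pheno, meta, truth
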