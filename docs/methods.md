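# Methods

## The analysis

The package analyzes NC II factorial hybrid panels: `n_m` male testers
crossed to `n_f` female lines (all inbred), genotyped with two marker
systems and phenotyped for quantitative traits in replicated environments.
The chain is: marker quality filters → pairwise parental genetic distance →
heterotic grouping → heterosis → stratified correlation of distance with
hybrid outcomes.

### Genetic distance

Two estimators, one per marker system.

**SSR (band sharing).** Each accession shows one band per marker when
homozygous, two when heterozygous.  For a pair (a, b), over the markers
scored in *both* accessions, `N_a` and `N_b` count bands in a and b and
`N_ab` counts bands shared per marker (summed panel-wide); then
`GD = 1 − 2·N_ab/(N_a + N_b)`.  Band identity is marker-scoped: the same
fragment length at two different markers is two different bands.

**SNP (identity by state).** Genotypes are stored as alternate-allele dosage
`d ∈ {0,1,2}`.  Per-site sharing between two diploid genotypes is the size
of the unordered allele-multiset intersection over two, which reduces to
`1 − |d₁ − d₂|/2`; IBS is its mean over pairwise-complete sites and
`GD = 1 − IBS`.  No allele-frequency weighting is applied.

Missing data is handled by pairwise-complete deletion in both estimators.
The per-pair count of usable markers/sites is recorded (`support`); a pair
with support 0 is *undefined* (NaN, with a warning), never 0.  For inbred
parents, the SNP GD between the two parents of a cross equals the expected
F1 heterozygosity over the genotyped sites — the identity connecting
distance to dominance-driven heterosis, asserted in the test suite.

### Filters

SNP sites are retained when missing rate ≤ 0.30 **and** MAF ≥ 0.05, both
inclusive at the boundary (a site at exactly 5% MAF survives).  MAF uses
non-missing allele counts (two per called accession); a site with zero calls
is treated as MAF 0.  Raising `min_maf` or lowering `max_missing` never adds
a site (nesting is tested).  SSR markers need ≥ 2 distinct observed alleles.

### Heterosis

Phenotype records (entity × trait × year × site) are averaged per entity ×
trait with an unweighted mean before any heterosis is computed — one
MPH/BPH per cross × trait, not per environment.  `MPH = (F1 − MP)/MP·100`,
`BPH = (F1 − HP)/HP·100`.  Rows with a missing F1 or parent mean are kept
and flagged `missing`; `MP = 0` or `HP = 0` flags `undefined`; negative
denominators compute as printed but carry `sign_caution` (ratio heterosis is
not meaningful there; all ten cotton traits are positive-valued).
Percentages are full precision internally, rounded (2 dp) only in reports.
For strictly positive phenotypes MPH ≥ BPH always, MPH/BPH are invariant to
parent swapping and to rescaling a trait — all property-tested.

### Heterotic grouping

UPGMA on the GD matrix.  The agglomeration is implemented explicitly (O(n³),
numpy) rather than delegated, because reproducibility demands a defined
tie-break: among minimum-distance candidate pairs, choose the one whose
lexicographically smallest member label sorts first.  scipy's average
linkage is used as an independent cross-check in the tests, never as the
implementation.  Cutting the k−1 highest merges yields exactly k groups
(UPGMA heights are monotone, so these are the last k−1 merges); group ids
are assigned by decreasing size, then lexicographic leader — group labels
are bit-reproducible under any input order.  Cuts at k and k+1 are nested
(refinement is tested).  Since GD exists between parents, female parents are
clustered and each cross inherits its female's group; with `m` males every
F1 group is `m ×` its female group.  Default `k`: 5 for SNP-based GD, 3 for
SSR-based; no automatic `k` selection.  Dendrograms export to Newick with
branch lengths equal to merge-height differences.

### Association

Pearson r on pairwise-complete pairs; two-sided p from
`t = r·√((n−2)/(1−r²))` with n−2 df.  Fewer than 3 complete pairs or zero
variance yields a flagged undefined result, never silent NaN propagation.
Correlations of GD with F1 / MPH / BPH are computed within each male
population — males are a design factor, and pooling across them would
conflate male general effects with the GD gradient.  Significance marks:
`**` p < 0.01, `*` p < 0.05.  Parent–hybrid correlations use the mid-parent
mean as the parent statistic (reported as `mid_parent` in the output).
Group contrasts (origin-class hybrid sets, cluster groups) use pairwise
Welch t-tests, Holm-adjusted within each trait at α = 0.05; Welch because
group sizes and variances are unequal by construction, Holm for exact
family-wise control without independence assumptions.

## The synthetic generator

### Model

Parents are fully inbred (homozygous), matching cultivar lines, which makes
F1 derivation deterministic: the F1 dosage is the parental mean, missing iff
either parent is missing, heterozygous exactly where the parents differ.

SNP structure follows Balding–Nichols: ancestral frequency
`p ~ U(0.05, 0.95)` per site; per-subpopulation frequency
`~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with divergence `F` = `fst` (at `F = 0`
all subpopulations share `p` exactly).  SSR markers use the Dirichlet
analogue over `k ~ U{1..10}` alleles.  Subpopulations correspond to the
three cultivar origin classes (elite / historic / exotic, reference
composition 136/103/47 of a 286-parent panel, apportioned by largest
remainder for other panel sizes; males are elite); for `n_subpops ≠ 3`
parents cycle through subpopulations.

Phenotypes: for entity i, trait t and environment e,

    y = μ_t + Σ_l a_l·x_il + Σ_l d_l·h_il + ε_e,   ε_e ~ N(0, σ_env²) i.i.d.

with `x ∈ {−1, 0, +1}` (homozygote coding, 0 when heterozygous),
`h ∈ {0, 1}` the heterozygosity flag at QTL l, QTLs drawn uniformly without
replacement from the genotyped SNPs, `a_l ~ N(0, σ_a)`,
`d_l ~ N(μ_d, σ_d)`.  Because `x` of an F1 is the mean of its parents'
codes, the additive part of an F1 equals its mid-parent value exactly: with
all `d_l = 0`, expected MPH is zero, and with `d_l > 0` the F1 advantage is
proportional to its heterozygous-QTL count — which tracks parental IBS
distance.  That is the causal chain the association stage probes.

`simulate_study` simulates phenotypes from the *complete* genotypes and
injects missingness afterwards into the released genotype panels (a field
phenotype does not depend on genotyping success); F1 genotypes are then
re-derived from the observed parents so their missingness is inherited.  The
op-level `simulate_phenotypes` keeps the stricter contract — an entity with
a missing genotype at any QTL of a trait has that trait flagged missing —
for callers who feed it observed genotypes directly.

### Defaults and their rationale

| parameter | default | why |
|---|---|---|
| `n_males × n_females` | 4 × 282 | reference factorial (1128 crosses) |
| origin composition | 136/103/47 | elite/historic/exotic panel of 286 |
| `fst` | 0.15 | moderate cultivar-group divergence |
| `n_snps` | 1000 | desk-scale stand-in for a dense SNP set |
| `n_ssr` | 198, 1–10 alleles | reference SSR panel richness |
| missing rates | 0.02 | post-filter call rates of array/GBS panels |
| `n_qtl_per_trait` | 20 | oligogenic quantitative traits |
| additive σ_a | 0.02·μ_t per QTL | parent CV ≈ 9%; sets best-parent margin |
| dominance μ_d | 0.006·μ_t per QTL | mean MPH ≈ 4% at h̄ ≈ 1/3 |
| dominance σ_d | 0.004·μ_t | spread in per-locus dominance |
| env σ | 0.03·μ_t | plot-level noise per year × site |
| environments | 2 years × 2 sites | replicated multi-environment trial |

Effect scales are relative to each trait mean so the ten traits (plant
height in cm through micronaire) behave comparably; scalars or per-trait
mappings override them.  The additive/dominance ratio was set by closed form
— 20 QTL × 0.006·μ × mean heterozygosity ≈ 4% MPH, and a best-parent margin
`E|P1−P2|/2 ≈ 4–5%·μ` so BPH straddles zero — reproducing the qualitative
heterosis profile of elite-by-diverse cotton factorials (strong mid-parent,
weak best-parent heterosis) rather than fitted to any dataset.

One shared RNG stream (numpy PCG64, seeded once) drives a documented
consumption order; every output is bit-identical across runs for a fixed
seed.

### What the generator does *not* emulate

No linkage or recombination maps (QTLs are exchangeable sites), no
epistasis, no genotype × environment interaction beyond i.i.d. noise, no
marker-clustered missingness, no selection or pedigree structure within
subpopulations, and origin classes map onto clean Balding–Nichols
subpopulations rather than the admixed structure of real germplasm.
Passing tests therefore demonstrate that the *estimators and the causal
dominance mechanism* behave correctly, not that any particular real panel
will show strong GD–heterosis correlations — with sparse QTL sets the
within-male coupling between GD and QTL heterozygosity can even invert for
individual traits (a male carrying locally rare alleles at
subpopulation-differentiated QTLs makes *distant* females less heterozygous
there), which is why trait-level GD–MPH correlations are intrinsically
noisy while the trait-averaged signal is robust.

## Numerical and statistical choices

* Thresholds inclusive (≤ missing, ≥ MAF); ties retained.
* Undefined distances/correlations propagate as flagged NaN, never 0.
* VCF positions are 1-based; density windows are half-open `[k·w, (k+1)·w)`.
* UPGMA ties broken lexicographically; group ids by size then leader.
* Heterosis: environment aggregation precedes ratio formation; full
  precision until report time.
* Simulation-based checks use the replicate (seed) as the independent unit
  for standard errors: all crosses of a male share that male's phenotype
  noise, so cross-level SEs would be anticonservative.
* Problem sizes in the test suite and acceptance script are desk-scale
  choices (hundreds of SNPs, 10–20 replicates) selected so the full chain —
  including twenty 4 × 282 factorials — runs in well under a minute while
  leaving the tested effects many standard errors away from their
  thresholds.

## Known limitations

* The band-sharing reading of the SSR formula counts bands (the standard
  Nei–Li similarity); with fully inbred parents it reduces to the fraction
  of markers with different alleles.
* Ratio heterosis is ill-behaved near zero denominators; rows are flagged
  rather than dropped, and downstream summaries use defined rows only.
* Group counts k are user choices; no gap statistic or model-based k
  selection is provided.
* No combining-ability (GCA/SCA) decomposition, BLUP, or genomic
  prediction — the scope ends at marker-distance-based assessment.
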