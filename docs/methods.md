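# Methods

`sweepset` implements, as a tested pipeline, the computational core of a
selection scan for oligogenic adaptation: forward simulation of selection on
standing variation in a four-population out-of-Africa demography, per-SNP
Weir–Cockerham F<sub>ST</sub>, empirical-tail outlier classification,
SNP-density-matched background gene sets, the SUMSTAT set statistic with a
background-set null, chi-squared tail-enrichment tests, and a power-analysis
harness. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Forward simulator

The engine is a discrete-generation Wright–Fisher simulator of one `L`-bp
region (default 100 kbp; the power experiments use 50 kbp). Haplotypes of one
generation are rows of a byte matrix over the currently segregating sites;
each next generation is produced by gather operations. Per meiosis the number
of crossovers is Poisson with mean `r·(L−1)` (uniform breakpoints; the
transmitted gamete alternates between the two parental haplotypes), and new
mutations arise as Poisson(`μ·L`) per gamete under the infinite-sites model on
integer coordinates, re-drawing collisions. Defaults
`μ = r = 1.25e−8 /bp/generation`. Columns fixed or lost in the whole
metapopulation are swept periodically; the tagged selected column is always
retained. When numba is importable the per-generation inner loops run as
compiled kernels (one for isolated neutral populations — the ancestral
burn-in — and one for the multi-population phase with migration, founding
events and selection); a vectorized numpy path implements the identical model
and is used otherwise. Both paths are exercised by the drift calibration
tests.

### Demography

The four sampled populations are AFR, EUR, EAS and AMR, with an internal
out-of-Africa bottleneck population (OOA). Exact values of the study this
design follows are not published at this granularity, so the default model is
a documented Gravel-2011-like stand-in, not a reproduction:

| event | time | size |
|---|---|---|
| ancestral burn-in starts | 1.66 Mya | N = 7,310 |
| ancestral expansion | 148 kya | N = 14,474 |
| forward phase starts | 70 kya | AFR = 14,474 |
| OOA splits from AFR | 57.1 kya | N = 1,861 |
| EUR/EAS split (OOA ends) | 25.8 kya | EUR 1,032 (g = 0.38%/gen), EAS 554 (g = 0.48%/gen) |
| AMR splits from EAS | 14 kya | 800 (g = 0.5%/gen) |

Migration (per generation, symmetric): AFR↔OOA 15e−5, AFR↔EUR 2.5e−5,
AFR↔EAS 0.78e−5, EUR↔EAS 3.11e−5; AMR exchanges no migrants (its post-split
isolation is a simplification). Generation time is 28 years, so that 500
generations correspond to 14 kya and 2,000 to 56 kya. All of this is
configurable through `build_demography`.

### Selection on standing variation

At the onset time (grid 1, 5, 10, 40 kya) one segregating allele with focal
frequency in [0.10, 0.15] is tagged uniformly at random and given additive
fitness 1, 1+hs, 1+s (`h = 0.5` by default). The selection coefficient is
either fixed or drawn per replicate from U[0.001, 0.005]; that range is the
default because the study's power curves are reported for selection strengths
in that interval. Selection acts only along the focal population's *lineage*:
for onsets predating a split, the ancestor carrying the focal lineage is
selected until the split, and only the focal branch afterwards — local
adaptation, with migrants carrying the allele neutrally. Replicates with no
eligible allele at onset, or whose tagged allele is lost (retention rule
`not_lost`; fixation is allowed and flagged), are discarded and re-simulated
with a fresh seed stream under a bounded retry budget, and the attempt count
is recorded.

### Rescaling

All power work uses the standard speed rescaling `Q`: sizes and times divided
by `Q`, while `μ`, `r`, `s` and migration rates are multiplied by `Q`,
preserving 4Nμ, 4Nr, 2Ns and 4Nm up to rounding. The desk scale is `Q = 20`
with 50-kbp regions. A calibration test checks that `Q = 1` and `Q = 10` give
statistically indistinguishable segregating-site counts and diversity on a
small instance; rescaling is still an approximation (it coarsens time and
exaggerates per-generation drift jumps), which is one reason desk-scale power
numbers carry Monte-Carlo and model error.

### Validation oracles

The engine is checked against closed forms: heterozygosity decay
`E[H_t] = H_0 (1 − 1/2N)^t`, neutral fixation probability ≈ initial
frequency, equilibrium diversity `E[π] ≈ 4Nμ(1 − e^{−t/2N})` per bp, and the
deterministic one-locus selection recursion in the large-N limit. The
remaining drift-scale deviation from the deterministic recursion at moderate
N matches an independently coded brute-force single-locus simulator, i.e. it
is finite-population physics, not implementation error.

## F<sub>ST</sub>

Per-site two-population Weir & Cockerham (1984) θ = a/(a+b+c) from the three
variance components, using per-site sample sizes (missing genotypes excluded
site by site), allele frequencies and observed heterozygosities. Raw θ is
reported, negatives included, because downstream tail ranking must preserve
the estimator's ordering; sites with a zero denominator (e.g. monomorphic in
both samples) are undefined (NaN), which is distinct from θ = 0, and never
enter empirical distributions. The scan pairs every test population with the
African reference (the Yoruba role in real data); the African focal
population, needing a non-focal out-pair, is paired with the European
population.

## Empirical outlier classification

For each channel (an F<sub>ST</sub> pair, or an external higher-is-stronger
score such as a genealogy-based −log10 p supplied as a TSV), the empirical
p-value of a SNP is `#{scores ≥ v} / N` over the genome-wide score set —
closed tail, so the maximum scores 1/N, ties share a p-value, and p = 0 never
occurs. SNPs with p ≤ 0.001 are *candidate* SNPs, p ≤ 0.05 *significant*
SNPs, with a stringent 0.0001 tier. The closed boundary (≤ rather than <) is
a deliberate choice where the source wording alternates; with continuous
scores the two differ only on ties. Gene slices take SNPs within 10 kbp of
the gene body (closed interval on 1-based coordinates, clipped at the
chromosome start).

## Background gene sets

Each catalog gene receives 1,500 candidate regions starting at distinct
random annotated gene starts, matched in exact length; candidates running off
the chromosome end are ineligible, as are candidates overlapping the focal
gene ±10 kbp (self-overlap would leak signal into the null; other genes are
allowed, as the sampling is otherwise agnostic). The 1,000 regions whose SNP
density — computed in a designated reference population, fixed per run and
recorded in the manifest — is closest to the gene's own are kept, ties broken
by lower start coordinate. Background *sets* mirror each micronutrient set's
gene count, each slot drawn uniformly from the member gene's pool. Starts are
drawn without replacement; whether the original study replaced them is
unstated, and the choice only matters for tiny gene universes.

## Set-level tests

`tail_enrichment` compares the observed number of tail SNPs O in a set's
slice with E = αT by a 1-df chi-squared on the two cells, without continuity
correction; percent excess 100(O−E)/E and an exact binomial cross-check are
reported. The approximation degrades beyond ~3σ deviations and for E < 5 (a
warning fires).

SUMSTAT sums, over member genes, the empirical p-value of each gene's
top-ranking SNP; smaller sums mean stronger evidence, so significance is the
lower tail of the same sum over background sets, with the permutation
pseudocount `p = (1 + #{null ≤ v}) / (n + 1)` and tier flags at 5%, 1%, 0.1%
and 0.01%. Summing the p-values themselves (rather than statistic values, as
in some earlier set-test literature) is the operative definition here. Genes
with no scored SNP are dropped with a logged count. Bonferroni thresholds are
computed from an explicit test count — 269 genes × 40 populations and 13
micronutrients × 40 populations reproduce the conventional printed values
4.65e−6 and 9.62e−5 — because the correction denominator is an analysis
decision, not a constant.

## Power analysis

Detection thresholds come from *neutral simulations*, not within-dataset
tails: a selected SNP is detected when its F<sub>ST</sub> reaches the 95th
percentile of the pooled per-SNP scores of the matched neutral replicates for
the same population pair. TPR is the percentage of tagged selected SNPs
detected (replicates whose tagged allele is absent from the sample, or whose
tagged-site θ is undefined for the scored pair, are excluded and counted);
FNR = 100 − TPR; FPR is measured on held-out neutral replicates. Set-level
power assembles test sets of a given size and selected fraction from the
region pools, scores each region by the empirical p of its top SNP against
the pooled neutral distribution, and calls a set detected when its sum falls
in the lower 5% tail of 1,000 neutral-set sums (drawn from the neutral region
pool with re-use across sets — at desk scale the pool is far smaller than the
original study's, which adds correlation between null sets but leaves their
marginal distribution intact).

Problem sizes: the shipped experiments use Q = 20, 50-kbp regions, 150
selected + 150 matched neutral replicates per focal population (200 for the
African cell backing the monotonicity checks), 50 test sets and 1,000 null
sets. These sizes make the experiments reproducible on a single CPU while
keeping binomial confidence intervals on a TPR of order ±4 percentage points
at n = 150; every result records its scale so desk-scale numbers are never
conflated with full-scale ones.

## What the synthetic data does and does not show

The generator emulates drift, migration, bottlenecks, growth, recombination
and selection on standing variation with a known tagged site — the features
the statistics respond to. It does not emulate: background selection or
deleterious variation, mutation-rate or recombination-rate heterogeneity,
genotyping error and missingness structure, phasing error, deep African
population structure, or archaic introgression. Passing power tests
therefore demonstrate the *statistical machinery* at the stated scale under
the stand-in demography; they do not certify power for any real cohort, and
the demographic stand-in means absolute TPR values should be read as
desk-scale reproductions of the study design, not as new population-genetic
estimates. The set-level experiments are the most scale-sensitive: with
50-kbp regions and 150-region pools, each neutral region's top SNP already
reaches a small empirical p, so sets diluted with neutral regions separate
from the null far less cleanly than they would at full scale (larger
regions, thousands of pooled replicates), and the mixed-set true-positive
rate is correspondingly depressed.

## Numerical and degenerate-input choices

- Empirical p-values and SUMSTAT nulls never return 0 (closed tails,
  pseudocount); undefined θ is NaN and excluded everywhere.
- Half-calls in VCF genotypes are missing; a site's missingness filter is
  strictly greater than the threshold (1 missing call in 11 samples, 9.1%,
  survives a 10% filter).
- BED is 0-based half-open, VCF 1-based: `chr1 0 100` covers positions
  1..100.
- Monomorphic-in-sample columns are dropped from simulated regions; if the
  tagged site is among them the region is returned with the event recorded in
  the metadata and the power harness excludes that replicate.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` fan-out; identical config and seed give
  byte-identical outputs (the numba and numpy engine paths each deterministic,
  but not byte-identical to one another since they consume different random
  streams).
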