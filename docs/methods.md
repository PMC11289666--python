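# Methods

This document describes the statistical models, algorithms, defaults, and
deliberate simplifications behind each module. Formulas use `p` for the
reference-allele frequency, `q = 1 − p` for the alternate, and genotypes
coded 0/1/2 as alternate-allele counts (−1 = missing).

## 1. De-lifing fecundity (`hfcpipe.fecundity`)

De-lifing attributes to each individual its marginal contribution to
population growth. Only the fecundity component is used: in year *t* a
female's contribution is

```
c_it = (b_it − f_t) / (N_t − 1)
```

- `b_it ∈ {0, 1}` — whether she calved within a sliding window of ±1 year
  of *t* (configurable `window`). The window absorbs the species'
  multi-year calving cycle: a female mid-cycle is not scored as failing in
  the off years. Calving events outside the analysis range still count
  toward windows overlapping the boundary.
- `f_t` — population fecundity, calves observed / adult females alive in
  year *t*. The census (`YearlyPopulationRecord`) may cover more females
  than are genotyped.
- `N_t` — adult females alive in year *t*.

A female's phenotype is the mean of `c_it` over the years in which she is
**adult and alive** inside the analysis range (default 1990–2020). Adult
onset: age 9 when the birth year is known; 8 years after first sighting
otherwise; a first calving before that threshold makes her adult in the
calving year. Females with fewer than 6 eligible years (default
`min_years`) are reported with `included = False` and a NaN phenotype.

Centering identity: with `window = 0` and a census that counts exactly the
analyzed females, `Σ_i c_it = 0` for every year, because `Σ_i b_it = N_t
f_t`. This exact identity is the main correctness oracle; it necessarily
breaks when the window widens (a calf is credited to up to three years) or
when the census includes unanalyzed females.

## 2. Variant filtering and concordance (`hfcpipe.variants`)

Genotypes are read with `cyvcf2` (0/1/2 alternate-allele dosage, −1
missing; per-genotype DP if present) and written as plain-text VCF v4.2;
the round trip is byte-identical for files produced by the writer.

The site-filter cascade applies rules in a **pinned order**, attributing
each removed site to the *first* rule it fails:

1. **Depth mask** — genotypes with DP below `min_genotype_depth` are set
   missing (genotype-level, not site-level).
2. **Missingness** — sites with a missing fraction > 0.2 (after the depth
   mask) are removed.
3. **Repeat mask** — sites inside BED intervals (0-based, half-open;
   VCF positions are 1-based) are removed.
4. **Biallelic** — sites flagged non-biallelic are removed.
5. **MAF** — kept only if minor-allele frequency > 0.01.
6. **MAC** — kept only if minor-allele count ≥ 3.

The order matters (a site may pass raw missingness but fail it after depth
masking) and the cascade is idempotent: filtering its own output removes
nothing. The report's per-rule counts plus retained sites always sum to
the input count.

Duplicate concordance compares the two calls of each (original, duplicate)
pair at sites where **both** are non-missing, reporting assessed count,
discordant count, and their ratio.

## 3. Genome-wide inbreeding coefficients (`hfcpipe.inbreeding`)

All coefficients use only each individual's typed sites. Allele
frequencies come from the full sample; `n_j` is the number of typed
individuals at site *j*.

- **F (homozygosity excess)**: `F = (O_hom − E_hom) / (L − E_hom)` with
  `E_hom = Σ_j [1 − 2 p_j q_j · 2n_j/(2n_j − 1)]` over the individual's
  typed sites — the small-sample–corrected expected homozygosity under
  Hardy–Weinberg. Undefined (NaN + warning) when every typed site is
  monomorphic.
- **sMLH (standardized multi-locus heterozygosity)**: observed
  heterozygosity divided by the mean population heterozygosity at the
  individual's typed loci. Under complete data the population mean of sMLH
  is exactly 1 (each locus contributes its own mean).
- **IR (internal relatedness)**: `IR = (2H − Σ f_i) / (2N − Σ f_i)`, where
  `H` is the number of homozygous typed loci, `N` the number of typed
  loci, and `Σ f_i` sums the frequencies of the alleles the individual
  carries (the homozygous allele counted once per locus). Negative values
  indicate outbreeding.
- **HL (homozygosity by loci)**: `HL = Σ_hom E_j / (Σ_hom E_j + Σ_het
  E_j)` with `E_j = 2 p_j q_j`, weighting loci by information content.

## 4. HBD segments (`hfcpipe.hbd`)

A hidden Markov model with `K = 11` states per individual: 10 HBD classes
with rates `R_k = 2^k` (k = 1…10; higher rate ⇒ shorter, older segments)
plus one non-HBD class sharing the rate of the last HBD class (`2^10`).
Genetic distance between adjacent markers is `d = Δbp × 10⁻⁸ ×
map_rate_cm_per_mb` Morgan (default 1 cM/Mb). Transitions factor as "stay
or reset to the mixing distribution π":

```
T_ij = exp(−R_i d) δ_ij + (1 − exp(−R_i d)) π_j
```

This structure gives an O(K)-per-step forward–backward with scaling,
vectorized across individuals; emissions and survival probabilities per
scaffold are precomputed once and reused across EM iterations.

Emissions with genotyping-error rate ε: in an HBD state the two alleles
are one draw, so `P(g) ∝ {(1−ε)p + εq, ε, (1−ε)q + εp}` normalized (a het
can only arise by error); in the non-HBD state `P(g) = (1−ε)·HW(g) +
(ε/2)(1 − HW(g))`. Missing genotypes emit 1 in every state.

**Fitting.** Only the per-individual mixing weights π are estimated, by
exact EM on the expected "reset" counts (the initial state draw plus every
re-entry event), which guarantees a monotone log-likelihood; class rates
stay fixed on the exponential grid. A warning flags individuals whose data
(< K informative sites) cannot dominate the prior, and non-convergence
after the iteration cap.

**Decoding and F_HBD.** Markers with aggregate HBD posterior > 0.5 (or a
Viterbi path, optionally) are merged into segments spanning the first to
last marker of each run; `F_HBD` is the summed length of segments
**strictly longer** than 100 kb divided by the total reference length.
Segment endpoints are marker positions, so very sparse panels
underestimate segment span.

## 5. Association (`hfcpipe.association`)

**Fitness regression.** `y_i ~ Normal(β0 + β1 x_i, σ)` on complete cases
(≥ 5 required), both variables z-transformed by default (ddof = 1), so β1
is on the correlation scale.

- `flat` prior: the reference prior `p(β, σ²) ∝ 1/σ²` gives a
  normal–inverse-gamma posterior sampled **exactly** — `σ² = SSR / χ²(n−2)`
  and `β | σ²` normal around the least-squares solution. The β1 marginal
  is then the classical scaled, shifted Student-t on n−2 degrees of
  freedom, which the tests verify by Kolmogorov–Smirnov.
- `weak` prior: Normal(0, 10) on β0 and β1, Half-Normal(10) on σ, sampled
  with the `emcee` affine-invariant ensemble (8 walkers). `warmup` and
  `iterations` count ensemble steps; retained draws are pooled across
  walkers. Convergence requires the kept chain length to exceed 50× the
  integrated autocorrelation time and split R-hat (across walkers, via
  arviz) below 1.1; failure produces a warning and `converged = False`,
  never a silent pass.

Intervals are 95% highest-density intervals (shortest contiguous interval
containing the mass), computed from sorted draws.

**Per-SNP scan.** Ordinary least squares of the phenotype on allele count,
vectorized across sites; two-sided t-test on the slope. Individuals
missing a genotype are dropped at that site only; sites monomorphic among
complete cases (or with < 3 of them) are skipped and counted. P-values of
exact fits are floored at the smallest positive float. The lowest-p sites
(default 20) are flagged as top hits. No multiple-testing correction is
applied — the scan mirrors an exploratory design; interpret p-values
accordingly.

**Annotation.** Genes (from a GFF3, parsed record-by-record with gffutils;
malformed lines are counted and skipped) are matched to each site when
their interval intersects `[pos − 100 kb, pos + 100 kb]` (boundary
inclusive); distance is 0 inside the gene, else the gap to the nearest
gene edge. Sites with no gene in range keep a row with empty gene fields.

## 6. Simulator (`hfcpipe.simulate`)

The generator produces ground-truth-labelled data shaped like a long-term
whale study. It is a *direct* generative model, not a population-genetic
(coalescent) simulation: sites are independent given F_true, and HBD
tracts are planted rather than arising from pedigree structure.

**Demography and calving.** Each female gets a birth year, optional known
birth (default 70% known), a yearly death hazard (default 0.02), and an
individual calving propensity `η_i ~ Normal(0, 0.5)` on the log-odds
scale. When she is adult (age ≥ 9) and at least `base_calving_cycle` (3)
years past her last calf, she calves with probability
`sigmoid(logit(1/3) + η_i + β·F_true_i)`; `inbreeding_effect_beta` is the
planted effect (0 = null), and the degenerate base probabilities 0 and 1
are preserved exactly so deterministic limits are testable. The census
additionally includes unsampled females (default 30) so population counts
exceed the genotyped cohort, as in real monitoring data.

**Genotypes.** Site frequencies `q ~ Beta(0.5, 0.5)` truncated to
[0.01, 0.99] (a post-MAF-filter panel shape), placed uniformly over 21
scaffolds of 10 Mb. Outside HBD tracts genotypes follow the
inbreeding-adjusted law `P(hom-ref) = p² + F pq`, `P(het) = 2pq(1 − F)`,
`P(hom-alt) = q² + F pq` with `F = F_true_i`. HBD tracts arrive per class
as a Poisson process along each scaffold (`rate per Morgan` configurable)
with exponential lengths of mean `1/2^class` Morgan; inside a tract both
alleles are one draw. Genotyping error flips a call to one of the other
two states with probability 0.001; missingness (0.1) and
negative-binomial depth (mean 20, dispersion 5) are layered per genotype.

**Reproducibility.** All randomness derives from `SimConfig.seed` through
`numpy.random.default_rng` (PCG64) with separate child streams for
demography, genetic truth, and genotypes, so e.g. genotypes are identical
whether or not life histories are generated. Fixed seed ⇒ bit-identical
output.

**What it does not emulate**: linkage disequilibrium outside HBD tracts,
pedigree-consistent inheritance, male genetics, observation error in the
census, age-dependent fecundity, and sequencing artifacts beyond symmetric
genotype error.

## 7. Numerical and design choices

- Forward–backward uses per-site scaling (not log-space), with the scaled
  structure exploited for O(K) updates; posteriors sum to 1 to 1e-10 and
  match exhaustive enumeration to 1e-8 in tests.
- The flat-prior regression samples the conjugate posterior exactly
  instead of running MCMC — no convergence question, and the analytic
  marginal provides a sharp oracle.
- Expected-homozygosity uses the `2n/(2n−1)` small-sample correction, so
  F is centred near zero in outbred samples of modest size.
- The filter cascade reports first-failure attribution to keep counts
  disjoint and auditable; an alternative "all failing rules" attribution
  would double-count.
- CSV/VCF/BED/GFF3 I/O relies on pandas, cyvcf2, and gffutils rather than
  bespoke parsers; the VCF writer is bespoke only to guarantee a stable,
  minimal, byte-reproducible output format.

## 8. Limitations

- De-lifing here covers only the fecundity component of individual
  contributions, not survival.
- The HBD model estimates mixing weights only; rates are fixed on the
  exponential grid, so class assignment is a binned approximation of
  segment age.
- F_HBD from sparse panels is biased downward (segment ends are marker
  positions, and segments with < 2 covered markers are invisible).
- The GWAS scan fits no kinship or structure correction; on structured
  cohorts its p-values are anticonservative.
- Sample allele frequencies are plugged in as truth everywhere; with very
  small cohorts this is a real loss of information (e.g. HBD is
  unidentifiable from a single individual because every homozygous site
  appears fixed).
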