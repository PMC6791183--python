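# Methods

This note documents the statistical models the package implements, the
choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Traits and scales

The demography phenotype is [S, M, N]: proportions of sorted animals in
the small and medium body-length bins and the progeny count per
founding L4. S and M live on the 2-simplex (S + M ≤ 1, the large-bin
proportion being the remainder); N ≥ 0. Raw-scale containers enforce
these bounds (tolerance 1e-9); residual-scale tables (after assay-day
adjustment or simulation on the latent scale) relax them and carry an
explicit scale flag. Proportions are stored as decimals.

## RIAIL scan

**Pre-processing.** Lines with ≤ 5 progeny per founding worm are
removed before mapping (they carry no usable demography signal).
Assay-day adjustment takes the residuals of a multivariate regression
of the three traits on the day factor, which for a single factor is
exactly per-day centering; each trait's residuals sum to zero within
every day. A day represented by a single line is an error, not a
silently degenerate residual.

**Marker regression.** For each focal marker the three traits are
regressed jointly on an intercept, any retained covariate markers, and
the focal 0/1 genotype code. The focal hypothesis is tested with
Wilks' Λ. For a rank-1 hypothesis Λ has the closed form
Λ = 1 − (g̃′Ỹ)(Ỹ′Ỹ)⁻¹(Ỹ′g̃)/(g̃′g̃), with Ỹ and g̃ residualized
against the covariate design; the associated F is exact with
(p, v − p + 1) degrees of freedom, v = n − rank(design). This form
evaluates all markers in one pass of dense linear algebra, which is
what makes the permutation threshold cheap (a full 100-marker scan of a
250-line panel costs two small GEMMs). Pillai's trace is available as
an alternative report; for rank-1 hypotheses V = 1 − Λ and the F
statistics coincide, so the choice only matters for the multi-degree
epistasis comparisons, where Rao's F approximation for Λ is used.
Monomorphic markers and markers collinear with the covariates are
flagged and skipped. Missing genotype calls are excluded listwise per
fitted model.

**Genome-wide threshold.** Residuals of the current covariate model are
permuted jointly (a line's trait triple stays together) against the
genotypes; each permutation is rescanned and its genome-wide maximum
−log₁₀ p recorded; the threshold is the empirical (1 − α) quantile
(order statistic, ceiling index) of the maxima. Default 1,000
permutations, α = 0.05. Lines with a missing call at any scanned
marker are excluded from the permutation scan so every permutation sees
an identical line set; observed scans still use per-marker listwise
exclusion.

**Forward search.** Scan, take the maximum-score marker (ties broken by
lowest marker index for determinism), accept it as a covariate if its
score strictly exceeds that scan's threshold, rescan; stop otherwise or
at a hard cap of 20 retained markers (a runtime safety net, never
binding at panel scale). Permutations of scan *i* use substream *i* of
the settings seed, so the search is a deterministic function of data
and seed. Effects (CB4856-direction coefficient vectors), per-trait R²,
and per-QTL univariate nominal significance come from the joint
additive fit at the retained markers. Epistasis is assessed by Wilks
model comparisons of the additive model against (i) + all pairwise
products of QTL codes and (ii) + all higher-order products.

With 200 permutations and strict exceedance the realized genome-wide
type-I error is slightly above nominal by construction (the observed
maximum must beat the 190th of 200 permutation maxima, ≈ 11/201); the
acceptance check therefore uses a 3-binomial-SE band around 0.05 at 200
null panels.

## NIL pipeline

**Replicate extraction.** For each trait separately a linear mixed
model with a fixed intercept and random intercepts for assay day,
plate (coded nested in day), well position, and replicate population
(strain × day × passage) is fitted by REML (statsmodels MixedLM,
variance-components parameterization). The adjusted phenotype of a
replicate population is the grand mean plus its BLUP. Strain identity
is deliberately absent from the model so genetic signal flows into the
replicate BLUPs — the two-stage structure keeps the downstream
pairwise tests honest.

Two consequences are worth knowing. First, BLUPs shrink toward the
grand mean; because each replicate population occupies a single well
position within a day (the plate layout is replicated across plates),
the well-position and replicate components are only partially
identifiable and REML may apportion some replicate variance to wells,
attenuating estimated interval effects roughly uniformly. Strain-level
contrasts remain well estimated (the extraction tests assert r > 0.95
against truth at small scale), and the arrangement test is invariant to
uniform attenuation, but absolute effect magnitudes are conservative.
Second, designs where every well position hosts a single replicate
(few days, many positions) maximize this confounding; position reuse
across days restores identifiability.

**Interval tests.** Each of the m intervals is tested by comparing the
two adjacent strains that differ only in that interval: a two-group
MANOVA on the three traits (Wilks' Λ; at least 3 observations per
strain), with p-values from shuffling strain labels among the pooled
observations, p = (1 + #{Λ_perm ≤ Λ_obs}) / (1 + n_perm) so p is never
zero. The same label shuffles feed the three univariate F statistics.
Default 10,000 permutations per pair. Family-wise significance uses
Bonferroni: threshold α/m, i.e. 0.05/15 ≈ 0.003 for the 15-interval
ladder. The interval effect vector is the difference of adjusted
strain means in the CB4856 direction; by construction the m effects
telescope to the parental (all-CB4856 minus all-N2) difference.

## Arrangement test

Given effects e₁…e_m ordered left to right and a right-anchored ladder,
strain k's phenotype is the sum of the k right-most effects (all-N2
strain at 0, all-CB4856 at Σe). The statistic is the sample variance
(n − 1 denominator; the p-value is invariant to this choice) of the
m + 1 phenotypes. The null draws uniform random orderings of the same
effects with replacement; one-sided p = (1 + #{V ≤ V_obs})/(1 + n_perm)
with low variance as the alternative (antagonistic arrangement), a
two-sided variant doubling the smaller tail. Default 100,000 shuffles
(scaled for desk runtime; overridable). Exhaustive enumeration over
all m! orderings serves as the exact oracle up to m = 8; tie handling
uses a 1e-12 absolute + 1e-9 relative comparison tolerance so
bit-identical orderings of tied effects count symmetrically in both
routes.

## Polygeny simulations

Each simulation draws n_qtl distinct marker indices uniformly without
replacement (re-drawn every simulation) and i.i.d. effects from the
configured distribution (normal by mean/variance, uniform, or
resampling from an effect ladder), computes additive genetic values
over the genotype matrix, optionally adds Gaussian noise with variance
Vg(1 − h²)/h² so expected broad-sense heritability is h², and records
the across-line sample variance. For L balanced unlinked loci and
effect second moment σ² + µ², the expected variance is L(σ² + µ²)/4,
the closed form the tests pin (600 · 0.25 · (8.6 + 0.01) = 1291.5 for
the default normal(−0.1, σ² = 8.6)). The dense-effects experiment
defaults to genetic values only — comparing genetic variance against a
total observed variance is the conservative direction — with noise
available behind the h² flag. The matched model (100 loci, effect sd
4.5, h² = 0.5) additionally returns one retained simulated phenotype
table (progeny in the N slot, residual scale) that the scan can consume
univariately via `traits=("N",)`.

## Synthetic data

The generator reproduces the statistical structure the analyses assume,
not the biology that produced it.

* **RIAIL genotypes**: first-order Markov chain per chromosome;
  CB4856 probability at the first marker = founder allele frequency
  (default 0.5); switch probability between markers d cM apart
  r = ½(1 − e^(−2λd/100)) (Haldane), with one map-expansion multiplier
  λ (default 5) standing in for the unspecified advanced-intercross
  breeding design. Chromosomes and lines independent. The default map
  — 1,000 markers over six 50 cM chromosomes — is a placeholder with
  realistic linkage scale, not a reconstruction of the real panel's map.
* **NIL assay**: strain latent means are cumulative sums of carried
  interval effects; each well adds day, plate, well-position,
  passaging-replicate, and residual Gaussian draws on the latent scale.
  Latent (S, M) map onto the simplex through the inverse
  additive-log-ratio transform around the baseline composition
  (S, M, L) = (0.25, 0.35, 0.40) — guaranteeing the simplex invariants
  without truncation artifacts — and N is a baseline of 45 progeny plus
  the latent offset, clamped at 0. Default nuisance sds (latent scale:
  0.15/0.05/0.05/0.10/0.20 for S and M in ALR units; 4.0/1.5/1.5/2.0/6.0
  progeny for N across day/plate/well/passage/residual) make day
  variation dominate plate and well effects, as in multi-day sorter
  experiments. A missingness flag (off by default) drops one strain on
  the last day and subsamples to a 2,293-well retained target — the
  shape of a real retained dataset (mean 143.3 wells per strain over
  16 strains).
* **RIAIL phenotypes**: one assay per line across 10 assay days (day
  effect + residual on the latent scale), with a configurable number of
  low-fecundity lines (default 10 of 282) forced to ≤ 5 progeny per
  founder to exercise the filter.
* All generators take explicit integer seeds; substreams use fixed
  spawn keys so adding one generator never perturbs another's draws;
  fixed seed ⇒ bit-identical output.

What passing tests on this data do **not** show: power on real sorter
data (real body-length histograms, outlier structure, and day-to-day
heteroscedasticity are not modelled), correctness of the ALR baseline
(a realism choice only), or recovery of any published QTL set — the
published raw data are not an input, and an optional adapter for
user-supplied tables is limited to mapping columns onto the well-record
schema.

## Numerical choices

Λ is clipped to [1e-12, 1]; p-values to [5e-324, 1] so −log₁₀ p stays
finite. Determinant ratios use slogdet with degenerate SSCPs mapped to
Λ = 1 (no testable variation). Quantile type for permutation
thresholds: empirical order statistic, ceiling index. Round-trips for
written results are bit-exact for integers and codes and good to 12
significant digits for reals. Genetic and physical positions are
validated non-decreasing within chromosomes; physical coordinates are
1-based, intervals closed.

## Problem sizes used in the checks

The calibration of the forward search is measured on 200 simulated
null panels of 250 lines × 100 markers with 200 permutations per scan;
Monte-Carlo-vs-exhaustive agreement uses 100,000 shuffles per ladder
(50 random ladders, m ≤ 6); the polygeny closed form uses 2,000
simulations of 600 loci on 250 × 700 balanced unlinked genotypes.
These sizes give the oracle comparisons tight Monte-Carlo error while
keeping a full suite run fast on a single CPU.

## Known limitations

* Marker regression only — no interval mapping between markers, no
  composite-interval or mixed-model GWAS machinery.
* The NIL permutation count of the original analyses is unknown; the
  default (10,000 per pair) sets the achievable p floor at ~1e-4.
* The epistasis comparison enumerates all products of retained QTL
  codes; with many QTL and binary codes higher-order products are often
  collinear, in which case the higher-order test reduces to the
  pairwise one.
* BLUP attenuation of interval effect magnitudes (discussed above) is
  accepted, not corrected; a fixed-effect second stage estimating
  strain means directly would trade it for more nuisance sensitivity.
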