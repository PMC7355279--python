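# Methods

This note describes the statistical model, the generator, and the
numerical choices made in `trionurture`, in the package's own terms.

## 1. Model and estimands

For child *j* in family *i* with true per-allele weights *w*, define the
transmitted and non-transmitted scores

```
S_T  = Σ_k w_k · g_T,k          S_NT = Σ_k w_k · g_NT,k
g_NT,k = g_father,k + g_mother,k − g_child,k
```

The pseudo-control identity on the second line holds exactly for
biallelic autosomal dosages of a Mendelian-consistent trio and requires
no phasing; `transmission.split_transmission` applies it after flagging
inconsistent entries. By construction `S_T + S_NT = S_father + S_mother`,
so the generative model

```
Y_ij = δ·S_T,ij + η·(S_father,i + S_mother,i) + c_i + e_ij
```

can be rewritten as `Y = (δ+η)·S_T + η·S_NT + c + e`. A family
random-intercept regression of `Y` on `(S_T, S_NT)` therefore has
population coefficients `(δ + η, η)`: the non-transmitted coefficient is
a clean estimate of genetic nurture, and subtracting it from the
transmitted coefficient estimates the direct effect `δ`. All scores are
standardized by the standard deviation of the transmitted score so the
two coefficients remain directly comparable (a common-scale convention;
standardizing each score by its own SD would change `η`'s units).

Variance explained is reported as `r2_pct = 100·β²` for standardized
predictor and outcome, the squared-standardized-beta convention.

## 2. Synthetic cohort generator

`synthetic.simulate_cohort` produces genotypes, pedigree, phenotypes and
ground truth from a `SimulationConfig`.

- **Family structure.** Families are MZ twins (default probability 0.45),
  DZ twins (0.35), DZ twins plus a singleton sibling (0.15) or singletons
  (0.05), each with two genotyped founders. MZ pairs share one
  transmission draw (identical genomes); all other children get
  independent Mendelian transmissions. This yields the within-family
  correlation structure the power module models (MZ ICC > DZ ICC).
- **Genotypes.** SNP allele frequencies are uniform on `maf_range`
  (default 0.05–0.5); founder dosages are Binomial(2, p); children are
  built one transmitted allele per parent (Bernoulli by parental
  genotype). Positions are spaced so that LD-window logic is exercised.
- **Effects.** A `causal_fraction` (default 0.2, exact count) of SNPs get
  normal weights for each of two traits (EA-like and ADHD-like). True
  scores are standardized by the SD of the transmitted-score
  distribution, then enter the phenotype model with coefficients
  `(δ, η)` for achievement and `(δ_adhd, η_adhd)` for ADHD symptoms.
- **Phenotypes.** Achievement is Gaussian: score terms + family intercept
  (`var_family`, default 0.2) + residual (`var_resid`, 0.7) + small sex
  and birth-year effects. Educational attainment of parents is an
  ordinal 4-level variable cut from a latent Gaussian at thresholds
  placed at cumulative probabilities 0.005 / 0.096 / 0.507, giving level
  frequencies of roughly 0.5%, 9%, 41%, 49%. ADHD symptom counts at home
  and school are produced by `floor(s·max(0, Z+a)²)` applied to a latent
  Gaussian `Z` — an L-shaped count distribution with calibrated means
  (≈2.9 at home on a 0–18 scale, ≈6.1 at school on 0–43); a square-root
  transform restores approximate linearity, which is how the association
  layer analyses them.
- **GWAS weights.** Marginal summary statistics are the true joint
  weights converted to per-allele marginal scale plus sampling noise with
  `se = 1/sqrt(2p(1−p)·N_gwas)`, with p-values from the Wald statistic.
- **Errors.** `mendel_error_rate` randomly corrupts child dosages to a
  different legal value, for exercising QC.
- **Determinism.** Every stochastic component draws from
  `np.random.default_rng([stream_id, seed])` with a fixed stream per
  component, so adding families or SNPs perturbs nothing else and a rerun
  is byte-identical.

Realism limits: SNPs are generated in linkage equilibrium (the LD
shrinkage machinery is exercised structurally, not by realistic LD);
assortative mating is absent; panels of a few hundred SNPs make the
heterozygosity-F sample filter noisy (documented in the README example).

## 3. Quality control

- **Samples**: call rate < 0.90; heterozygosity `F = 1 − obs/exp het`
  outside ±0.10; more than 20 Mendelian errors.
- **SNPs**: MAF ≤ 0.01; exact HWE p ≤ 1e-5 (founders only); call rate
  < 0.99; reference-frequency deviation > 0.10; palindromic with MAF
  > 0.40; Mendelian error rate ≥ 2%; plus structural filters (non-ACGT,
  non-autosomal, duplicate position, multiallelic).
- **Exact HWE test**: full enumeration of heterozygote counts at fixed
  allele counts, implemented with log-gamma weights and normalized; the
  p-value sums probabilities ≤ the observed table's (ties included via a
  `1+1e-12` relative guard). Monomorphic SNPs return 1. Validated in the
  test suite against an independent exact-rational (`fractions.Fraction`)
  oracle, exhaustively for all tables of ≤60 genotypes and on random
  larger tables.
- **PCA**: fitted on founders only (children are linear combinations of
  parents and would distort axes), frequency-standardized, mean-imputed,
  SVD-based with a deterministic sign convention; children are projected
  onto the founder axes.

## 4. Polygenic scoring

Weight tables are aligned to the genotype panel by allele pair: exact
match, sign flip (swapped alleles), strand flip, or both; palindromic
SNPs that cannot be disambiguated and genuine mismatches are dropped and
logged. Two adjustment steps are available:

1. **Causal-fraction screen**: keep the top fraction of SNPs by GWAS
   p-value (stable ordering), zero the rest.
2. **Infinitesimal LD shrinkage**: within non-overlapping 250 kb windows,
   solve `[(M/(N·h²))·I + D]·x = β_marginal` where `D` is the local
   standardized-genotype correlation from a reference panel — the
   closed-form infinitesimal limit of LDpred-style adjustment; a Gibbs
   sampler over sparse causal configurations is deliberately out of
   scope, with the p-value screen as the sparse surrogate.

Scores impute missing dosages at `2·p̂` and are computed for both the
transmitted and non-transmitted datasets.

## 5. Association models

Continuous outcomes (achievement, square-root ADHD counts) are
residualized on covariates (sex; plus birth year and sex×birth-year for
parental attainment; ancestry PCs; platform dummies), standardized
(population SD), and fitted with a linear family-random-intercept model
via maximum likelihood (`statsmodels` MixedLM, ML not REML, with an
optimizer-fallback ladder since variance components on the boundary can
break individual optimizers). Ordinal outcomes (parental attainment) use
a hand-rolled proportional-odds model with a family random intercept,
integrated by 31-node Gauss–Hermite quadrature (non-adaptive: the
integrand is well-scaled here, and fixed nodes keep the likelihood
deterministic; validated against `lme4::glmer` with 25-point adaptive
quadrature to 5 decimals on a binary reduction, and against
`OrderedModel` at σ = 0). Aliased covariate columns are dropped by
pivoted QR before fitting.

The report table fits, per outcome, the EA score pair (model 1), the ADHD
score pair (model 2) and all four scores jointly (model 3), flagging
significance at α = 0.01.

## 6. Power for clustered designs

With `n` families of size `m` and within-family outcome correlation ICC,
the effective sample size is `N_e = n·m / (1 + ICC·(m−1))`, summed over
strata (MZ pairs, DZ pairs, singletons with their own ICCs). Power for a
single standardized predictor explaining `r²` of the outcome is the
noncentral-F tail `P(F(1, N_e−2; λ) > F_crit)` with
`λ = N_e·r²/(1−r²)`. The detectable `r²` at a target power inverts this
with Brent's method (tolerance 1e-12). The Monte-Carlo oracle in the
test suite confirms the analytic power against simulated t-test rejection
rates across a grid of `(n, r²)`.

Default ICCs follow twin-study conventions for the implemented outcomes:
0.8 (MZ) / 0.4 (DZ) for achievement and 0.8 / 0.3 for ADHD symptoms;
`power_curve` reports ±0.1 ICC sensitivity bands.

## 7. Problem sizes and defaults

The defaults (1000 families, 500 SNPs) run the full pipeline in seconds
on one CPU; the acceptance experiments scale to 5000 families / 200 SNPs
(parameter recovery) and hundreds of replicate fits (null calibration)
within a minutes-scale budget. All sizes are package choices: nothing in
the code depends on a particular cohort, and file-based mode accepts any
VCF + pedigree + phenotype + weight tables.

## 8. Limitations

- Linkage-equilibrium genotypes mean LD shrinkage is only structurally
  tested; with real data, reference-panel mismatch is the user's risk.
- The ordinal random-intercept model is unreliable when most clusters
  are singletons (the random-intercept SD is weakly identified); the
  linear models are robust to this.
- Power assumes a single predictor tested at a time; joint-model power
  is approximated by the marginal calculation.
- No X-chromosome or imputation-dosage handling; dosages are treated as
  hard calls in QC error checks.
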