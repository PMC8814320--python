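# Methods

This note documents the models the package implements, the defaults it
ships, the numerical choices behind them, and what the synthetic-data
validation does and does not establish.

## Income constructs

**Equivalization.** Household income is divided by √(household size)
(the 0.5-elasticity equivalence scale), making income a per-head quantity
that accounts for shared consumption.

**Income bands.** Income is recorded in 29 bands from HKD 1–499 to
HKD ≥ 150,000. Only the first and last band boundaries are fixed by the
survey design; the intermediate edges shipped in
`income.DEFAULT_BAND_EDGES` are a package default chosen to be ~HKD
500-wide at low incomes and progressively wider above, tracking the
right-skew of household incomes. Bands are integer HKD ranges; the
representative income of a closed band is its arithmetic midpoint
((lower + upper)/2 with upper = next edge − 1) and of the open top band its
lower edge (HKD 150,000). The midpoint rule bounds the unbanding error by
half the band width.

**Yitzhaki index.** D_i = (1/N) Σ_{y_j > y_i} (y_j − y_i) with N the *full*
reference-group size (the standard population-averaged form), not the count
of richer households. The reference group defaults to all households in the
analysis sample; `yitzhaki_index` accepts an explicit reference mask for
subgroup sensitivity analyses. Income is a household attribute: the index
is computed once per household and broadcast to members. The vectorized
implementation (sorting + suffix sums, O(n log n)) is tested against the
O(n²) double loop.

**Gini.** Population (uncorrected) mean-difference form
G = ΣΣ|y_i − y_j| / (2n²ȳ), computed via the sorted-rank identity and
cross-checked against the Lorenz-curve trapezoid formula. No finite-sample
correction is applied.

**Neighborhood quartiles.** Cut points are empirical 25/50/75 percentiles
of the *neighborhood-level* distribution (not person-weighted); a value on
a cut point goes to the lower quartile. Person-level quartile shares are
therefore unequal when neighborhoods differ in population — intended.

## Multilevel association models

One model per outcome contains all four income exposures simultaneously
(continuous terms per HKD 1,000; quartile terms as indicators against the
1st quartile) plus age, sex and birthplace. Continuous outcomes use a
linear mixed model with a neighborhood random intercept and a household
variance component nested inside it, fitted by REML. ICCs follow the nested
convention: ICC(neighborhood) = σ²_nb/total and ICC(household) =
(σ²_nb + σ²_hh)/total, with total = σ²_nb + σ²_hh + σ²_resid (π²/3 residual
on the latent logistic scale).

Numerical note: the default L-BFGS optimizer in the mixed-model solver
converges to spurious optima for this nested variance-component profile
(including attributing household variance to the neighborhood level, and
failing at zero-variance boundaries); Powell is used instead, which is
slower but lands on the right components in both regimes.

Binary outcomes default to a single-level logistic model with
household-cluster-robust standard errors, flagged as such in the output
(`fit_method`), because no reliable quadrature GLMM is available in the
dependency set; a variational-Bayes mixed logistic (`binary_method=
"mixed_vb"`) is provided when latent-scale ICCs are wanted, with automatic
fallback. Missing outcome/covariate values are dropped per model
(complete-case), so n varies by outcome. The Bonferroni flag defaults to
α = 0.05 over (exposure terms × outcomes) tests — 48 for the full grid.

## Mediation

Linear mediator model M = β₀ + β₁A + β₂ᵀC + ε, ε ~ N(0, σ²); outcome model
g(E[Y]) = θ₀ + θ₁A + θ₂M + θ₃AM + θ₄ᵀC with identity or logit link. Natural
effects for the contrast a vs a\*: in the linear family

- NDE = (θ₁ + θ₃(β₀ + β₁a\* + β₂ᵀc))(a − a\*)
- NIE = (θ₂ + θ₃a)β₁(a − a\*), TE = NDE + NIE (exact), PM = NIE/TE.

The logistic family uses the rare-outcome odds-ratio approximation (the σ²
correction terms in the direct effect; PM on the OR scale); a warning is
attached above 10% outcome prevalence. With θ₃ = 0 the NIE reduces to the
classical product of coefficients. The closed forms are verified against
numerical standardization (Gauss–Hermite integration of the outcome model
over the mediator's normal law).

Defaults: exposure scaled per HKD 1,000; contrast a\* = sample-mean
deprivation, a = a\* + 1; covariates evaluated at sample means (binary
covariates at observed proportions), since a single summary effect is
reported rather than covariate-conditional curves. p-for-interaction is the
Wald test of θ₃. CIs are percentile bootstrap over individuals, refitting
both models per replicate, minimum 200 replicates, aborting if >5% of
replicates fail. Cortisol enters as its natural log.

## Genotype toolkit

QC filters run sequentially, each recomputed on the survivors of the
previous one (making the pass idempotent): SNP missingness > 2%, sample
missingness > 2%, MAF < 0.05, HWE p < 10⁻⁶, sample heterozygosity outside
mean ± 3 SD. The published "call rate < 0.02" thresholds are read as
missingness > 0.02 — the conventional meaning; a literal call rate below 2%
would remove essentially nothing. If all heterozygosity rates are equal
(SD 0) no sample is flagged. HWE defaults to the 1-df chi-square
goodness-of-fit test computed on all retained samples (the exact
conditional test is available as `hwe_exact_test`); monomorphic SNPs return
p = 1 by convention.

LD pruning is a greedy pass in input order: keep a SNP iff its squared
Pearson correlation (pairwise-complete) with every kept SNP is below the
threshold; zero-variance SNPs count as uncorrelated and are kept. PCA
mean-imputes missing dosages per SNP, standardizes columns by the *sample*
SD (the expected-binomial-variance alternative is not used), and returns
SVD scores. Pedigree kinship is twice the recursive kinship coefficient
(self 1, full sibs and parent–offspring 0.5, half sibs 0.25), computed
within family blocks. Genomic kinship is the allele-frequency-standardized
cross-product averaged over markers.

## Mendelian randomization

**Variance components.** Ω = σ²_g·K + σ²_e·I is estimated once on the
covariate-adjusted log-cortisol by Haseman–Elston regression (off-diagonal
trait cross-products on kinship entries) — deterministic and fast; negative
estimates are clipped to zero with a warning. On cohorts where the true
kinship-tagged variance is small, clipping fires often and GLS then reduces
toward OLS, which is the right limiting behavior.

**Weights and score.** Per-SNP *marginal* GLS slopes (not a joint fit —
candidates are pre-pruned for independence) of log-cortisol on
[1, dosage, age, sex, PC1–10], whitened through the Cholesky factor of Ω.
Each SNP is re-aligned so the counted allele has a non-negative weight
(the cortisol-increasing allele); the score is the weighted dosage sum with
missing dosages imputed to twice the counted-allele frequency. Weights and
MR estimates use the same sample (internal weighting). PCs enter weight
estimation only; the MR stage adjusts for age and sex alone.

**2SLS.** Stage 1 regresses exposure on instrument + covariates; stage 2
uses fitted exposure with residuals from the observed exposure
(2SLS-consistent SEs). With one instrument and no covariates this equals
the Wald ratio. First-stage partial F is the squared t of the instrument;
partial R² = F/(F + dof), so F = (n − k)R²/(1 − R²) holds by construction.
F < 10 raises a weak-instrument warning but still returns the estimate.

**MGMM.** Just-identified multiplicative structural mean model:
E[(Y·exp(−β₀ − β_x X − γᵀC) − 1)·(1, Z, Cᵀ)ᵀ] = 0, reporting exp(β_x) as a
risk ratio. The solver standardizes exposure and covariates (the raw moment
surface is badly scaled), starts from a Poisson log-linear fit, and tries
several restarts; when the moment system has no exact root — which happens
with weak instruments and few cases, even in the observed sample — the
GMM-objective (moment-norm) minimizer is reported with a warning, matching
what quadratic-form GMM software returns. CIs are percentile bootstrap over
individuals (heteroskedasticity-robust by construction), minimum 200
replicates; bootstrap replicates accept the minimizer without warning.

**Hausman.** H = (b_IV − b_obs)²/(V_IV − V_obs) on 1 df; if the variance
difference is non-positive the statistic is reported as 0 with p = 1 and a
degeneracy flag. The observational comparators are linear regression
(continuous) and Poisson regression with HC0-robust errors reporting an
IRR (binary), adjusted for age and sex. For MGMM the IV variance in the
comparison is the bootstrap variance of the log risk ratio.

## Synthetic cohort generator

What it emulates: households sampled within neighborhoods; one lognormal
income draw per household with neighborhood-specific (μ, σ) drawn from
configurable ranges, reported in the 29 bands; two-generation pedigrees
(founder couples plus optional full siblings — `sibling_fraction` is the
probability that a household's extra members are children rather than
unrelated adults); founder genotypes in HWE at MAF ~ U(0.30, 0.50)
(mirroring the common-variant screen of the instrument SNPs); log-cortisol
= 2.0 + Σβ_j·dosage_j + deprivation effect + N(0, 0.38²) (mean 2.0, SD
~0.4 log µg/dL); SBP with age, sex, deprivation (per HKD 1,000) and
cortisol effects plus household/neighborhood intercepts; binary outcomes
from a logistic model whose intercept is solved numerically (Brent) to hit
the target prevalence (CVD 4.6%, diabetes 6.5%). Shared cluster intercepts
are specified as fractions of each outcome's noise SD (defaults 0.35/0.15,
giving household/neighborhood ICCs near 0.13/0.02). All randomness flows
from a single seeded generator; a config's seed fully determines the
output, and a `SimTruth` record stores every parameter needed to compute
the expected value of each downstream estimator.

Instrument strength: defaults of 30 SNPs with |β| = 0.02 log µg/dL per
allele were chosen so that the *realized* in-sample partial R² of the
internally weighted score lands near 0.03 at n ≈ 1,500, with first-stage F
in the tens. Note the same-sample ("winner's curse") floor: with m SNPs
weighted in-sample, the score's observed R² cannot fall much below m/n even
with null effects, which is why the default SNP count is 30 rather than
larger.

What it does not emulate: realistic census income distributions or
geography, assortative mating, linkage disequilibrium between the candidate
SNPs, age-structured disease onset, measurement error in self-reports, or
missing data (cortisol is observed for everyone). Passing tests therefore
establish the *estimators'* correctness under the assumed data-generating
structure, not robustness to these real-data features.

## Problem sizes used in validation

The validation suite exercises: oracle equivalences on up to 200 random
vectors of n ≤ 500; mixed-model recovery on cohorts of ~3,500; mediation
recovery at n = 5,000–10,000; 2SLS recovery at n = 5,000; MGMM recovery
over 50 replicates at n = 20,000 (the multiplicative DGP keeps event
probabilities below 1 and prevalence near 4%, matching the binary outcomes
modeled); Hausman type-I calibration over 1,000 simulations at n = 500; and
the full PGS-MR chain over 100 replicate family cohorts of ~1,500 —
mirroring the target design's n = 1,562 — checking that first-stage F lands
in the tens, partial R² near 0.03, and the true cortisol→SBP effect is
covered by the 2SLS CI in ≥ 90% of replicates.

## Known limitations

- The logistic mediation decomposition relies on the rare-outcome
  approximation; it degrades above ~10% prevalence (flagged, not blocked).
- The reported binary-outcome mediation estimates are log-ORs; other scales
  (risk differences) are not implemented.
- MGMM assumes the multiplicative structural model; with a weak instrument
  its bootstrap intervals can be very wide and the moment system can lack
  an exact root (reported via warning).
- The mixed logistic option uses a variational approximation; its ICCs are
  approximate and its CIs are credible intervals, not profile CIs.
- Haseman–Elston is less efficient than REML for variance components; with
  small kinship-tagged variance the GLS weights are close to OLS weights.
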