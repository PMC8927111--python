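# Methods

## Pedigree representation and the relationship matrix

A pedigree is a directed acyclic graph with father/mother links; parents
referenced but never listed are materialized as founders of unknown sex.
Families are the connected components of the undirected parent-link (plus
declared partner-link) graph, and serve as the clustering/resampling unit
everywhere downstream. Generation index is the longest-path depth from
founders, which guarantees that parents precede offspring in the tabular
recursion for the additive relationship matrix A:

    a_ij = (a_{j,father(i)} + a_{j,mother(i)}) / 2     (j before i)
    a_ii = 1 + a_{father(i),mother(i)} / 2

with missing parents contributing zero. A is computed per family component
(components are exactly the non-zero blocks), over the *full* pedigree and
restricted afterwards, so unphenotyped connecting ancestors still
contribute relatedness between their phenotyped descendants. Output is
dense below 2,000 retained individuals and sparse block-diagonal CSR
above; values are identical.

Relative pairs: first-degree means parent-offspring or full sibling (both
parents shared and known). Half-siblings, grandparents and avuncular pairs
are "other" and excluded from first-degree analyses. Spouses are couples
with at least one common child — always derivable from a pedigree file —
plus declared partner links for childless couples where the input dialect
carries them; a couple sharing any pedigree ancestor (or being each
other's ancestor) is flagged consanguineous and excluded from spouse
analyses.

## Recurrence risk ratios

Exposure: an individual is *exposed* for trait X and relative set S iff at
least one relative in S has X affected; the individual's own status never
enters. Individuals none of whose S-relatives have an observed X are
dropped and counted in the log — their exposure is undefined, not
"unexposed" (the cohort gives no basis for another rule; this is a package
choice).

Two reference groups are always reported, because the verbal definition of
λ_R divides by the total population while regression compares exposed to
unexposed: `lambda_pop` and `lambda_unexposed`. The adjusted estimator is
prevalence-ratio regression — GLM with Poisson family and log link on the
binary outcome with constant time-at-risk (exposure + age + age² + sex) —
whose exponentiated exposure coefficient is the prevalence ratio of
exposed vs unexposed; this is the same estimand a modified
proportional-hazards model with constant follow-up yields, fitted by
standard IRLS instead. Variance is the robust sandwich clustered on
family, which also absorbs the double use of individuals as probands and
relatives; CI and p are Wald. The unadjusted estimator resamples whole
families (the exchangeable unit; 2,000 resamples by default, seeded) and
reports the percentile CI and two-sided bootstrap tail p-value.
Significance is two-sided p < 0.05 with no multiple-testing correction.
Separation (zero events in a group) raises an error advising the naive
estimator. Co-aggregation runs every ordered (exposure trait → outcome)
pair; per-cell failures are stored in-cell and the matrix is still
returned.

## Animal-model REML

Univariate model: y = Xβ + a + e with cov(a) = σ²_a A, cov(e) = σ²_e I;
h² = σ²_a/(σ²_a+σ²_e). Bivariate: 2×2 genetic (G) and residual (R)
covariance matrices, r_G = G₁₂/√(G₁₁G₂₂), r_E likewise on R, and
r_P from P = G + R. Individuals with one trait missing contribute through
the joint likelihood over observed entries (no listwise deletion — the
choice that maximizes information). Covariates are complete-case;
binary traits are never fed to REML (no liability-scale conversion is
implemented; heritability analyses are for continuous traits).

### Optimizer

Average-information (AI) REML. The univariate path exploits the
block-diagonal structure of A: each family block is eigendecomposed once,
rotating the model into an independent-observation form in which every
likelihood, gradient and AI evaluation is O(n). The bivariate path builds
one dense covariance template per distinct (A-block, missingness-pattern)
and factorizes each template once per iteration, so a cohort of thousands
of identically structured families costs one small matrix factorization
plus batched matrix products per iteration.

Updates are AI steps with monotone step-halving toward the current
iterate; after 20 halvings the direction switches to a gradient-scaled
EM-style step. Proposed G and R are projected into the PSD cone by
eigenvalue clipping (variances floored at 1e-8 of the phenotypic
variance). Estimates that finish on the cone boundary are flagged
(`boundary_`), never silently clamped. Convergence is declared when the
change in restricted log-likelihood falls below max(1e-8, 1e-9·(1+|logL|))
— the second term acknowledges that a log-likelihood of magnitude ~1e4
cannot be resolved below its floating-point accumulation noise — or when
an exhausted line search follows a < 1e-3 improvement (numerically
stationary point). Maximum 200 iterations; genuine non-convergence raises
an error carrying the iteration trace. A PSD projection with flagged
boundaries was preferred to a log-Cholesky reparameterization: it keeps
the AI updates in the natural (co)variance coordinates, where the
boundary case σ²_a = 0 that the mixture LRT needs is representable exactly.

Starting values: half the OLS-residual variance to each component
(bivariate covariances: half the residual cross-covariance). Standard
errors come from the inverse AI matrix by the delta method; the r_G test
against 0 is Wald on the Fisher-z scale, the test against 1 is Wald on the
raw scale and is skipped when |r̂_G| ≥ 1 − 1e-6 (no scale yields a usable
statistic at the boundary). Significance of σ²_a > 0 uses the boundary
likelihood-ratio test referred to the ½χ²₀ + ½χ²₁ mixture,
p = ½ P(χ²₁ > LRT).

If the relationship matrix restricted to phenotyped individuals is the
identity, σ²_a and σ²_e are confounded; the fit warns and the result
carries a boundary/flat-likelihood flag rather than a meaningful h².

## Synthetic cohorts

Structures: trios, nuclear families with k children, and three-generation
families (two founder couples, sibships of k in the middle generation, one
middle couple with k grandchildren — aunts/uncles stay unpartnered).
Founders draw a ~ MVN(0, G); offspring receive ½(a_f + a_m) plus a
Mendelian-sampling deviation MVN(0, ½G·(1 − ½(F_f + F_m))) — the parental
inbreeding correction is kept general although the generated structures
are non-consanguineous (F ≡ 0). Phenotypes add e ~ MVN(0, R) and fixed
effects β_age·age + β_age²·age² + β_sex·female. Ages are drawn per
generation — 68±8, 42±6, 15±4 years for three-generation structures,
45±8 / 16±4 for two-generation ones — so age and age² effects are
estimable; all configurable.

Binary traits are liability-threshold indicators: the total liability
a + e (+ couple-shared c), standardized by its theoretical SD, is compared
to the standard-normal (1−K) quantile, so the expected prevalence is K and
the liability-scale heritability is G_tt/(G_tt+R_tt+v_t). Fixed effects
are excluded from the liability by construction (age-varying prevalence is
out of scope).

Spouse resemblance, two separable mechanisms: (1) `shared_env` adds a
couple-shared residual c ~ N(0, v) to both partners of every couple;
(2) `assortative` re-pairs founder spouses by Gaussian rank-matching — the
male pool's liabilities become normal scores z, a noisy target
t = ρz + √(1−ρ²)ε is formed, and females are matched by rank of t — which
hits the target spouse correlation ρ without changing any marginal
distribution (the pairing is a permutation). Assortative pairing acts on
one designated trait's liability (the first trait by default) and applies
to founder couples; middle-generation couples in three-generation
structures pair at random, since re-pairing them would rewire family
membership. Real cohorts presumably mix both mechanisms; no attempt is
made to calibrate that mix.

All randomness comes from one integer seed via `numpy.random.default_rng`;
identical configs regenerate bit-identically, and the seed is stored in
the truth sidecar. Missingness is an optional uniform MAR mask per trait
column — the generator makes no claim about informative dropout, so
passing tests demonstrate estimator correctness under MCAR, not robustness
to real-world MNAR missingness. Likewise it omits dominance, epistasis,
gene-environment interaction, household clustering beyond couples, and
secular/cohort effects; parameter-recovery results bound what the
estimators can do when their model is true, not what real data will give.

## Pipeline

`run_study` executes phenotype derivation → pedigree → recurrence (per
trait and relative set, full co-aggregation matrix) → variance components
(all continuous traits univariate, all pairs bivariate) and assembles a
report; per-analysis failures are captured in the report and the run
continues. All stage randomness derives from the config seed via named
streams (CRC-derived offsets), so reports are byte-identical across reruns
(timestamps excluded by design — none are stored). The descriptive table
uses mean±SD unless |skewness| > 1, then median (IQR); binary variables
report prevalence. The power sensitivity analysis subsamples whole
families up to the nearest family boundary below the requested n —
individual-level subsampling would break the pedigree models — and
reports, per analysis class, the percentage of p < 0.05 findings in the
full data that lose significance. The missing-data comparison contrasts
age and sex (standardized mean differences) between complete and missing
rows per trait; age and sex are the minimal demographic set.

## Derived phenotype variables

BMI = weight(kg)/height(m)²; WHR = waist/hip. Adults: obesity BMI ≥ 30,
overweight BMI ≥ 25 *inclusive of obesity* (so obesity ⇒ overweight);
children (< 18 y) are classified on BMI z-scores (≥ 2 obese, ≥ 1
overweight) against a user-supplied age×sex reference (mean/SD or LMS);
the test suite ships a small synthetic reference, since national growth
references are external data. High tobacco consumption is ≥ 20
cigarettes/day and high alcohol consumption ≥ 15 g/day — the inclusive
orientation, with a `strict` flag for the strict reading. Packyears =
(cigarettes/day ÷ 20) × years smoked. Sum scores over binary items use
the complete-item rule (any missing item → missing score). Cronbach's
α = k/(k−1)·(1 − Σ var(item)/var(total)), complete-case, n−1 variances.
All derivations are pure functions of the raw columns (idempotent,
order-independent); invalid rows (non-positive height, negative counts)
are flagged and excluded with a log entry.

## Problem sizes used in the validation suite

Chosen as the package's own validation design: relationship-matrix oracle
— 20 random pedigrees of 8–20 members, 200,000 gene drops each, pairs
checked at 3 Monte-Carlo SE with a multiplicity allowance (≥ 99% within
3 SE, all within 5 SE, deterministic pairs exact). REML oracle — a fixed
10-family (~40 individual) fixture against a 50×50 grid search plus
Nelder-Mead refinement of the dense restricted log-likelihood, agreement
to 1e-4 per component. Univariate recovery — 3,000 nuclear families,
h² ∈ {0.25, 0.53}, 10 seeds (each run within ±0.05, mean bias < 0.02).
Bivariate recovery — 3,000 families at r_G ∈ {0.9, 0, −0.14} (±0.05);
null type-I error of the r_G-vs-0 test over 200 replicates of 400
families; r_G = 1 via a noise-duplicated trait. λ_R calibration — 500
null replicates of 300 families (bootstrap CI coverage of 1), positive
control of 100 replicates of 2,000 families (power ≥ 90%), and exact
agreement of the adjusted estimator with the closed-form 2×2 prevalence
ratio. Qualitative sign pattern — one 4,000-family cohort with four
liability traits at prevalences 3.44%, 7.74%, 15.04% and 15.57%,
heritabilities 0.25–0.53, genetic correlations +0.94/+0.26/+0.20 and
−0.14: positive pairs co-aggregate (λ_R > 1), the negative pair shows
λ_R < 1 (averaged over the two directions, whose Monte-Carlo errors are
partly independent).

## Known limitations

- No liability-scale transformation: binary-trait heritability is out of
  scope; λ_R is the binary-trait familiality measure.
- The animal model fits a + e only — no household, maternal or dominance
  components — so shared-environment effects inflate ĥ² when present
  (visible in the simulator's `shared_env` mode).
- The exposure-construction drop rule and the spouse definition
  (common-child ∪ declared partners) are package choices; cohorts with
  registry partner data may define spouses differently.
- Sum-score skip logic of interview instruments is not modeled; item
  lists are caller-supplied.
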