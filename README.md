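# kinstats

Familial aggregation and shared heritability analysis for multi-generation
family cohorts: recurrence risk ratios, pedigree-based REML variance
components, and a synthetic family-cohort generator with known ground truth.

## Who this is for

Epidemiologists and quantitative geneticists working with population-based
family studies — cohorts in which relatives (parents, offspring, siblings,
spouses) are phenotyped for a mix of binary conditions (e.g. depression,
obesity, high substance use) and continuous measures (e.g. BMI,
questionnaire sum scores). `kinstats` answers two families of questions:

1. **Do phenotypes aggregate (and co-aggregate) within families?** —
   recurrence risk ratios λ_R for first-degree relatives and spouses, for
   the same phenotype and across phenotypes.
2. **How much of the variance is additive-genetic, and how much do traits
   overlap genetically?** — heritability h² and genetic/phenotypic/
   environmental correlations from pedigree linear mixed models.

## The statistics

**Recurrence risk ratio.** For a binary phenotype, λ_R compares the
prevalence among individuals with an affected relative against a reference
prevalence. Two references are reported: the total analysis population
(`lambda_pop`, the classical definition) and the unexposed group
(`lambda_unexposed`). The covariate-adjusted estimator is a
prevalence-ratio regression — log-link Poisson regression of the binary
outcome on exposure, age, age² and sex with constant time-at-risk — whose
exponentiated exposure coefficient is the prevalence ratio; variance is a
robust sandwich clustered on family. The unadjusted estimator uses a
family-cluster bootstrap.

**Animal model REML.** For continuous traits the model is

    y = Xβ + a + e,   a ~ N(0, σ²_a A),   e ~ N(0, σ²_e I)

where A is the additive relationship matrix computed from the pedigree by
the tabular method (a_ij = ½(a_{j,father(i)} + a_{j,mother(i)}),
a_ii = 1 + ½ a_{father(i),mother(i)}). Variance components are estimated by
average-information REML; narrow-sense heritability is
h² = σ²_a / (σ²_a + σ²_e). The bivariate model estimates 2×2 genetic (G)
and residual (R) covariance matrices jointly — individuals missing one
trait contribute through the joint likelihood — giving the genetic
correlation r_G = σ_AxAy / √(σ²_Ax σ²_Ay) along with r_P and r_E.

**Synthetic cohorts.** The generator draws founder additive-genetic values
from MVN(0, G), transmits them with Mendelian-sampling noise, adds
residuals and age/age²/sex fixed effects, dichotomizes binary traits by
liability thresholds at specified prevalences, and can induce spouse
resemblance by a couple-shared environmental component or by assortative
mating (Gaussian rank-matching to a target spouse correlation). Every run
returns a `TruthRecord` with the generating parameters and per-individual
breeding values.

## Worked example

```python
from kinstats import (SimConfig, TraitSpec, simulate_cohort,
                      AnimalModelREML, RecurrenceRiskRatio)

cfg = SimConfig(
    n_families=2000, structure="nuclear", k_children=2,
    traits=[TraitSpec("bmi"), TraitSpec("obesity", "binary", 0.15)],
    G=[[0.53, 0.20], [0.20, 0.50]],   # additive-genetic covariance
    R=[[0.47, 0.00], [0.00, 0.50]],   # residual covariance
    seed=7,
)
ped, pheno, truth = simulate_cohort(cfg)

reml = AnimalModelREML(traits="bmi").fit(pheno, ped)
print(f"h2[bmi] = {reml.h2_['bmi']:.3f} (se {reml.se_h2_['bmi']:.3f})")

rrr = RecurrenceRiskRatio(outcome="obesity", relative_set="first_degree").fit(pheno, ped)
print(f"lambda_R = {rrr.lambda_r_:.2f} (95% CI {rrr.ci_[0]:.2f}-{rrr.ci_[1]:.2f})")
```

Output:

```
h2[bmi] = 0.527 (se 0.020)
lambda_R = 2.21 (95% CI 1.91-2.55)
```

The heritability estimate recovers the generating value (0.53) within its
standard error. The recurrence risk ratio says individuals with an
affected first-degree relative have ~2.2 times the obesity prevalence of
individuals without one — the expected enrichment for a 15%-prevalence
trait with liability heritability 0.5.

The same analyses run from the shell on pedigree (.fam / LINKAGE / CSV)
and phenotype (CSV/TSV) files:

```bash
kinstats simulate --config sim.yaml --out cohort/
kinstats recurrence --ped cohort/cohort.fam --pheno cohort/phenotypes.tsv \
    --traits obesity --relatives fdr
kinstats varcomp --ped cohort/cohort.fam --pheno cohort/phenotypes.tsv --traits bmi
kinstats run --config study.yaml --out results/
```

`kinstats run` executes the full surface — descriptive table, aggregation
and co-aggregation matrices per relative set, heritability table,
correlation matrices, missing-data comparison — into `report.json` and
tidy TSVs.

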