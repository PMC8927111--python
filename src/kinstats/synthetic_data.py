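"""Synthetic multi-generation family cohorts with known genetic architecture.

Generates family structures (trios, nuclear families, three-generation
families with sibships and spouse pairs) and multivariate phenotypes under
the additive polygenic model: founders draw additive genetic values
``a ~ MVN(0, G)``; each offspring receives the parental mean plus a
Mendelian-sampling deviation ``m ~ MVN(0, G/2 * (1 - (F_f + F_m)/2))``;
phenotypes add fixed effects of age, age^2 and sex and a residual
``e ~ MVN(0, R)``.  Binary traits are liability-threshold indicators at a
specified prevalence.  Spouse resemblance can be induced either by a
couple-shared environmental component or by assortative mating
(rank-matching of founder spouses to a target phenotypic correlation).

Every generated quantity is recorded in a :class:`TruthRecord` so that
downstream estimators can be validated against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pedigree import FEMALE, MALE, Individual, Pedigree, write_fam

__all__ = [
    "TraitSpec",
    "SimConfig",
    "TruthRecord",
    "simulate_cohort",
    "liability_threshold",
    "apply_assortative_mating",
    "write_cohort",
]


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: continuous, or binary with a population prevalence."""

    name: str
    kind: str = "continuous"  # 'continuous' | 'binary'
    prevalence: float | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.kind == "binary":
            if self.prevalence is None or not 0 < self.prevalence < 1:
                raise ValueError(f"binary trait {self.name!r} needs prevalence in (0,1)")
        elif self.prevalence is not None:
            raise ValueError(f"continuous trait {self.name!r} must not carry a prevalence")


# default per-generation age distributions (years): grandparents, parents, children
_DEFAULT_AGES = {0: (68.0, 8.0), 1: (42.0, 6.0), 2: (15.0, 4.0)}
_TWO_GEN_AGES = {0: (45.0, 8.0), 1: (16.0, 4.0)}


@dataclass
class SimConfig:
    """Generating parameters for one synthetic cohort.

    Parameters
    ----------
    n_families : number of independent families.
    structure : {'trio', 'nuclear', 'three_generation'}.
    k_children : sibship size (middle generation for three_generation).
    k_grandchildren : youngest-generation sibship (three_generation only).
    traits : trait specifications, in the order matching G and R.
    G, R : additive-genetic and residual covariance matrices (trait^2 units),
        symmetric PSD, one row/column per trait.
    beta_age, beta_age2, beta_sex : per-trait fixed-effect coefficients
        (sex effect applies to females).
    spouse_model : {'none', 'shared_env', 'assortative'}.
    spouse_shared_var : couple-shared environmental variance per trait
        (scalar broadcast), used when spouse_model == 'shared_env'.
    spouse_rho : target spouse phenotypic correlation for assortative mating.
    spouse_trait : trait name assortative mating acts on (default: first).
    age_distribution : {generation index: (mean, sd)} in years.
    missing_rate : uniform missing-at-random mask applied per trait column.
    seed : integer seed; identical configs regenerate bit-identically.
    """

    n_families: int = 1000
    structure: str = "nuclear"
    k_children: int = 2
    k_grandchildren: int = 2
    traits: Sequence[TraitSpec] = field(default_factory=lambda: [TraitSpec("trait1")])
    G: Sequence[Sequence[float]] = field(default_factory=lambda: [[0.5]])
    R: Sequence[Sequence[float]] = field(default_factory=lambda: [[0.5]])
    beta_age: Sequence[float] | None = None
    beta_age2: Sequence[float] | None = None
    beta_sex: Sequence[float] | None = None
    spouse_model: str = "none"
    spouse_shared_var: float = 0.0
    spouse_rho: float = 0.0
    spouse_trait: str | None = None
    age_distribution: dict[int, tuple[float, float]] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.traits = [
            t if isinstance(t, TraitSpec) else TraitSpec(**t) for t in self.traits
        ]
        T = len(self.traits)
        self.G = np.asarray(self.G, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        for name, M in (("G", self.G), ("R", self.R)):
            if M.shape != (T, T):
                raise ValueError(f"{name} must be {T}x{T}, got {M.shape}")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-10:
                raise ValueError(f"{name} is not positive semi-definite")
        for attr in ("beta_age", "beta_age2", "beta_sex"):
            v = getattr(self, attr)
            v = np.zeros(T) if v is None else np.asarray(v, dtype=float)
            if v.shape != (T,):
                raise ValueError(f"{attr} must have one entry per trait")
            setattr(self, attr, v)
        if self.structure not in ("trio", "nuclear", "three_generation"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.spouse_model not in ("none", "shared_env", "assortative"):
            raise ValueError(f"unknown spouse_model {self.spouse_model!r}")
        if self.spouse_model == "assortative" and not 0 <= self.spouse_rho < 1:
            raise ValueError("assortative mating requires 0 <= spouse_rho < 1")
        if self.age_distribution is None:
            self.age_distribution = (
                dict(_TWO_GEN_AGES) if self.structure in ("trio", "nuclear") else dict(_DEFAULT_AGES)
            )

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def true_h2(self) -> dict[str, float]:
        tot = np.diag(self.G) + np.diag(self.R)
        if self.spouse_model == "shared_env":
            tot = tot + self.spouse_shared_var
        return {t.name: float(self.G[i, i] / tot[i]) for i, t in enumerate(self.traits)}

    def true_rg(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.G))
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.G / np.outer(d, d)


@dataclass
class TruthRecord:
    """Generating parameters plus per-individual additive genetic values."""

    config: SimConfig
    h2: dict[str, float]
    rg: np.ndarray
    breeding_values: pd.DataFrame  # iid x trait

    def to_json(self) -> str:
        cfg = asdict(self.config)
        cfg["G"] = self.config.G.tolist()
        cfg["R"] = self.config.R.tolist()
        for k in ("beta_age", "beta_age2", "beta_sex"):
            cfg[k] = np.asarray(cfg[k]).tolist()
        cfg["age_distribution"] = {str(k): list(v) for k, v in cfg["age_distribution"].items()}
        return json.dumps(
            {"config": cfg, "h2": self.h2, "rg": self.rg.tolist(), "seed": self.config.seed},
            indent=2,
        )


def liability_threshold(liability: np.ndarray, prevalence: float) -> np.ndarray:
    """Dichotomize a standardized liability at the quantile matching ``prevalence``.

    An individual is affected iff its liability exceeds the ``1 - K``
    quantile of the standard normal, so the expected affected fraction of a
    standard-normal liability is ``K``.  The input is assumed already
    standardized (mean 0, variance 1).
    """
    if not 0 < prevalence < 1:
        raise ValueError(f"prevalence must be in (0,1), got {prevalence}")
    thr = norm.ppf(1.0 - prevalence)
    return (np.asarray(liability, dtype=float) > thr).astype(int)


def apply_assortative_mating(
    male_values: np.ndarray,
    female_values: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pair spouses to a target phenotypic correlation by Gaussian rank-matching.

    The male pool's values are converted to normal scores; a noisy target
    ``t = rho * z + sqrt(1 - rho^2) * eps`` is formed, and the female pool is
    matched to the males by rank of ``t``.  Marginal distributions are
    unchanged (the pairing is a permutation); for Gaussian phenotypes the
    spouse correlation converges to ``rho``.

    Returns
    -------
    ndarray of indices ``j`` such that male ``i`` is paired with female
    ``j[i]``.
    """
    if not 0 <= rho < 1:
        raise ValueError(f"target correlation must be in [0,1), got {rho}")
    male_values = np.asarray(male_values, dtype=float)
    female_values = np.asarray(female_values, dtype=float)
    n = len(male_values)
    if len(female_values) != n:
        raise ValueError("male and female pools must have equal size")
    if n == 1:
        return np.array([0])
    z = norm.ppf((np.argsort(np.argsort(male_values)) + 0.5) / n)
    t = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    # female of rank r goes to the male whose t has rank r
    female_by_rank = np.argsort(female_values)
    pairing = np.empty(n, dtype=int)
    pairing[np.argsort(t)] = female_by_rank
    return pairing


# ---------------------------------------------------------------------------
# family structure templates
# ---------------------------------------------------------------------------


def _template(cfg: SimConfig):
    """Per-family member template.

    Returns (members, couples, founder_couples) where members is a list of
    (tag, father_tag, mother_tag, sex, generation) and couples are
    (male_tag, female_tag) pairs sharing children.
    """
    if cfg.structure == "trio":
        members = [
            ("pa", None, None, MALE, 0),
            ("ma", None, None, FEMALE, 0),
            ("c1", "pa", "ma", None, 1),
        ]
        couples = [("pa", "ma")]
        return members, couples, couples

    if cfg.structure == "nuclear":
        members = [("pa", None, None, MALE, 0), ("ma", None, None, FEMALE, 0)]
        for k in range(cfg.k_children):
            members.append((f"c{k+1}", "pa", "ma", None, 1))
        couples = [("pa", "ma")]
        return members, couples, couples

    # three_generation: two founder couples; one child of each marries the
    # other and they have k_grandchildren; remaining children are aunts/uncles
    members = [
        ("gpa1", None, None, MALE, 0),
        ("gma1", None, None, FEMALE, 0),
        ("gpa2", None, None, MALE, 0),
        ("gma2", None, None, FEMALE, 0),
    ]
    for k in range(cfg.k_children):
        members.append((f"a{k+1}", "gpa1", "gma1", MALE if k == 0 else None, 1))
        members.append((f"b{k+1}", "gpa2", "gma2", FEMALE if k == 0 else None, 1))
    for k in range(cfg.k_grandchildren):
        members.append((f"g{k+1}", "a1", "b1", None, 2))
    founder_couples = [("gpa1", "gma1"), ("gpa2", "gma2")]
    couples = founder_couples + [("a1", "b1")]
    return members, couples, founder_couples


def _mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    """n draws from MVN(0, cov), via eigen square root (PSD-safe)."""
    w, U = np.linalg.eigh(cov)
    L = U * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, cov.shape[0])) @ L.T


def simulate_cohort(cfg: SimConfig) -> tuple[Pedigree, pd.DataFrame, TruthRecord]:
    """Generate a cohort: pedigree, phenotype table and ground truth.

    Phenotypes for continuous traits are
    ``y = beta_age*age + beta_age2*age^2 + beta_sex*female + a + e (+ c)``;
    binary traits are liability-threshold indicators on the standardized
    total liability ``a + e (+ c)`` (fixed effects removed by construction).
    ``c`` is the couple-shared environmental component under
    ``spouse_model='shared_env'``.  The generated structures contain no
    consanguineous matings, so parental inbreeding coefficients are zero
    and the Mendelian-sampling covariance is exactly ``G/2``.

    Returns
    -------
    (Pedigree, DataFrame, TruthRecord)
        The phenotype table has columns iid, family, sex, age,
        generation and one column per trait.
    """
    rng = np.random.default_rng(cfg.seed)
    members, couples, founder_couples = _template(cfg)
    T = len(cfg.traits)
    F = cfg.n_families
    tags = [m[0] for m in members]

    iids = {tag: np.array([f"F{f:05d}-{tag}" for f in range(F)]) for tag in tags}

    # genetics and residuals per tag, arrays of shape (F, T)
    a: dict[str, np.ndarray] = {}
    e: dict[str, np.ndarray] = {}
    Lm = _chol_factor(0.5 * cfg.G)  # Mendelian sampling, F = 0 structures
    for tag, ftag, mtag, _, _ in members:
        e[tag] = _mvn(rng, cfg.R, F)
        if ftag is None:
            a[tag] = _mvn(rng, cfg.G, F)
        else:
            mend = rng.standard_normal((F, T)) @ Lm.T
            a[tag] = 0.5 * (a[ftag] + a[mtag]) + mend

    # spouse resemblance
    shared_var = np.zeros(T)
    if cfg.spouse_model == "assortative":
        ti = cfg.trait_names.index(cfg.spouse_trait or cfg.trait_names[0])
        for mtag, ftag in founder_couples:
            perm = apply_assortative_mating(
                a[mtag][:, ti] + e[mtag][:, ti],
                a[ftag][:, ti] + e[ftag][:, ti],
                cfg.spouse_rho,
                rng,
            )
            a[ftag] = a[ftag][perm]
            e[ftag] = e[ftag][perm]
    elif cfg.spouse_model == "shared_env":
        shared_var = np.full(T, float(cfg.spouse_shared_var))
        for mtag, ftag in couples:
            c = rng.standard_normal((F, T)) * np.sqrt(shared_var)
            e[mtag] = e[mtag] + c
            e[ftag] = e[ftag] + c

    # sexes: template-fixed or random
    sexes = {}
    for tag, _, _, sex, _ in members:
        if sex is None:
            sexes[tag] = np.where(rng.random(F) < 0.5, MALE, FEMALE)
        else:
            sexes[tag] = np.full(F, sex)

    # ages per generation
    ages = {}
    for tag, _, _, _, gen in members:
        mu, sd = cfg.age_distribution.get(gen, (40.0, 10.0))
        ages[tag] = np.clip(rng.normal(mu, sd, F), 0.5, None)

    # assemble phenotypes
    frames = []
    bvs = []
    for tag, ftag, mtag, _, gen in members:
        liab = a[tag] + e[tag]  # (F, T), includes shared c within e
        female = (sexes[tag] == FEMALE).astype(float)
        cols = {}
        for i, spec in enumerate(cfg.traits):
            if spec.kind == "continuous":
                cols[spec.name] = (
                    cfg.beta_age[i] * ages[tag]
                    + cfg.beta_age2[i] * ages[tag] ** 2
                    + cfg.beta_sex[i] * female
                    + liab[:, i]
                )
            else:
                sd = np.sqrt(cfg.G[i, i] + cfg.R[i, i] + shared_var[i])
                cols[spec.name] = liability_threshold(liab[:, i] / sd, spec.prevalence)
        frames.append(
            pd.DataFrame(
                {"iid": iids[tag], "sex": sexes[tag], "age": ages[tag], "generation": gen, **cols}
            )
        )
        bvs.append(pd.DataFrame(liab - e[tag], columns=cfg.trait_names, index=iids[tag]))

    pheno = pd.concat(frames, ignore_index=True)
    breeding = pd.concat(bvs)

    if cfg.missing_rate > 0:
        for name in cfg.trait_names:
            mask = rng.random(len(pheno)) < cfg.missing_rate
            pheno.loc[mask, name] = np.nan

    # pedigree
    inds = []
    for f in range(F):
        for tag, ftag, mtag, _, _ in members:
            inds.append(
                Individual(
                    iids[tag][f],
                    iids[ftag][f] if ftag else None,
                    iids[mtag][f] if mtag else None,
                    sexes[tag][f],
                )
            )
    partner_links = [
        (iids[mt][f], iids[ft][f]) for mt, ft in couples for f in range(F)
    ]
    ped = Pedigree(inds, partner_links)
    pheno.insert(1, "family", pheno["iid"].map(ped.family_of))
    pheno = pheno.sort_values("iid", ignore_index=True)

    truth = TruthRecord(
        config=cfg,
        h2=cfg.true_h2(),
        rg=cfg.true_rg(),
        breeding_values=breeding.sort_index(),
    )
    return ped, pheno, truth


def _chol_factor(M: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(np.atleast_2d(M))
    return U * np.sqrt(np.clip(w, 0.0, None))


def write_cohort(
    ped: Pedigree, pheno: pd.DataFrame, truth: TruthRecord, outdir: str | Path
) -> dict[str, Path]:
    """Write pedigree (.fam), phenotypes (TSV) and truth sidecar (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fam": outdir / "cohort.fam",
        "pheno": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_fam(ped, paths["fam"])
    pheno.to_csv(paths["pheno"], sep="\t", index=False)
    paths["truth"].write_text(truth.to_json())
    return paths
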