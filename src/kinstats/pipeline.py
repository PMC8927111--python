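"""Config-driven orchestration of the full family-study analysis surface.

``run_study`` executes, on any pedigree + phenotype input (file paths or
in-memory objects): descriptive statistics, familial aggregation and
co-aggregation recurrence risk ratios per relative set, univariate
heritabilities for the continuous traits, bivariate genetic/phenotypic/
environmental correlations for all trait pairs, and a missing-data
comparison — assembling everything into a :class:`StudyReport` that is
deterministic given the config seed.  Per-analysis failures are captured
in the report; the pipeline continues.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .pedigree import Pedigree, read_pedigree
from .phenotypes import derive_all
from .recurrence import RecurrenceRiskRatio, coaggregation_matrix
from .varcomp import AnimalModelREML

__all__ = [
    "AnalysisConfig",
    "StudyReport",
    "run_study",
    "descriptive_table",
    "subsample_sensitivity",
    "missing_data_comparison",
]


@dataclass
class AnalysisConfig:
    """Study configuration (YAML-loadable).

    ``binary_traits`` feed the recurrence analyses; ``continuous_traits``
    feed the variance-component analyses.  ``subsample_n`` triggers the
    power sensitivity analysis on a family-intact random subset.
    """

    ped_path: str | None = None
    ped_dialect: str = "plink_fam"
    pheno_path: str | None = None
    binary_traits: list[str] = field(default_factory=list)
    continuous_traits: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=lambda: ["age", "age2", "sex"])
    relative_sets: list[str] = field(default_factory=lambda: ["first_degree", "spouse"])
    estimator: str = "adjusted"
    n_boot: int = 2000
    max_iter: int = 200
    subsample_n: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def stream_seed(self, name: str) -> int:
        """Independent named seed stream derived from the config seed."""
        return (self.seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class StudyReport:
    """All result tables plus run metadata."""

    descriptive: pd.DataFrame
    aggregation: pd.DataFrame
    coaggregation: dict[str, pd.DataFrame]
    heritability: pd.DataFrame
    correlations: pd.DataFrame
    missing_comparison: pd.DataFrame
    metadata: dict
    errors: list[str] = field(default_factory=list)

    def to_payload(self) -> dict:
        def tbl(df):
            return json.loads(df.to_json(orient="records")) if len(df) else []

        return {
            "metadata": self.metadata,
            "descriptive": tbl(self.descriptive),
            "aggregation": tbl(self.aggregation),
            "coaggregation": {k: tbl(v) for k, v in self.coaggregation.items()},
            "heritability": tbl(self.heritability),
            "correlations": tbl(self.correlations),
            "missing_comparison": tbl(self.missing_comparison),
            "errors": self.errors,
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "tables").mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_payload(), indent=2))
        self.descriptive.to_csv(outdir / "tables" / "descriptive.tsv", sep="\t", index=False)
        self.aggregation.to_csv(outdir / "tables" / "aggregation.tsv", sep="\t", index=False)
        for k, v in self.coaggregation.items():
            v.to_csv(outdir / "tables" / f"coaggregation_{k}.tsv", sep="\t", index=False)
        self.heritability.to_csv(outdir / "tables" / "heritability.tsv", sep="\t", index=False)
        self.correlations.to_csv(outdir / "tables" / "correlations.tsv", sep="\t", index=False)
        self.missing_comparison.to_csv(
            outdir / "tables" / "missing_comparison.tsv", sep="\t", index=False
        )


def descriptive_table(t: pd.DataFrame, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-variable n plus mean±sd, median(IQR) or prevalence.

    Binary variables (values within {0,1}) report prevalence in percent;
    continuous variables use mean±sd unless |skewness| > 1, in which case
    median and interquartile range are reported.
    """
    if variables is None:
        variables = [
            c
            for c in t.columns
            if c not in ("iid", "family", "sex", "generation")
            and pd.api.types.is_numeric_dtype(t[c])
        ]
    rows = []
    for v in variables:
        x = t[v].dropna().astype(float)
        n = len(x)
        rec = {"variable": v, "n": n}
        if n == 0:
            rec.update(kind="empty", summary="")
        elif set(np.unique(x)) <= {0.0, 1.0}:
            rec.update(
                kind="binary",
                prevalence_pct=round(100.0 * x.mean(), 2),
                summary=f"{int(x.sum())} ({100.0 * x.mean():.2f}%)",
            )
        else:
            skew = float(x.skew()) if n > 2 else 0.0
            if abs(skew) > 1:
                q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
                rec.update(kind="median_iqr", summary=f"{med:.2f} ({q1:.2f}-{q3:.2f})")
            else:
                rec.update(kind="mean_sd", summary=f"{x.mean():.2f} ± {x.std(ddof=1):.2f}")
        rows.append(rec)
    return pd.DataFrame(rows)


def missing_data_comparison(t: pd.DataFrame, traits: Sequence[str]) -> pd.DataFrame:
    """Compare age/sex of complete vs missing rows per trait.

    Reports group means and the standardized mean difference (SMD) for age
    and the female proportion; traits without missingness are omitted.
    """
    rows = []
    female = (t["sex"].astype(str) == "female").astype(float)
    for v in traits:
        if v not in t.columns:
            continue
        miss = t[v].isna()
        if not miss.any() or miss.all():
            continue
        for var, x in (("age", t["age"].astype(float)), ("female", female)):
            a, b = x[~miss].dropna(), x[miss].dropna()
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            smd = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
            rows.append(
                {
                    "trait": v,
                    "variable": var,
                    "n_complete": len(a),
                    "n_missing": len(b),
                    "mean_complete": float(a.mean()),
                    "mean_missing": float(b.mean()),
                    "smd": float(smd),
                }
            )
    return pd.DataFrame(rows, columns=[
        "trait", "variable", "n_complete", "n_missing",
        "mean_complete", "mean_missing", "smd",
    ])


def _load_inputs(cfg, ped, pheno):
    if ped is None:
        if cfg.ped_path is None:
            raise ValueError("no pedigree given (ped_path empty and no object passed)")
        ped = read_pedigree(cfg.ped_path, cfg.ped_dialect)
    if pheno is None:
        if cfg.pheno_path is None:
            raise ValueError("no phenotype table given")
        sep = "\t" if str(cfg.pheno_path).endswith((".tsv", ".txt")) else ","
        pheno = pd.read_csv(cfg.pheno_path, sep=sep)
    pheno = derive_all(pheno)
    if "family" not in pheno.columns:
        pheno = pheno.copy()
        pheno["family"] = pheno["iid"].map(ped.family_of)
    return ped, pheno


def run_study(
    cfg: AnalysisConfig,
    ped: Pedigree | None = None,
    pheno: pd.DataFrame | None = None,
) -> StudyReport:
    """Execute the full analysis surface and assemble the report."""
    ped, pheno = _load_inputs(cfg, ped, pheno)
    errors: list[str] = []

    desc = descriptive_table(pheno)

    agg_rows = []
    for rel in cfg.relative_sets:
        for trait in cfg.binary_traits:
            row = {"outcome": trait, "relative_set": rel, "error": ""}
            try:
                est = RecurrenceRiskRatio(
                    outcome=trait,
                    relative_set=rel,
                    covariates=tuple(cfg.covariates),
                    estimator=cfg.estimator,
                    n_boot=cfg.n_boot,
                    seed=cfg.stream_seed(f"boot:{rel}:{trait}"),
                ).fit(pheno, ped)
                r = est.result_
                row.update(
                    lambda_r=r.lambda_r, ci_low=r.ci_low, ci_high=r.ci_high,
                    p_value=r.p_value, stars=r.stars(), n_exposed=r.n_exposed,
                    n_unexposed=r.n_unexposed, n_events=r.n_events,
                    lambda_pop=r.lambda_pop, lambda_unexposed=r.lambda_unexposed,
                    estimator=r.estimator,
                )
            except Exception as exc:
                row["error"] = str(exc)
                errors.append(f"aggregation {trait}/{rel}: {exc}")
            agg_rows.append(row)
    aggregation = pd.DataFrame(agg_rows)

    coagg = {}
    for rel in cfg.relative_sets:
        if len(cfg.binary_traits) >= 1:
            try:
                coagg[rel] = coaggregation_matrix(
                    ped, pheno, cfg.binary_traits, rel,
                    covariates=tuple(cfg.covariates), estimator=cfg.estimator,
                    n_boot=cfg.n_boot, seed=cfg.stream_seed(f"coagg:{rel}"),
                )
            except Exception as exc:
                coagg[rel] = pd.DataFrame()
                errors.append(f"coaggregation {rel}: {exc}")

    herit_rows = []
    for trait in cfg.continuous_traits:
        row = {"trait": trait, "error": ""}
        try:
            est = AnimalModelREML(
                traits=trait, covariates=tuple(cfg.covariates), max_iter=cfg.max_iter
            ).fit(pheno, ped)
            f = est.fit_
            row.update(
                h2=f.h2[trait], se_h2=f.se_h2[trait],
                sigma2_a=f.sigma2_a, sigma2_e=f.sigma2_e,
                n=f.n, loglik=f.loglik, converged=f.converged, boundary=f.boundary,
            )
        except Exception as exc:
            row["error"] = str(exc)
            errors.append(f"heritability {trait}: {exc}")
        herit_rows.append(row)
    heritability = pd.DataFrame(herit_rows)

    corr_rows = []
    for t1, t2 in combinations(cfg.continuous_traits, 2):
        row = {"trait_x": t1, "trait_y": t2, "error": ""}
        try:
            est = AnimalModelREML(
                traits=[t1, t2], covariates=tuple(cfg.covariates), max_iter=cfg.max_iter
            ).fit(pheno, ped)
            f = est.fit_
            row.update(
                r_G=f.r_G, se_rG=f.se_rG, p_rg_zero=f.p_rg_zero, p_rg_one=f.p_rg_one,
                r_P=f.r_P, r_E=f.r_E, h2_x=f.h2[t1], h2_y=f.h2[t2],
                n=f.n, converged=f.converged, boundary=f.boundary,
            )
        except Exception as exc:
            row["error"] = str(exc)
            errors.append(f"correlation {t1}/{t2}: {exc}")
        corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    missing = missing_data_comparison(pheno, cfg.binary_traits + cfg.continuous_traits)

    metadata = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "n_individuals": int(len(pheno)),
        "n_families": int(pheno["family"].nunique()),
    }
    return StudyReport(
        descriptive=desc,
        aggregation=aggregation,
        coaggregation=coagg,
        heritability=heritability,
        correlations=correlations,
        missing_comparison=missing,
        metadata=metadata,
        errors=errors,
    )


def family_intact_subsample(
    pheno: pd.DataFrame, n_sub: int, seed: int
) -> pd.DataFrame:
    """Seeded random subset keeping whole families, up to the nearest
    family boundary at or below ``n_sub`` individuals (at least one family)."""
    rng = np.random.default_rng(seed)
    fams = pheno["family"].unique()
    rng.shuffle(fams)
    sizes = pheno["family"].value_counts()
    keep, total = [], 0
    for f in fams:
        if keep and total + sizes[f] > n_sub:
            break
        keep.append(f)
        total += int(sizes[f])
    return pheno[pheno["family"].isin(keep)].reset_index(drop=True)


def subsample_sensitivity(
    cfg: AnalysisConfig,
    n_sub: int,
    ped: Pedigree | None = None,
    pheno: pd.DataFrame | None = None,
) -> dict:
    """Power sensitivity: rerun all analyses on a family-intact subsample.

    Returns the full and subsample reports plus, per analysis class, the
    percentage of findings significant at p < 0.05 in the full data that
    lose significance in the subsample.
    """
    ped, pheno = _load_inputs(cfg, ped, pheno)
    if n_sub > len(pheno):
        raise ValueError(f"subsample_n = {n_sub} exceeds cohort size {len(pheno)}")
    full = run_study(cfg, ped, pheno)
    sub_pheno = family_intact_subsample(pheno, n_sub, cfg.stream_seed("subsample"))
    sub = run_study(cfg, ped, sub_pheno)

    def loss(df_full, df_sub, keys, pcol="p_value"):
        if len(df_full) == 0 or pcol not in df_full:
            return np.nan, 0
        f = df_full.set_index(keys)[pcol]
        s = df_sub.set_index(keys)[pcol] if len(df_sub) else pd.Series(dtype=float)
        sig = f[f < 0.05]
        if len(sig) == 0:
            return np.nan, 0
        lost = sum(1 for k in sig.index if not (k in s.index and s[k] < 0.05))
        return 100.0 * lost / len(sig), len(sig)

    summary = {}
    pct, nsig = loss(full.aggregation, sub.aggregation, ["outcome", "relative_set"])
    summary["aggregation"] = {"pct_lost": pct, "n_significant_full": nsig}
    for rel in full.coaggregation:
        pct, nsig = loss(
            full.coaggregation[rel], sub.coaggregation.get(rel, pd.DataFrame()),
            ["exposure_trait", "outcome"],
        )
        summary[f"coaggregation_{rel}"] = {"pct_lost": pct, "n_significant_full": nsig}
    pct, nsig = loss(full.correlations, sub.correlations, ["trait_x", "trait_y"], "p_rg_zero")
    summary["correlations"] = {"pct_lost": pct, "n_significant_full": nsig}
    vals = [v["pct_lost"] for v in summary.values() if np.isfinite(v.get("pct_lost", np.nan))]
    summary["overall_pct_lost"] = float(np.mean(vals)) if vals else np.nan
    return {"full": full, "subsample": sub, "n_sub": len(sub_pheno), "concordance": summary}
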