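"""Familial aggregation and co-aggregation: recurrence risk ratios.

The recurrence risk ratio lambda_R compares the prevalence of a binary
phenotype among individuals with an affected relative (first-degree
relative or spouse) to a reference prevalence.  Two reference groups are
reported: the total analysis population (``lambda_pop``, the classical
definition) and the unexposed group (``lambda_unexposed``, the regression
estimand).  The adjusted estimator is a prevalence-ratio regression:
log-link Poisson regression of the binary outcome on exposure plus
covariates with constant time-at-risk, whose exponentiated exposure
coefficient is the prevalence ratio; variance is a robust sandwich
clustered on family, since relatives' outcomes are correlated and
individuals contribute both as probands and as relatives.

Cross-phenotype co-aggregation uses the same machinery with the exposure
trait (in relatives) different from the outcome trait (in probands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .pedigree import FIRST_DEGREE, SPOUSE, Pedigree, classify_pairs
from .varcomp import build_design, covariate_complete

__all__ = [
    "ExposureDesign",
    "RecurrenceResult",
    "build_exposure",
    "lambda_naive",
    "lambda_adjusted",
    "coaggregation_matrix",
    "RecurrenceRiskRatio",
    "significance_stars",
]

log = logging.getLogger(__name__)

RELATIVE_SETS = ("first_degree", "spouse")


class EstimationError(RuntimeError):
    """Recurrence estimation failed; message carries diagnostic counts."""


@dataclass(frozen=True)
class ExposureDesign:
    """Defines one lambda_R analysis.

    ``exposure_trait`` equals ``outcome`` for familial aggregation and
    differs for co-aggregation.  ``relative_set`` selects which relatives
    define exposure: first-degree (parents, offspring, full siblings) or
    spouses (couples with a common child or declared partners;
    consanguineous couples excluded).
    """

    outcome: str
    exposure_trait: str | None = None
    relative_set: str = "first_degree"
    covariates: tuple[str, ...] = ("age", "age2", "sex")

    def __post_init__(self):
        if self.relative_set not in RELATIVE_SETS:
            raise ValueError(f"relative_set must be one of {RELATIVE_SETS}")

    @property
    def exposure(self) -> str:
        return self.exposure_trait or self.outcome


@dataclass
class RecurrenceResult:
    """lambda_R point estimate with 95% CI, p-value and analysis metadata.

    ``lambda_r`` is the primary estimate for the requested estimator
    (population-referenced for 'naive', unexposed-referenced regression
    estimate for 'adjusted'); both reference-group variants are always
    reported because the classical verbal definition divides by the total
    population while regression compares exposed to unexposed.
    """

    lambda_r: float
    ci_low: float
    ci_high: float
    p_value: float
    n_exposed: int
    n_unexposed: int
    n_events: int
    estimator: str
    outcome: str
    exposure_trait: str
    relative_set: str
    lambda_pop: float = np.nan
    lambda_unexposed: float = np.nan

    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------


def relative_map(ped: Pedigree, relative_set: str, pairs: pd.DataFrame | None = None):
    """id -> list of relative ids for the requested relative set."""
    if pairs is None:
        pairs = classify_pairs(ped)
    if relative_set == "first_degree":
        sel = pairs[pairs["relation"].isin(FIRST_DEGREE)]
    else:
        sel = pairs[(pairs["relation"] == SPOUSE) & ~pairs["consanguineous"]]
    rel: dict[str, list[str]] = {}
    for a, b in zip(sel["id_a"], sel["id_b"]):
        rel.setdefault(a, []).append(b)
        rel.setdefault(b, []).append(a)
    return rel


def build_exposure(
    ped: Pedigree,
    t: pd.DataFrame,
    d: ExposureDesign,
    pairs: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-individual exposure indicator.

    An individual is exposed iff at least one relative in the relative set
    has the exposure trait affected.  The individual's own status never
    enters its exposure.  Individuals with no relative having an observed
    exposure trait are dropped (logged): their exposure is undefined, not
    unexposed.
    """
    status = t.set_index("iid")[d.exposure]
    rel = relative_map(ped, d.relative_set, pairs)
    idx, vals = [], []
    n_dropped = 0
    for iid in t["iid"]:
        relatives = rel.get(iid, ())
        observed = [status.get(r) for r in relatives if pd.notna(status.get(r, np.nan))]
        if not observed:
            n_dropped += 1
            continue
        idx.append(iid)
        vals.append(int(any(v == 1 for v in observed)))
    if n_dropped:
        log.info(
            "build_exposure(%s, %s): dropped %d individuals with no relative "
            "having an observed exposure trait", d.exposure, d.relative_set, n_dropped,
        )
    exposure = pd.Series(vals, index=pd.Index(idx, name="iid"), name="exposed")
    if len(exposure) == 0:
        raise EstimationError(
            f"no individual has a relative with an observed {d.exposure!r} "
            f"({n_dropped} dropped)"
        )
    return exposure


def _analysis_frame(t, exposure, outcome, covariates=()):
    df = t.set_index("iid").loc[exposure.index].copy()
    df["exposed"] = exposure
    df = df[df[outcome].notna()]
    if covariates:
        df = df[covariate_complete(df, covariates)]
    if df.empty or df["exposed"].nunique() < 2:
        raise EstimationError(f"empty exposed or unexposed group for outcome {outcome!r}")
    return df


def lambda_naive(
    t: pd.DataFrame,
    exposure: pd.Series,
    outcome: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> RecurrenceResult:
    """Unadjusted lambda_R with family-cluster bootstrap CI.

    lambda_R = P(outcome | exposed) / P(outcome | all retained individuals).
    The bootstrap resamples whole families (the exchangeable unit) with
    replacement; the CI is the percentile interval and the p-value the
    two-sided bootstrap tail probability of lambda_R = 1.
    """
    df = _analysis_frame(t, exposure, outcome)
    y = df[outcome].to_numpy(float)
    ex = df["exposed"].to_numpy(float)
    prev_all = y.mean()
    if prev_all == 0:
        raise EstimationError(f"zero population prevalence for {outcome!r}")
    prev_exposed = y[ex == 1].mean()
    lam = prev_exposed / prev_all
    lam_unexp = prev_exposed / y[ex == 0].mean() if y[ex == 0].mean() > 0 else np.inf

    fams = df["family"].to_numpy()
    counts = (
        pd.DataFrame({"f": fams, "n": 1.0, "y": y, "e": ex, "ey": ex * y})
        .groupby("f")
        .sum()
        .to_numpy()
    )  # columns: n, y, e, ey
    F = counts.shape[0]
    rng = np.random.default_rng(seed)
    w = rng.multinomial(F, np.full(F, 1.0 / F), size=n_boot).astype(float)
    agg = w @ counts
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_star = (agg[:, 3] / agg[:, 2]) / (agg[:, 1] / agg[:, 0])
    lam_star = lam_star[np.isfinite(lam_star)]
    lo, hi = np.percentile(lam_star, [2.5, 97.5])
    p = 2 * min(np.mean(lam_star <= 1.0), np.mean(lam_star >= 1.0))
    return RecurrenceResult(
        lambda_r=float(lam),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(min(p, 1.0)),
        n_exposed=int(ex.sum()),
        n_unexposed=int((1 - ex).sum()),
        n_events=int(y.sum()),
        estimator="naive",
        outcome=outcome,
        exposure_trait=str(exposure.name or outcome),
        relative_set="",
        lambda_pop=float(lam),
        lambda_unexposed=float(lam_unexp),
    )


def lambda_adjusted(
    t: pd.DataFrame,
    exposure: pd.Series,
    outcome: str,
    covariates: Sequence[str] = ("age", "age2", "sex"),
) -> RecurrenceResult:
    """Covariate-adjusted lambda_R by prevalence-ratio regression.

    Log-link Poisson regression of the binary outcome on exposure and
    covariates (constant time-at-risk); the exponentiated exposure
    coefficient is the prevalence ratio of exposed vs unexposed.  Variance
    is the robust sandwich clustered on family; CI and p-value are Wald.
    """
    df = _analysis_frame(t, exposure, outcome, covariates)
    y = df[outcome].to_numpy(float)
    if y.sum() == 0:
        raise EstimationError(f"no events for outcome {outcome!r}")
    for grp in (0, 1):
        if y[df["exposed"] == grp].sum() == 0:
            raise EstimationError(
                f"separation: no events in {'exposed' if grp else 'unexposed'} group; "
                "use the naive estimator"
            )
    Xcov, names = build_design(df, covariates)
    X = np.column_stack([Xcov, df["exposed"].to_numpy(float)])
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": df["family"].to_numpy()}
        )
    except Exception as exc:  # pragma: no cover - statsmodels failure paths
        raise EstimationError(f"prevalence-ratio regression failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or abs(res.params[-1]) > 20:
        raise EstimationError("non-convergence or separation in adjusted model")
    beta, se = res.params[-1], res.bse[-1]
    lam = float(np.exp(beta))
    zcrit = float(norm.ppf(0.975))
    p = float(2 * norm.sf(abs(beta / se)))
    prev_all = y.mean()
    prev_exposed = y[df["exposed"] == 1].mean()
    return RecurrenceResult(
        lambda_r=lam,
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        p_value=p,
        n_exposed=int(df["exposed"].sum()),
        n_unexposed=int((1 - df["exposed"]).sum()),
        n_events=int(y.sum()),
        estimator="adjusted",
        outcome=outcome,
        exposure_trait=str(exposure.name or outcome),
        relative_set="",
        lambda_pop=float(prev_exposed / prev_all) if prev_all > 0 else np.nan,
        lambda_unexposed=lam,
    )


def coaggregation_matrix(
    ped: Pedigree,
    t: pd.DataFrame,
    traits: Sequence[str],
    relative_set: str = "first_degree",
    covariates: Sequence[str] = ("age", "age2", "sex"),
    estimator: str = "adjusted",
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """lambda_R for every ordered (exposure trait -> outcome) pair.

    Diagonal cells are familial aggregation of one trait; off-diagonal
    cells are cross-phenotype co-aggregation (relative's trait on the
    exposure axis, proband's trait on the outcome axis).  Per-cell failures
    are recorded in the ``error`` column; the matrix is still returned.
    """
    if len(traits) < 1:
        raise ValueError("need at least one binary trait")
    pairs = classify_pairs(ped)
    exposures: dict[str, pd.Series | Exception] = {}
    for u in traits:
        try:
            ex = build_exposure(
                ped, t, ExposureDesign(u, relative_set=relative_set), pairs
            )
            ex.name = u
            exposures[u] = ex
        except Exception as exc:
            exposures[u] = exc
    rows = []
    for u in traits:
        for v in traits:
            rec = {
                "exposure_trait": u,
                "outcome": v,
                "relative_set": relative_set,
                "error": "",
            }
            try:
                ex = exposures[u]
                if isinstance(ex, Exception):
                    raise ex
                if estimator == "adjusted":
                    res = lambda_adjusted(t, ex, v, covariates)
                else:
                    res = lambda_naive(t, ex, v, n_boot=n_boot, seed=seed)
                rec.update(
                    lambda_r=res.lambda_r,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    p_value=res.p_value,
                    stars=res.stars(),
                    n_exposed=res.n_exposed,
                    n_unexposed=res.n_unexposed,
                    n_events=res.n_events,
                    lambda_pop=res.lambda_pop,
                    lambda_unexposed=res.lambda_unexposed,
                    estimator=res.estimator,
                )
            except Exception as exc:
                rec["error"] = str(exc)
                rec.update(lambda_r=np.nan, p_value=np.nan, stars="")
            rows.append(rec)
    return pd.DataFrame(rows)


class RecurrenceRiskRatio(BaseEstimator):
    """Recurrence-risk-ratio estimator in scikit-learn style.

    Parameters
    ----------
    outcome : binary trait of the proband.
    exposure_trait : binary trait of the relatives (defaults to outcome).
    relative_set : {'first_degree', 'spouse'}.
    covariates : adjustment set for the 'adjusted' estimator.
    estimator : {'adjusted', 'naive'}.
    n_boot, seed : family-cluster bootstrap settings (naive estimator).

    Attributes
    ----------
    result_ : RecurrenceResult
    lambda_r_, ci_, p_value_ : headline numbers.
    """

    def __init__(
        self,
        outcome: str = "trait1",
        exposure_trait: str | None = None,
        relative_set: str = "first_degree",
        covariates: tuple[str, ...] = ("age", "age2", "sex"),
        estimator: str = "adjusted",
        n_boot: int = 2000,
        seed: int = 0,
    ):
        self.outcome = outcome
        self.exposure_trait = exposure_trait
        self.relative_set = relative_set
        self.covariates = covariates
        self.estimator = estimator
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, pheno: pd.DataFrame, pedigree: Pedigree) -> "RecurrenceRiskRatio":
        design = ExposureDesign(
            self.outcome, self.exposure_trait, self.relative_set, tuple(self.covariates)
        )
        exposure = build_exposure(pedigree, pheno, design)
        exposure.name = design.exposure
        if self.estimator == "adjusted":
            res = lambda_adjusted(pheno, exposure, self.outcome, self.covariates)
        elif self.estimator == "naive":
            res = lambda_naive(pheno, exposure, self.outcome, self.n_boot, self.seed)
        else:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        res.relative_set = self.relative_set
        self.result_ = res
        self.lambda_r_ = res.lambda_r
        self.ci_ = (res.ci_low, res.ci_high)
        self.p_value_ = res.p_value
        return self
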