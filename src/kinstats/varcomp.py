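"""Pedigree-based variance components: heritability and genetic correlation.

Fits the animal model

    y = X beta + a + e,    a ~ N(0, sigma2_a * A),    e ~ N(0, sigma2_e * I)

by restricted maximum likelihood (REML), where A is the additive
relationship matrix from the pedigree.  Narrow-sense heritability is
``h2 = sigma2_a / (sigma2_a + sigma2_e)``.  The bivariate model estimates
the 2x2 additive-genetic (G) and residual (R) covariance matrices jointly,
from which the genetic correlation ``r_G = G12 / sqrt(G11 G22)``, the
residual correlation r_E and the phenotypic correlation r_P are derived.
Individuals missing one of the two traits contribute through the joint
likelihood over their observed entries.

Standard errors come from the inverse average-information matrix by the
delta method.  Significance of a variance component at the boundary
(sigma2_a = 0) uses the ½chi2(0) + ½chi2(1) mixture likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from ._reml import (
    RemlError,
    RemlResult,
    TemplateGroup,
    make_basis,
    reml_bivariate_groups,
    reml_univariate_diag,
)
from .pedigree import Pedigree, family_blocks

__all__ = [
    "VarCompFit",
    "AnimalModelREML",
    "reml_univariate",
    "reml_bivariate",
    "h2_from_components",
    "rg_from_components",
    "lrt_variance",
    "build_design",
]

DEFAULT_COVARIATES = ("age", "age2", "sex")


def build_design(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix with intercept.

    Covariate names 'age2' (age squared) and 'sex' (female indicator) are
    derived from the 'age' and 'sex' columns; any other name is taken as a
    numeric column of ``df``.
    """
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for c in covariates:
        if c == "age2":
            v = df["age"].to_numpy(dtype=float) ** 2
        elif c == "sex":
            v = (df["sex"].astype(str) == "female").to_numpy(dtype=float)
        else:
            v = df[c].to_numpy(dtype=float)
        cols.append(v)
        names.append(c)
    return np.column_stack(cols), names


def covariate_complete(df: pd.DataFrame, covariates: Sequence[str]) -> pd.Series:
    """Boolean mask of rows with all covariates observed."""
    ok = pd.Series(True, index=df.index)
    for c in covariates:
        src = "age" if c == "age2" else c
        ok &= df[src].notna()
    return ok


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------


@dataclass
class VarCompFit:
    """Fitted variance components and derived genetic parameters.

    For univariate fits ``sigma2_a``/``sigma2_e`` are scalars; for
    bivariate fits they are the 2x2 G and R matrices and the correlation
    fields are populated.
    """

    traits: list[str]
    n: int  # phenotypic records entering the likelihood
    sigma2_a: float | np.ndarray
    sigma2_e: float | np.ndarray
    h2: dict[str, float]
    se_h2: dict[str, float]
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool
    gradient_norm: float
    cov_params: np.ndarray
    beta: np.ndarray | None = None
    beta_names: list[str] | None = None
    r_G: float | None = None
    se_rG: float | None = None
    p_rg_zero: float | None = None
    p_rg_one: float | None = None
    r_P: float | None = None
    r_E: float | None = None
    fixed_sigma_a: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def is_bivariate(self) -> bool:
        return len(self.traits) == 2


# ---------------------------------------------------------------------------
# closed-form helpers
# ---------------------------------------------------------------------------


def h2_from_components(sigma2_a: float, sigma2_e: float) -> float:
    """Narrow-sense heritability sigma2_a / (sigma2_a + sigma2_e)."""
    if sigma2_a < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma2_a + sigma2_e
    if tot == 0:
        raise ValueError("h2 undefined: both components are zero")
    return sigma2_a / tot


def rg_from_components(cov_axy: float, var_ax: float, var_ay: float) -> float:
    """Genetic correlation cov / sqrt(var_x var_y), clamped to [-1, 1]."""
    if var_ax <= 0 or var_ay <= 0:
        raise ValueError("genetic variances must be positive")
    r = cov_axy / np.sqrt(var_ax * var_ay)
    if abs(r) > 1:
        warnings.warn(f"genetic correlation {r:.6f} numerically outside [-1,1]; clamped")
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


def lrt_variance(fit_full: VarCompFit, fit_null: VarCompFit) -> float:
    """Boundary likelihood-ratio p-value for sigma2_a > 0.

    The null (sigma2_a = 0) lies on the boundary of the parameter space, so
    the statistic is referred to the ½chi2(0) + ½chi2(1) mixture:
    p = ½ P(chi2_1 > LRT).
    """
    if fit_null.fixed_sigma_a != 0.0:
        raise ValueError("null fit must have sigma2_a fixed at 0")
    if fit_full.traits != fit_null.traits or fit_full.n != fit_null.n:
        raise ValueError("fits are not nested (different traits or records)")
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
    return float(0.5 * chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def _prep_univariate(ped, df, trait, covariates):
    d = df.set_index("iid")
    ok = d[trait].notna() & covariate_complete(d, covariates)
    ids = [i for i in d.index[ok] if i in ped]
    if len(ids) < 3:
        raise ValueError(f"too few complete records for trait {trait!r} ({len(ids)})")
    d = d.loc[ids]
    blocks = family_blocks(ped, subset=ids)
    lam_parts, y_parts, X_parts = [], [], []
    for fam_ids, A in blocks:
        w, U = np.linalg.eigh(A)
        sub = d.loc[fam_ids]
        Xf, names = build_design(sub, covariates)
        yf = sub[trait].to_numpy(dtype=float)
        lam_parts.append(w)
        y_parts.append(U.T @ yf)
        X_parts.append(U.T @ Xf)
    lam = np.concatenate(lam_parts)
    y = np.concatenate(y_parts)
    X = np.vstack(X_parts)
    msgs = []
    if np.max(np.abs(lam - 1.0)) < 1e-8:
        msgs.append(
            "relationship matrix restricted to phenotyped individuals is the "
            "identity: sigma2_a and sigma2_e are confounded"
        )
    return lam, y, X, names, len(ids), msgs


def reml_univariate(
    ped: Pedigree,
    pheno: pd.DataFrame,
    trait: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    max_iter: int = 200,
    tol: float = 1e-8,
    fix_sigma_a: float | None = None,
) -> VarCompFit:
    """Univariate animal-model REML fit for one continuous trait.

    Rows missing the trait or any covariate are excluded (complete-case);
    the relationship matrix is computed over the full pedigree and then
    restricted to phenotyped individuals, so unphenotyped connecting
    ancestors still contribute relatedness.
    """
    lam, y, X, names, n_ids, msgs = _prep_univariate(ped, pheno, trait, covariates)
    for m in msgs:
        warnings.warn(m)
    res = reml_univariate_diag(
        lam, y, X, max_iter=max_iter, tol=tol, fix_sigma_a=fix_sigma_a
    )
    sa, se = res.theta
    h2 = h2_from_components(sa, se)
    # delta method on h2 = sa / (sa + se)
    g = np.array([se, -sa]) / (sa + se) ** 2
    var_h2 = float(g @ res.cov_theta @ g)
    se_h2 = float(np.sqrt(var_h2)) if var_h2 >= 0 else np.nan

    d = sa * lam + se
    Xd = X / d[:, None]
    beta = np.linalg.solve(X.T @ Xd, Xd.T @ y)
    return VarCompFit(
        traits=[trait],
        n=len(y),
        sigma2_a=float(sa),
        sigma2_e=float(se),
        h2={trait: h2},
        se_h2={trait: se_h2},
        loglik=res.loglik,
        n_iter=res.n_iter,
        converged=res.converged,
        boundary=res.boundary,
        gradient_norm=res.gradient_norm,
        cov_params=res.cov_theta,
        beta=beta,
        beta_names=names,
        fixed_sigma_a=fix_sigma_a,
        warnings=msgs,
    )


def _prep_bivariate(ped, df, traits, covariates):
    t1, t2 = traits
    d = df.set_index("iid")
    cov_ok = covariate_complete(d, covariates)
    obs1 = d[t1].notna() & cov_ok
    obs2 = d[t2].notna() & cov_ok
    keep = [i for i in d.index[(obs1 | obs2)] if i in ped]
    if len(keep) < 4:
        raise ValueError("too few records for bivariate fit")
    d = d.loc[keep]
    obs1, obs2 = obs1.loc[keep], obs2.loc[keep]

    blocks = family_blocks(ped, subset=keep)
    p = len(covariates) + 1
    q = 2 * p
    groups: dict[tuple, dict] = {}
    n_records = 0
    for fam_ids, A in blocks:
        m1 = np.array([bool(obs1.get(i, False)) for i in fam_ids])
        m2 = np.array([bool(obs2.get(i, False)) for i in fam_ids])
        if not (m1.any() or m2.any()):
            continue
        idx1 = np.where(m1)[0]
        idx2 = np.where(m2)[0]
        key = (np.round(A, 12).tobytes(), m1.tobytes(), m2.tobytes())
        sub = d.loc[fam_ids]
        X1, names = build_design(sub.iloc[idx1], covariates)
        X2, _ = build_design(sub.iloc[idx2], covariates)
        mo = len(idx1) + len(idx2)
        Xf = np.zeros((mo, q))
        Xf[: len(idx1), :p] = X1
        Xf[len(idx1) :, p:] = X2
        yf = np.concatenate(
            [sub.iloc[idx1][t1].to_numpy(float), sub.iloc[idx2][t2].to_numpy(float)]
        )
        n_records += mo
        g = groups.setdefault(key, {"A": A, "idx1": idx1, "idx2": idx2, "Y": [], "X": []})
        g["Y"].append(yf)
        g["X"].append(Xf)
    out = [
        TemplateGroup(
            K=make_basis(g["A"], g["idx1"], g["idx2"]),
            Y=np.asarray(g["Y"]),
            X=np.asarray(g["X"]),
        )
        for g in groups.values()
    ]
    names2 = [f"{t1}:{nm}" for nm in names] + [f"{t2}:{nm}" for nm in names]
    return out, n_records, q, names2, d, (obs1, obs2)


def reml_bivariate(
    ped: Pedigree,
    pheno: pd.DataFrame,
    traits: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> VarCompFit:
    """Bivariate animal-model REML fit; returns G, R, r_G, r_P, r_E.

    Individuals with only one of the two traits observed contribute via the
    joint likelihood over observed entries (no listwise deletion).
    """
    t1, t2 = traits
    groups, n, q, names, d, (obs1, obs2) = _prep_bivariate(ped, pheno, traits, covariates)

    # starting values: half the OLS residual (co)variance to each side
    def resid(trait, mask):
        sub = d.loc[mask[mask].index]
        X, _ = build_design(sub, covariates)
        y = sub[trait].to_numpy(float)
        return pd.Series(y - X @ np.linalg.lstsq(X, y, rcond=None)[0], index=sub.index)

    r1, r2 = resid(t1, obs1), resid(t2, obs2)
    v1, v2 = max(r1.var(), 1e-10), max(r2.var(), 1e-10)
    both = r1.index.intersection(r2.index)
    c12 = float(np.cov(r1.loc[both], r2.loc[both])[0, 1]) if len(both) > 2 else 0.0
    theta0 = np.array([0.5 * v1, 0.5 * c12, 0.5 * v2, 0.5 * v1, 0.5 * c12, 0.5 * v2])

    res = reml_bivariate_groups(groups, theta0, n, q, max_iter=max_iter, tol=tol)
    th = res.theta
    G = np.array([[th[0], th[1]], [th[1], th[2]]])
    R = np.array([[th[3], th[4]], [th[4], th[5]]])
    P = G + R

    h2 = {}
    se_h2 = {}
    for i, t in enumerate(traits):
        gi, ri = G[i, i], R[i, i]
        h2[t] = h2_from_components(gi, ri)
        ig, ir = (0, 3) if i == 0 else (2, 5)
        grad = np.zeros(6)
        grad[ig] = ri / (gi + ri) ** 2
        grad[ir] = -gi / (gi + ri) ** 2
        v = float(grad @ res.cov_theta @ grad)
        se_h2[t] = float(np.sqrt(v)) if v >= 0 else np.nan

    if G[0, 0] > 0 and G[1, 1] > 0:
        rg = rg_from_components(G[0, 1], G[0, 0], G[1, 1])
        grad = np.zeros(6)
        grad[0] = -rg / (2 * G[0, 0])
        grad[1] = 1.0 / np.sqrt(G[0, 0] * G[1, 1])
        grad[2] = -rg / (2 * G[1, 1])
        v = float(grad @ res.cov_theta @ grad)
        se_rg = float(np.sqrt(v)) if v >= 0 else np.nan
        p0, p1 = _rg_tests(rg, se_rg)
    else:
        rg, se_rg, p0, p1 = np.nan, np.nan, np.nan, np.nan

    r_p = float(P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])) if P[0, 0] > 0 and P[1, 1] > 0 else np.nan
    r_e = float(R[0, 1] / np.sqrt(R[0, 0] * R[1, 1])) if R[0, 0] > 0 and R[1, 1] > 0 else np.nan

    return VarCompFit(
        traits=list(traits),
        n=n,
        sigma2_a=G,
        sigma2_e=R,
        h2=h2,
        se_h2=se_h2,
        loglik=res.loglik,
        n_iter=res.n_iter,
        converged=res.converged,
        boundary=res.boundary,
        gradient_norm=res.gradient_norm,
        cov_params=res.cov_theta,
        beta_names=names,
        r_G=rg,
        se_rG=se_rg,
        p_rg_zero=p0,
        p_rg_one=p1,
        r_P=r_p,
        r_E=r_e,
    )


def _rg_tests(rg: float, se_rg: float) -> tuple[float, float]:
    """Wald tests of r_G against 0 (Fisher-z scale) and against 1 (raw scale).

    The vs-1 test is skipped (NaN) when the estimate sits at the boundary
    |r_G| >= 1 - 1e-6, where neither scale yields a usable statistic.
    """
    if not np.isfinite(se_rg) or se_rg <= 0:
        return np.nan, np.nan
    r = float(np.clip(rg, -1 + 1e-12, 1 - 1e-12))
    z = np.arctanh(r)
    se_z = se_rg / (1 - r**2)
    p0 = float(2 * norm.sf(abs(z) / se_z))
    if abs(rg) >= 1 - 1e-6:
        return p0, np.nan
    p1 = float(2 * norm.sf(abs(rg - 1.0) / se_rg))
    return p0, p1


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class AnimalModelREML(BaseEstimator):
    """Pedigree linear mixed model fitted by average-information REML.

    Parameters
    ----------
    traits : str or sequence of 1-2 trait names
        One trait fits the univariate model; two traits the bivariate model
        with genetic and residual covariance.
    covariates : fixed-effect names (default age, age^2, sex).
    max_iter, tol : optimizer settings (convergence on the change in
        restricted log-likelihood).
    fix_sigma_a : hold sigma2_a at a value (univariate only; used for the
        null model of the boundary LRT).

    Attributes
    ----------
    fit_ : VarCompFit
    sigma2_a_, sigma2_e_ : scalar (univariate) or 2x2 matrices (bivariate)
    h2_, se_h2_ : dict trait -> value
    r_G_, se_rG_, r_P_, r_E_ : bivariate only
    loglik_, n_iter_, converged_, boundary_ : fit diagnostics
    """

    def __init__(
        self,
        traits: str | Sequence[str] = "trait1",
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        max_iter: int = 200,
        tol: float = 1e-8,
        fix_sigma_a: float | None = None,
    ):
        self.traits = traits
        self.covariates = covariates
        self.max_iter = max_iter
        self.tol = tol
        self.fix_sigma_a = fix_sigma_a

    def fit(self, pheno: pd.DataFrame, pedigree: Pedigree) -> "AnimalModelREML":
        traits = [self.traits] if isinstance(self.traits, str) else list(self.traits)
        if len(traits) == 1:
            fit = reml_univariate(
                pedigree,
                pheno,
                traits[0],
                self.covariates,
                max_iter=self.max_iter,
                tol=self.tol,
                fix_sigma_a=self.fix_sigma_a,
            )
        elif len(traits) == 2:
            if self.fix_sigma_a is not None:
                raise ValueError("fix_sigma_a applies to univariate fits only")
            fit = reml_bivariate(
                pedigree, pheno, traits, self.covariates,
                max_iter=self.max_iter, tol=self.tol,
            )
        else:
            raise ValueError("traits must name 1 or 2 continuous traits")
        self.fit_ = fit
        self.sigma2_a_ = fit.sigma2_a
        self.sigma2_e_ = fit.sigma2_e
        self.h2_ = fit.h2
        self.se_h2_ = fit.se_h2
        self.r_G_ = fit.r_G
        self.se_rG_ = fit.se_rG
        self.r_P_ = fit.r_P
        self.r_E_ = fit.r_E
        self.loglik_ = fit.loglik
        self.n_iter_ = fit.n_iter
        self.converged_ = fit.converged
        self.boundary_ = fit.boundary
        return self
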