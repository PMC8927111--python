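"""Recurrence risk ratios: exposure construction, estimators, co-aggregation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from kinstats import (
    ExposureDesign,
    Individual,
    Pedigree,
    RecurrenceRiskRatio,
    SimConfig,
    TraitSpec,
    build_exposure,
    coaggregation_matrix,
    lambda_adjusted,
    lambda_naive,
    simulate_cohort,
)
from kinstats.recurrence import EstimationError, significance_stars


def pheno_frame(ped, status):
    rows = []
    for iid in ped.ids:
        rows.append(
            {"iid": iid, "family": ped.family_of[iid], "age": 40.0,
             "sex": ped[iid].sex if ped[iid].sex != "unknown" else "male",
             "d": status.get(iid, np.nan)}
        )
    return pd.DataFrame(rows)


class TestBuildExposure:
    def test_trio_father_affected(self, trio):
        t = pheno_frame(trio, {"dad": 1, "mom": 0, "kid": 0})
        fdr = build_exposure(trio, t, ExposureDesign("d", relative_set="first_degree"))
        assert fdr["kid"] == 1 and fdr["mom"] == 0  # mom is not first-degree of dad
        sp = build_exposure(trio, t, ExposureDesign("d", relative_set="spouse"))
        assert sp["mom"] == 1 and "kid" not in sp.index  # kid has no spouse

    def test_mutual_sibling_exposure(self):
        ped = Pedigree(
            [Individual("f"), Individual("m"), Individual("a", "f", "m"),
             Individual("b", "f", "m")]
        )
        t = pheno_frame(ped, {"f": 0, "m": 0, "a": 1, "b": 1})
        ex = build_exposure(ped, t, ExposureDesign("d"))
        assert ex["a"] == 1 and ex["b"] == 1  # each exposed via the other

    def test_unobserved_relatives_dropped(self, trio):
        t = pheno_frame(trio, {"dad": np.nan, "mom": np.nan, "kid": 1})
        ex = build_exposure(trio, t, ExposureDesign("d"))
        # kid's only relatives are unobserved -> dropped; parents exposed via kid
        assert "kid" not in ex.index
        assert ex["dad"] == 1 and ex["mom"] == 1

    def test_all_relatives_unobserved_errors(self, trio):
        t = pheno_frame(trio, {"dad": np.nan, "mom": np.nan, "kid": np.nan})
        with pytest.raises(EstimationError, match="observed"):
            build_exposure(trio, t, ExposureDesign("d"))

    def test_own_status_never_enters(self):
        ped = Pedigree([Individual("f"), Individual("m"), Individual("c", "f", "m")])
        t = pheno_frame(ped, {"f": 0, "m": 0, "c": 1})
        ex = build_exposure(ped, t, ExposureDesign("d"))
        assert ex["c"] == 0  # own affection does not expose oneself


def synthetic_counts_frame(n_exposed, k_exposed, n_unexposed, k_unexposed):
    """Independent individuals (one family each) with fixed 2x2 counts."""
    rows = []
    i = 0
    for n, k, e in ((n_exposed, k_exposed, 1), (n_unexposed, k_unexposed, 0)):
        for j in range(n):
            rows.append(
                {"iid": f"i{i}", "family": f"fam{i}", "age": 40.0 + (i % 7),
                 "sex": "female" if i % 2 else "male", "d": int(j < k), "exposed": e}
            )
            i += 1
    df = pd.DataFrame(rows)
    exposure = df.set_index("iid")["exposed"]
    exposure.name = "d"
    return df.drop(columns="exposed"), exposure


class TestLambdaNaive:
    def test_ratio_arithmetic(self):
        # prevalence among exposed 0.40, overall 0.20 -> lambda = 2
        t, ex = synthetic_counts_frame(100, 40, 300, 40)
        res = lambda_naive(t, ex, "d", n_boot=200, seed=1)
        assert res.lambda_r == pytest.approx(0.40 / 0.20)
        assert res.n_exposed == 100 and res.n_events == 80
        assert res.ci_low <= res.lambda_r <= res.ci_high

    def test_all_exposed_affected_boundary(self):
        t, ex = synthetic_counts_frame(50, 50, 50, 0)
        # overall prevalence 0.5, exposed prevalence 1.0 -> lambda = 2
        res = lambda_naive(t, ex, "d", n_boot=100, seed=2)
        assert res.lambda_r == pytest.approx(2.0)

    def test_zero_prevalence_error(self):
        t, ex = synthetic_counts_frame(50, 0, 50, 0)
        with pytest.raises(EstimationError, match="prevalence"):
            lambda_naive(t, ex, "d")

    def test_family_relabel_and_row_order_invariance(self):
        t, ex = synthetic_counts_frame(80, 30, 200, 30)
        base = lambda_naive(t, ex, "d", n_boot=50, seed=3)
        t2 = t.copy()
        t2["family"] = "x_" + t2["family"]
        t2 = t2.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res = lambda_naive(t2, ex, "d", n_boot=50, seed=3)
        assert res.lambda_r == pytest.approx(base.lambda_r, abs=1e-12)


class TestLambdaAdjusted:
    def test_matches_closed_form_prevalence_ratio(self):
        # exposed 30/100 vs unexposed 15/100 -> prevalence ratio 2.0
        t, ex = synthetic_counts_frame(100, 30, 100, 15)
        res = lambda_adjusted(t, ex, "d", covariates=())
        assert res.lambda_r == pytest.approx(2.0, abs=1e-8)
        assert res.estimator == "adjusted"

    def test_singleton_clusters_equal_hc0_sandwich(self):
        t, ex = synthetic_counts_frame(100, 30, 100, 15)
        res = lambda_adjusted(t, ex, "d", covariates=())
        df = t.set_index("iid").loc[ex.index]
        X = np.column_stack([np.ones(len(df)), ex.to_numpy(float)])
        hc0 = sm.GLM(df["d"].to_numpy(float), X, family=sm.families.Poisson()).fit(
            cov_type="HC0"
        )
        n, k, g = len(df), 2, len(df)
        correction = np.sqrt(g / (g - 1) * (n - 1) / (n - k))
        se_ours = (np.log(res.ci_high) - np.log(res.lambda_r)) / 1.959963984540054
        assert se_ours == pytest.approx(hc0.bse[1] * correction, abs=1e-10)

    def test_separation_advises_naive(self):
        t, ex = synthetic_counts_frame(50, 10, 50, 0)
        with pytest.raises(EstimationError, match="naive"):
            lambda_adjusted(t, ex, "d", covariates=())

    def test_agrees_with_naive_unexposed_reference_when_covariates_null(self):
        cfg = SimConfig(
            n_families=2000, structure="nuclear", k_children=2,
            traits=[TraitSpec("d", "binary", 0.2)], G=[[0.5]], R=[[0.5]], seed=42,
        )
        ped, pheno, _ = simulate_cohort(cfg)
        ex = build_exposure(ped, pheno, ExposureDesign("d"))
        ex.name = "d"
        adj = lambda_adjusted(pheno, ex, "d", covariates=())
        nai = lambda_naive(pheno, ex, "d", n_boot=200, seed=0)
        assert adj.lambda_r == pytest.approx(nai.lambda_unexposed, abs=1e-8)

    def test_sandwich_vs_bootstrap_variance(self):
        """Cluster-sandwich and family-bootstrap variances agree to ~20%."""
        cfg = SimConfig(
            n_families=2000, structure="nuclear", k_children=2,
            traits=[TraitSpec("d", "binary", 0.15)], G=[[0.5]], R=[[0.5]], seed=77,
        )
        ped, pheno, _ = simulate_cohort(cfg)
        ex = build_exposure(ped, pheno, ExposureDesign("d"))
        ex.name = "d"
        adj = lambda_adjusted(pheno, ex, "d", covariates=())
        se_sand = (np.log(adj.ci_high) - np.log(adj.lambda_r)) / 1.959963984540054
        # family-cluster bootstrap of the same (unexposed-referenced) estimand
        df = pheno.set_index("iid").loc[ex.index]
        counts = (
            pd.DataFrame(
                {"f": df["family"], "n": 1.0, "y": df["d"],
                 "e": ex.to_numpy(float), "ey": ex.to_numpy(float) * df["d"]}
            )
            .groupby("f").sum().to_numpy()
        )
        rng = np.random.default_rng(5)
        F = counts.shape[0]
        w = rng.multinomial(F, np.full(F, 1.0 / F), size=1000).astype(float)
        agg = w @ counts
        lam = (agg[:, 3] / agg[:, 2]) / ((agg[:, 1] - agg[:, 3]) / (agg[:, 0] - agg[:, 2]))
        se_boot = np.log(lam[np.isfinite(lam) & (lam > 0)]).std(ddof=1)
        ratio = (se_sand / se_boot) ** 2
        assert 0.8 <= ratio <= 1.25, ratio


class TestMonotonicity:
    def test_lambda_increases_with_h2(self):
        """lambda_R rises with generating heritability at fixed prevalence."""
        means = []
        for h2 in (0.0, 0.3, 0.6):
            vals = []
            for seed in (1, 2, 3):
                cfg = SimConfig(
                    n_families=1200, structure="nuclear", k_children=2,
                    traits=[TraitSpec("d", "binary", 0.15)],
                    G=[[h2]], R=[[1.0 - h2]], seed=900 + seed,
                )
                ped, pheno, _ = simulate_cohort(cfg)
                ex = build_exposure(ped, pheno, ExposureDesign("d"))
                ex.name = "d"
                vals.append(lambda_adjusted(pheno, ex, "d", covariates=()).lambda_r)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(1.0, abs=0.1)


class TestCoaggregation:
    def test_diagonal_reproduces_aggregation(self):
        cfg = SimConfig(
            n_families=800, structure="nuclear", k_children=2,
            traits=[TraitSpec("d", "binary", 0.2)], G=[[0.5]], R=[[0.5]], seed=55,
        )
        ped, pheno, _ = simulate_cohort(cfg)
        mat = coaggregation_matrix(ped, pheno, ["d"], "first_degree")
        est = RecurrenceRiskRatio(outcome="d", relative_set="first_degree").fit(pheno, ped)
        assert len(mat) == 1
        assert mat["lambda_r"].iloc[0] == pytest.approx(est.lambda_r_, abs=1e-10)

    def test_null_cross_trait_lambda_near_one(self):
        cfg = SimConfig(
            n_families=2500, structure="nuclear", k_children=2,
            traits=[TraitSpec("d1", "binary", 0.2), TraitSpec("d2", "binary", 0.2)],
            G=[[0.5, 0.0], [0.0, 0.5]], R=[[0.5, 0.0], [0.0, 0.5]], seed=56,
        )
        ped, pheno, _ = simulate_cohort(cfg)
        mat = coaggregation_matrix(ped, pheno, ["d1", "d2"], "first_degree")
        off = mat[mat.exposure_trait != mat.outcome]
        assert np.allclose(off["lambda_r"], 1.0, atol=0.15)

    def test_errors_recorded_in_cell(self, trio):
        t = pheno_frame(trio, {"dad": 1, "mom": 1, "kid": 1})
        mat = coaggregation_matrix(trio, t, ["d"], "first_degree")
        assert len(mat) == 1 and mat["error"].iloc[0] != ""


def test_significance_stars():
    assert [significance_stars(p) for p in (0.0005, 0.005, 0.03, 0.2, np.nan)] == [
        "***", "**", "*", "", ""
    ]
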