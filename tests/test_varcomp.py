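"""Variance-component estimation: closed forms, oracle equivalence, recovery."""

import numpy as np
import pandas as pd
import pytest

from kinstats import (
    AnimalModelREML,
    Individual,
    Pedigree,
    SimConfig,
    TraitSpec,
    h2_from_components,
    lrt_variance,
    reml_bivariate,
    reml_univariate,
    rg_from_components,
    simulate_cohort,
)
from kinstats.varcomp import build_design
from kinstats.pedigree import relationship_matrix

from helpers import dense_reml_loglik, grid_search_reml


class TestClosedForms:
    @pytest.mark.parametrize(
        "sa,se,expected", [(1.0, 1.0, 0.5), (0.0, 1.0, 0.0), (0.53, 0.47, 0.53)]
    )
    def test_h2(self, sa, se, expected):
        assert h2_from_components(sa, se) == pytest.approx(expected)

    def test_h2_errors(self):
        with pytest.raises(ValueError):
            h2_from_components(0.0, 0.0)
        with pytest.raises(ValueError):
            h2_from_components(-0.1, 1.0)

    @pytest.mark.parametrize(
        "cov,vx,vy,expected",
        [(0.0, 1.0, 1.0, 0.0), (2.0, 4.0, 4.0, 0.5),
         (-0.14 * np.sqrt(0.3 * 0.7), 0.3, 0.7, -0.14)],
    )
    def test_rg(self, cov, vx, vy, expected):
        assert rg_from_components(cov, vx, vy) == pytest.approx(expected)

    def test_rg_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert rg_from_components(1.0000001, 1.0, 1.0) == 1.0

    def test_rg_errors(self):
        with pytest.raises(ValueError):
            rg_from_components(0.1, 0.0, 1.0)


class TestBoundaryLRT:
    @staticmethod
    def fake_fit(loglik, fixed=None):
        from kinstats.varcomp import VarCompFit

        return VarCompFit(
            traits=["y"], n=100, sigma2_a=0.1, sigma2_e=0.9, h2={"y": 0.1},
            se_h2={"y": 0.1}, loglik=loglik, n_iter=1, converged=True,
            boundary=False, gradient_norm=0.0, cov_params=np.eye(2),
            fixed_sigma_a=fixed,
        )

    def test_identical_likelihoods_p_half(self):
        p = lrt_variance(self.fake_fit(-100.0), self.fake_fit(-100.0, fixed=0.0))
        assert p == pytest.approx(0.5)

    def test_statistic_2706_p_005(self):
        p = lrt_variance(self.fake_fit(-100.0 + 2.706 / 2), self.fake_fit(-100.0, fixed=0.0))
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="fixed at 0"):
            lrt_variance(self.fake_fit(-99.0), self.fake_fit(-100.0))


class TestGridOracle:
    def test_univariate_matches_grid_search(self, toy_cohort):
        """REML optimum matches brute-force grid + refinement of the
        restricted log-likelihood on a fixed 10-family fixture."""
        ped, pheno, _ = toy_cohort
        fit = reml_univariate(ped, pheno, "y")
        ids = pheno["iid"].tolist()
        A = relationship_matrix(ped, subset=ids).dense()
        d = pheno.set_index("iid").loc[ids]
        X, _ = build_design(d, ("age", "age2", "sex"))
        y = d["y"].to_numpy(float)
        (sa_o, se_o), ll_o, grid_lls = grid_search_reml(A, y, X)
        assert fit.sigma2_a == pytest.approx(sa_o, abs=1e-4)
        assert fit.sigma2_e == pytest.approx(se_o, abs=1e-4)
        # engine loglik agrees with the dense definition and dominates the grid
        assert fit.loglik == pytest.approx(
            dense_reml_loglik(fit.sigma2_a, fit.sigma2_e, A, y, X), abs=1e-6
        )
        assert fit.loglik >= grid_lls.max() - 1e-8


class TestRecovery:
    def test_univariate_h2(self):
        cfg = SimConfig(
            n_families=1500, structure="nuclear", k_children=2,
            traits=[TraitSpec("y")], G=[[0.5]], R=[[0.5]],
            beta_age=[0.02], beta_sex=[0.3], seed=101,
        )
        ped, pheno, truth = simulate_cohort(cfg)
        fit = reml_univariate(ped, pheno, "y")
        assert fit.converged
        assert fit.h2["y"] == pytest.approx(truth.h2["y"], abs=0.06)
        assert 0 < fit.se_h2["y"] < 0.1

    def test_bivariate_consistent_with_univariate(self):
        cfg = SimConfig(
            n_families=800, structure="nuclear", k_children=2,
            traits=[TraitSpec("y1"), TraitSpec("y2")],
            G=[[0.5, 0.2], [0.2, 0.5]], R=[[0.5, 0.1], [0.1, 0.5]], seed=102,
        )
        ped, pheno, _ = simulate_cohort(cfg)
        bi = reml_bivariate(ped, pheno, ["y1", "y2"])
        uni = reml_univariate(ped, pheno, "y1")
        assert bi.h2["y1"] == pytest.approx(uni.h2["y1"], abs=0.02)
        assert abs(bi.r_P) <= 1 and abs(bi.r_E) <= 1 and abs(bi.r_G) <= 1
        # decomposition identity: phenotypic = genetic + residual covariance
        P = bi.sigma2_a + bi.sigma2_e
        assert bi.r_P == pytest.approx(P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]), abs=1e-12)

    def test_missing_one_trait_uses_joint_likelihood(self):
        cfg = SimConfig(
            n_families=1200, structure="nuclear", k_children=2,
            traits=[TraitSpec("y1"), TraitSpec("y2")],
            G=[[0.5, 0.3], [0.3, 0.5]], R=[[0.5, 0.0], [0.0, 0.5]], seed=103,
        )
        ped, pheno, truth = simulate_cohort(cfg)
        rng = np.random.default_rng(7)
        mask = rng.random(len(pheno)) < 0.3
        pheno.loc[mask, "y2"] = np.nan
        fit = reml_bivariate(ped, pheno, ["y1", "y2"])
        assert fit.converged
        assert fit.n == int(pheno["y1"].notna().sum() + pheno["y2"].notna().sum())
        assert fit.r_G == pytest.approx(0.6, abs=0.1)


class TestInvariances:
    def test_affine_rescaling(self, toy_cohort):
        ped, pheno, _ = toy_cohort
        base = reml_univariate(ped, pheno, "y")
        scaled = pheno.copy()
        scaled["y"] = 10.0 * scaled["y"] + 3.0
        fit = reml_univariate(ped, scaled, "y")
        assert fit.h2["y"] == pytest.approx(base.h2["y"], abs=1e-8)
        assert fit.sigma2_a == pytest.approx(100.0 * base.sigma2_a, rel=1e-6)

    def test_row_order_invariance(self, toy_cohort):
        ped, pheno, _ = toy_cohort
        base = reml_univariate(ped, pheno, "y")
        shuffled = pheno.sample(frac=1.0, random_state=3).reset_index(drop=True)
        fit = reml_univariate(ped, shuffled, "y")
        assert fit.h2["y"] == pytest.approx(base.h2["y"], abs=1e-8)
        assert fit.loglik == pytest.approx(base.loglik, abs=1e-8)

    def test_unrelated_individuals_identifiability_warning(self, rng):
        inds = [Individual(f"u{k}") for k in range(60)]
        ped = Pedigree(inds)
        pheno = pd.DataFrame(
            {"iid": [f"u{k}" for k in range(60)], "age": rng.uniform(30, 60, 60),
             "sex": rng.choice(["male", "female"], 60), "y": rng.standard_normal(60)}
        )
        with pytest.warns(UserWarning, match="confounded"):
            reml_univariate(ped, pheno, "y")


class TestNullCalibration:
    def test_boundary_lrt_type_i_error(self):
        """Under h2 = 0 the mixture LRT rejects at ~nominal 5%."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            cfg = SimConfig(
                n_families=150, structure="nuclear", k_children=2,
                traits=[TraitSpec("y")], G=[[1e-12]], R=[[1.0]], seed=5000 + rep,
            )
            ped, pheno, _ = simulate_cohort(cfg)
            full = reml_univariate(ped, pheno, "y", covariates=())
            null = reml_univariate(ped, pheno, "y", covariates=(), fix_sigma_a=0.0)
            if lrt_variance(full, null) < 0.05:
                rejections += 1
        rate = rejections / n_rep
        tol = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= tol + 1e-9, rate
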