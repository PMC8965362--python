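"""REML animal model: oracles, BLUP equations, accuracies, correlations."""

import numpy as np
import pandas as pd
import pytest

from treegs.evaluation import (
    ModelSpec,
    _design,
    family_rank_correlation,
    fit_bivariate,
    fit_univariate,
    phenotypic_correlation,
    theoretical_accuracy,
)
from treegs.relatedness import RelationshipMatrix, blend, build_G
from treegs.simulate import simulate_dataset

from conftest import single_site_config


# --- independent oracle: dense REML over a heritability grid ------------------


def grid_reml(df, trait, K, fixed=("block",), n_grid=400):
    """Dense-matrix REML maximized over h2 with the total variance profiled
    analytically; independent of the AI-REML path."""
    idx = K.index
    rows = np.array([idx[i] for i in df["id"].astype(str)])
    M = K.values[np.ix_(rows, rows)]
    y = df[trait].to_numpy(float)
    X, _ = _design(df, fixed)
    n, p = X.shape
    best = (None, -np.inf)
    for h2 in np.linspace(1e-4, 1 - 1e-4, n_grid):
        V0 = h2 * M + (1 - h2) * np.eye(n)
        Vi = np.linalg.inv(V0)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        vtot = (r @ Vi @ r) / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(vtot)
            + np.linalg.slogdet(V0)[1]
            + np.linalg.slogdet(XtViX)[1]
            + (n - p)
        )
        if ll > best[1]:
            best = (h2, ll)
    return best[0]


class TestUnivariateREML:
    def test_matches_grid_oracle_on_small_instances(self):
        diffs = []
        for seed in range(8):
            cfg = single_site_config(
                800 + seed, n_mothers=10, n_fathers=5,
                offspring_per_family_per_site=5, n_snps=300, h2_true=(0.4,),
            )
            data = simulate_dataset(cfg)
            K = blend(build_G(data.genotypes))
            fit = fit_univariate(data.phenotypes, "height", K)
            h2_grid = grid_reml(data.phenotypes, "height", K)
            diffs.append(abs(fit.h2 - h2_grid))
        assert max(diffs) < 0.01

    def test_loglik_monotone_over_iterations(self, eval_trial):
        data, G, Gb, A = eval_trial
        fit = fit_univariate(data.phenotypes, "height", Gb)
        lls = [ll for _, ll in fit.trajectory]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_blup_satisfies_mixed_model_equations(self, eval_trial):
        data, G, Gb, A = eval_trial
        ph = data.phenotypes
        fit = fit_univariate(ph, "height", Gb)
        idx = Gb.index
        rows = np.array([idx[i] for i in ph["id"]])
        X, _ = _design(ph, ("block",))
        n, N = len(ph), len(Gb.ids)
        Z = np.zeros((n, N))
        Z[np.arange(n), rows] = 1.0
        Kinv = np.linalg.inv(Gb.values)
        s2a, s2e = fit.sigma2_a, fit.sigma2_e
        y = ph["height"].to_numpy(float)
        C = np.block(
            [
                [X.T @ X / s2e, X.T @ Z / s2e],
                [Z.T @ X / s2e, Z.T @ Z / s2e + Kinv / s2a],
            ]
        )
        rhs = np.concatenate([X.T @ y / s2e, Z.T @ y / s2e])
        sol = np.concatenate([fit.beta.to_numpy(), fit.ebv["ebv"].to_numpy()])
        assert np.linalg.norm(C @ sol - rhs) < 1e-8 * np.linalg.norm(C) * np.linalg.norm(sol)

    def test_ebv_se_matches_inverse_coefficient_matrix(self, eval_trial):
        data, G, Gb, A = eval_trial
        ph = data.phenotypes
        fit = fit_univariate(ph, "height", Gb)
        idx = Gb.index
        rows = np.array([idx[i] for i in ph["id"]])
        X, _ = _design(ph, ("block",))
        n, N = len(ph), len(Gb.ids)
        Z = np.zeros((n, N))
        Z[np.arange(n), rows] = 1.0
        Kinv = np.linalg.inv(Gb.values)
        C = np.block(
            [
                [X.T @ X / fit.sigma2_e, X.T @ Z / fit.sigma2_e],
                [Z.T @ X / fit.sigma2_e, Z.T @ Z / fit.sigma2_e + Kinv / fit.sigma2_a],
            ]
        )
        pev = np.diag(np.linalg.inv(C))[X.shape[1] :]
        assert np.abs(np.sqrt(pev) - fit.ebv["se"].to_numpy()).max() < 1e-8

    def test_repeated_records_match_intraclass_oracle(self):
        # K = I and duplicated records reduce the animal model to a balanced
        # one-way random-effects design with a closed-form REML solution
        rng = np.random.default_rng(0)
        n_id, k = 60, 4
        a = rng.normal(0, np.sqrt(0.4), n_id)
        y = (a[:, None] + rng.normal(0, np.sqrt(0.6), (n_id, k))).ravel()
        ids = np.repeat([f"i{j}" for j in range(n_id)], k)
        df = pd.DataFrame({"id": ids, "y": y})
        K = RelationshipMatrix([f"i{j}" for j in range(n_id)], np.eye(n_id), "G_blended")
        fit = fit_univariate(df, "y", K, ModelSpec(("y",), fixed=()))
        grand = y.mean()
        group_means = y.reshape(n_id, k).mean(axis=1)
        msb = k * np.sum((group_means - grand) ** 2) / (n_id - 1)
        msw = np.sum((y.reshape(n_id, k) - group_means[:, None]) ** 2) / (n_id * (k - 1))
        s2a_anova = (msb - msw) / k
        h2_anova = s2a_anova / (s2a_anova + msw)
        assert abs(fit.h2 - h2_anova) < 1e-3

    def test_permutation_drives_h2_to_zero(self, eval_trial):
        data, G, Gb, A = eval_trial
        ph = data.phenotypes.copy()
        h2s = []
        for rep in range(20):
            rng = np.random.default_rng(rep)
            ph["shuffled"] = rng.permutation(ph["height"].to_numpy())
            h2s.append(fit_univariate(ph, "shuffled", Gb).h2)
        assert np.median(h2s) < 0.05

    def test_ablup_and_gblup_agree_within_joint_se(self, eval_trial):
        data, G, Gb, A = eval_trial
        fg = fit_univariate(data.phenotypes, "height", Gb)
        fa = fit_univariate(data.phenotypes, "height", A)
        assert abs(fg.h2 - fa.h2) <= 2 * (fg.h2_se + fa.h2_se)

    def test_too_few_records_rejected(self, eval_trial):
        data, G, Gb, A = eval_trial
        with pytest.raises(ValueError, match="at least"):
            fit_univariate(data.phenotypes.head(10), "height", Gb)


class TestTheoreticalAccuracy:
    def _fit_like(self, se_values, s2a):
        ebv = pd.DataFrame({"ebv": 0.0, "se": se_values}, index=[f"i{k}" for k in range(len(se_values))])
        from treegs.evaluation import ModelFit

        return ModelFit(
            sigma2_a=s2a, sigma2_e=1.0, se_sigma2=(0, 0), cov_sigma2=np.eye(2),
            h2=0.5, h2_se=0.1, loglik=0.0, beta=pd.Series(dtype=float), ebv=ebv,
            converged=True, n_iter=1, lrt_sigma_a=(0, 1),
        )

    def test_reference_points(self):
        s2a = 2.0
        fit = self._fit_like([0.0, np.sqrt(s2a), np.sqrt(0.75 * s2a)], s2a)
        F = pd.Series(0.0, index=fit.ebv.index)
        acc = theoretical_accuracy(fit, F)
        assert acc.iloc[0] == pytest.approx(1.0)  # SE = 0: perfect information
        assert acc.iloc[1] == pytest.approx(0.0)  # PEV equals additive variance
        assert acc.iloc[2] == pytest.approx(0.5)  # SE^2 = 0.75 s2a

    def test_inbreeding_enters_denominator(self):
        s2a = 1.0
        fit = self._fit_like([1.0], s2a)
        F = pd.Series([1.0], index=fit.ebv.index)  # (1+F) s2a = 2
        acc = theoretical_accuracy(fit, F)
        assert acc.iloc[0] == pytest.approx(np.sqrt(0.5))

    def test_clamping_logged(self):
        fit = self._fit_like([2.0], 1.0)
        log = []
        acc = theoretical_accuracy(fit, pd.Series([0.0], index=fit.ebv.index), log=log)
        assert acc.iloc[0] == 0.0
        assert log

    def test_zero_additive_variance_errors(self):
        fit = self._fit_like([0.5], 0.0)
        with pytest.raises(ValueError, match="zero additive"):
            theoretical_accuracy(fit, pd.Series([0.0], index=fit.ebv.index))


class TestBivariate:
    def test_phenotypic_correlation_hand_example(self):
        assert phenotypic_correlation(1, 1, 0.5, 1, 1, 0.1) == pytest.approx(0.3)

    def test_recovers_genetic_correlation(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        cfg = single_site_config(
            41, trait_names=("height", "dbh"), h2_true=(0.45, 0.45),
            genetic_corr_true=corr, drought_corr_traits=(0.0, 0.0),
            pheno_means=(784.0, 126.0), pheno_sds=(158.0, 25.0),
        )
        data = simulate_dataset(cfg)
        K = blend(build_G(data.genotypes))
        comp, est = fit_bivariate(data.phenotypes, ("height", "dbh"), K)
        assert est.converged
        assert abs(est.r_a - 0.6) <= 2 * est.r_a_se
        assert est.lrt_genetic[1] < 0.05

    def test_trait_paired_with_itself_hits_boundary(self, eval_trial):
        data, G, Gb, A = eval_trial
        ph = data.phenotypes.copy()
        ph["height2"] = ph["height"]
        comp, est = fit_bivariate(ph, ("height", "height2"), Gb)
        assert est.r_a > 0.98 or est.boundary


class TestFamilyRankCorrelation:
    def test_identical_and_reversed_rankings(self):
        a = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        rho, _ = family_rank_correlation(a, a * 2 + 1)
        assert rho == pytest.approx(1.0)
        rho, _ = family_rank_correlation(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_independent_sites_give_small_rho(self):
        rhos = []
        for rep in range(30):
            rng = np.random.default_rng(rep)
            fams = [f"f{k}" for k in range(38)]
            a = pd.Series(rng.normal(size=38), index=fams)
            b = pd.Series(rng.normal(size=38), index=fams)
            rhos.append(family_rank_correlation(a, b)[0])
        assert abs(np.mean(rhos)) < 0.1

    def test_too_few_common_families(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="common families"):
            family_rank_correlation(a, a)
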