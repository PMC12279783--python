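"""Cholesky ACE/AE twin model: implied moments, FIML likelihood,
information criteria and standardized variance components."""

import numpy as np
import pytest
from scipy import stats as sps

import twinlag as tl
from twinlag.cholesky import ModelFit, implied_pair_moments


def ae_params(a2=(0.6, 0.5), r_a=-0.5, r_e=-0.3, labels=("x", "y")):
    a2 = np.asarray(a2)
    e2 = 1 - a2
    A = np.array([[a2[0], r_a * np.sqrt(a2.prod())],
                  [r_a * np.sqrt(a2.prod()), a2[1]]])
    E = np.array([[e2[0], r_e * np.sqrt(e2.prod())],
                  [r_e * np.sqrt(e2.prod()), e2[1]]])
    return tl.CholeskyParams(labels=labels, a=np.linalg.cholesky(A),
                             c=np.zeros((2, 2)), e=np.linalg.cholesky(E))


class TestImpliedMoments:
    def test_e_only_gives_block_diagonal_pair_covariance(self):
        p = tl.CholeskyParams(labels=("x", "y"), a=np.zeros((2, 2)),
                              c=np.zeros((2, 2)), e=np.linalg.cholesky(np.eye(2) * 2))
        _, sigma = implied_pair_moments(p, "MZ", (0, 0))
        np.testing.assert_allclose(sigma[:2, 2:], 0.0, atol=1e-12)

    def test_mz_cross_block_equals_genetic_covariance_without_c(self):
        p = ae_params()
        _, sigma = implied_pair_moments(p, "MZ", (0, 1))
        np.testing.assert_allclose(sigma[:2, 2:], p.A, atol=1e-12)
        _, sigma_dz = implied_pair_moments(p, "DZ", (0, 1))
        np.testing.assert_allclose(sigma_dz[:2, 2:], 0.5 * p.A, atol=1e-12)

    def test_sex_specific_means_enter_by_twin(self):
        p = ae_params()
        p.means = np.array([[1.0, 2.0], [3.0, 4.0]])
        mu, _ = implied_pair_moments(p, "DZ", (0, 1))
        np.testing.assert_allclose(mu, [1.0, 2.0, 3.0, 4.0])


class TestLikelihood:
    def test_complete_data_fiml_equals_per_pair_density_sum(self):
        p = ae_params()
        panel = tl.simulate_cholesky_panel(p, 150, 250, seed=1)
        variables = [(lab, 1) for lab in p.labels]
        fit = tl.fit_cholesky(panel, variables, model="AE", n_starts=2, seed=0)
        total = 0.0
        for _, row in panel.df.iterrows():
            sexes = (int(row.sex_t1), int(row.sex_t2))
            mu, sigma = implied_pair_moments(fit.params, row.zygosity, sexes)
            y = [row[f"{lab}_1_t{j}"] for j in (1, 2) for lab in p.labels]
            total += -2 * sps.multivariate_normal(mu, sigma).logpdf(y)
        assert abs(total - fit.minus2lnl) < 1e-8 * abs(total)

    def test_likelihood_invariant_to_twin_order_swap(self):
        p = ae_params(a2=(0.54, 0.54))
        panel = tl.simulate_cholesky_panel(p, 200, 300, seed=2)
        variables = [(lab, 1) for lab in p.labels]
        fit = tl.fit_cholesky(panel, variables, model="AE", n_starts=2, seed=0)
        fit_sw = tl.fit_cholesky(panel.swap_twins(), variables, model="AE",
                                 n_starts=2, seed=0)
        assert abs(fit.minus2lnl - fit_sw.minus2lnl) < 0.02

    def test_ae_never_beats_nested_ace_and_single_group_rejected(self):
        p = ae_params()
        panel = tl.simulate_cholesky_panel(p, 400, 600, seed=3)
        variables = [(lab, 1) for lab in p.labels]
        ace = tl.fit_cholesky(panel, variables, model="ACE", seed=0)
        ae = tl.fit_cholesky(panel, variables, model="AE", seed=0)
        assert ae.minus2lnl >= ace.minus2lnl - 1e-6
        mz_only = tl.TwinPanelData(
            panel.df[panel.df.zygosity == "MZ"].reset_index(drop=True),
            panel.traits, panel.waves)
        with pytest.raises(ValueError, match="zygosity"):
            tl.fit_cholesky(mz_only, variables, model="ACE")

    def test_fiml_uses_observed_subvectors(self):
        p = ae_params()
        panel = tl.simulate_cholesky_panel(p, 800, 1200, seed=4)
        masked = tl.apply_missingness(panel, tl.MissingnessSpec((0.3,),), seed=5)
        variables = [(lab, 1) for lab in p.labels]
        fit = tl.fit_cholesky(masked, variables, model="AE", seed=0)
        vc = tl.variance_components(fit)
        assert fit.converged
        np.testing.assert_allclose(vc.a2, [0.6, 0.5], atol=0.1)


class TestInformationCriteria:
    def test_aic_bic_arithmetic(self):
        fit = ModelFit(model="AE", params=ae_params(), minus2lnl=100.0,
                       n_params=5, n_pairs=1000, converged=True)
        assert fit.aic == 110.0
        assert abs(fit.bic - 134.5388) < 1e-3  # 5·ln(1000) = 34.5388

    def test_identical_fits_have_zero_delta(self):
        p = ae_params()
        panel = tl.simulate_cholesky_panel(p, 100, 150, seed=6)
        fit = tl.fit_cholesky(panel, [(lab, 1) for lab in p.labels],
                              model="AE", n_starts=2, seed=0)
        tab = tl.compare_models([fit, fit])
        np.testing.assert_allclose(tab["dAIC"], 0.0)

    def test_mismatched_data_rejected(self):
        p = ae_params()
        a = tl.simulate_cholesky_panel(p, 50, 80, seed=7)
        b = tl.simulate_cholesky_panel(p, 50, 80, seed=8)
        va = [(lab, 1) for lab in p.labels]
        fa = tl.fit_cholesky(a, va, model="AE", n_starts=1, seed=0)
        fb = tl.fit_cholesky(b, va, model="AE", n_starts=1, seed=0)
        with pytest.raises(ValueError, match="different data"):
            tl.compare_models([fa, fb])

    def test_ae_preferred_when_c_absent(self):
        """Under a C = 0 generator, AIC prefers the parsimonious AE model
        in the clear majority of replicates."""
        p = tl.CholeskyParams(labels=("x",), a=[[np.sqrt(0.55)]], c=[[0.0]],
                              e=[[np.sqrt(0.45)]])
        wins = 0
        reps = 20
        for i in range(reps):
            panel = tl.simulate_cholesky_panel(p, 200, 300, seed=100 + i)
            fits = [tl.fit_cholesky(panel, [("x", 1)], model=m, n_starts=1, seed=0)
                    for m in ("ACE", "AE")]
            tab = tl.compare_models(fits)
            wins += bool(tab.loc[tab.model == "AE", "preferred_AIC"].iloc[0])
        assert wins > reps / 2


class TestVarianceComponents:
    def test_standardized_shares_sum_to_one(self, composite_cholesky_fit):
        vc = composite_cholesky_fit["components"]
        np.testing.assert_allclose(vc.a2 + vc.c2 + vc.e2, 1.0, atol=1e-8)

    def test_zero_genetic_correlation_gives_zero_shared(self):
        p = ae_params(r_a=0.0)
        panel = tl.simulate_cholesky_panel(p, 1500, 2500, seed=9)
        fit = tl.fit_cholesky(panel, [(lab, 1) for lab in p.labels],
                              model="AE", seed=0)
        vc = tl.variance_components(fit)
        assert vc.shared_pct_a[0] < 4.0

    def test_path_and_symmetric_conventions_agree_at_the_optimum(self, composite_cholesky_fit):
        fit = composite_cholesky_fit["fit"]
        sym = tl.variance_components(fit, convention="rA2")
        path = tl.variance_components(fit, convention="path")
        # identical for the second-ordered trait: rA² = a21²/(a21²+a22²)
        assert abs(sym.shared_pct_a[1] - path.shared_pct_a[1]) < 1e-8
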