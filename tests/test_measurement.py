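"""Imputation, the constrained one-factor model, factor scores and
cross-wave composites."""

import numpy as np
import pandas as pd
import pytest

import twinlag as tl
from twinlag import calibration as cal
from twinlag.data import column_name, default_trait_specs
from twinlag.pipeline import _standardize_panel


def indicator_panel(n_mz, n_dz, seed, traits=("psychopathology",)):
    """Factor-level panel → standardized → study-loading indicators."""
    params = cal.study_riclpm_params(sex_effect=(0.0, 0.0))
    panel = tl.simulate_riclpm_panel(params, n_mz, n_dz, seed=seed)
    mps = [mp for mp in cal.study_measurement_params() if mp.trait in traits]
    return panel, tl.emit_indicators(_standardize_panel(panel), mps, seed=seed + 1)


class TestImputeFcs:
    def test_complete_data_passes_through(self):
        panel, _ = indicator_panel(20, 20, seed=1)
        out = tl.impute_fcs(panel, n_imputations=2, n_iterations=3, seed=0)
        pd.testing.assert_frame_equal(out.df, panel.df)

    def test_all_missing_variable_raises(self):
        panel, _ = indicator_panel(10, 10, seed=1)
        broken = panel.replace_values({
            ("personality", 2, j): np.full(panel.n_pairs, np.nan) for j in (1, 2)})
        with pytest.raises(ValueError, match="zero observed"):
            tl.impute_fcs(broken, n_imputations=1, n_iterations=2, seed=0)

    def test_mcar_imputation_preserves_correlation_structure(self):
        """20% MCAR, mean of 3 completed datasets: correlations are
        recovered up to the variance shrinkage inherent in averaging
        imputations (imputed cells sit near their conditional means, so
        correlations inflate slightly — here bounded by 0.05)."""
        panel, _ = indicator_panel(750, 750, seed=2)
        masked = tl.apply_missingness(
            panel, tl.MissingnessSpec(cell_mcar_prob=0.2), seed=3)
        imputed = tl.impute_fcs(masked, n_imputations=3, n_iterations=5, seed=4)
        full_corr = tl.phenotypic_correlations(panel).phenotypic.to_numpy()
        imp_corr = tl.phenotypic_correlations(imputed).phenotypic.to_numpy()
        diff = imp_corr - full_corr
        assert np.abs(diff).max() < 0.05
        # the deviation is inflation (same sign as r), not distortion
        off = ~np.eye(6, dtype=bool)
        assert np.corrcoef(full_corr[off], imp_corr[off])[0, 1] > 0.995


class TestGeneralFactorModel:
    def test_recovers_generating_loadings(self):
        _, ind = indicator_panel(4000, 4000, seed=5)
        spec = default_trait_specs()[1]
        fit = tl.fit_general_factor(ind, spec)
        truth = cal.PSYCHOPATHOLOGY_LOADINGS
        for i, name in enumerate(spec.indicators):
            assert abs(fit.lam[i] - truth[name]) < 0.03
        # anchor orientation: depressive symptoms load positively
        assert fit.lam[spec.indicators.index("depressive")] > 0

    def test_personality_factor_sign_convention(self):
        _, ind = indicator_panel(3000, 3000, seed=6, traits=("personality",))
        spec = default_trait_specs()[0]
        fit = tl.fit_general_factor(ind, spec)
        assert fit.lam[spec.indicators.index("extraversion")] > 0
        assert fit.lam[spec.indicators.index("neuroticism")] < 0

    def test_zero_loading_generator_recovers_near_zero(self, study_params):
        panel = tl.simulate_riclpm_panel(study_params, 5000, 5000, seed=7)
        spec = default_trait_specs()[1]
        mp = tl.MeasurementParams(
            trait="psychopathology",
            loadings={ind: 0.0 for ind in spec.indicators},
            uniqueness={ind: 1.0 for ind in spec.indicators})
        ind = tl.emit_indicators(_standardize_panel(panel), mp, seed=8)
        fit = tl.fit_general_factor(ind, spec)
        # the ML factor chases the top sample eigenvalue, which sits at
        # ≈ (1 + sqrt(p/n))² even for pure noise; bound loadings by that
        p_, n_ = 21, 20000
        noise_lam = np.sqrt(((1 + np.sqrt(p_ / n_)) ** 2 - 1))
        assert np.abs(fit.lam).max() < noise_lam
        assert fit.explained_variance < 0.01

    def test_explained_variance_matches_brute_force_accounting(self):
        _, ind = indicator_panel(1000, 1000, seed=9)
        spec = default_trait_specs()[1]
        fit = tl.fit_general_factor(ind, spec)
        shares = [fit.lam[i] ** 2 / (fit.lam[i] ** 2 + fit.psi[i, t])
                  for i in range(len(spec.indicators)) for t in range(3)]
        assert abs(fit.explained_variance - np.mean(shares)) < 1e-10
        # and against the implied covariance: common variance of each
        # standardized indicator is total minus uniqueness
        sigma = fit.implied_cov()
        k = len(spec.indicators)
        tot = np.diag(sigma)
        uniq = fit.psi.T.reshape(-1)
        alt = np.mean((tot - uniq) / tot)
        assert abs(fit.explained_variance - alt) < 1e-10


class TestFactorScores:
    def test_score_matches_single_indicator_when_uniqueness_vanishes(self, study_params):
        panel = tl.simulate_riclpm_panel(study_params, 200, 200, seed=10)
        mp = tl.MeasurementParams(
            trait="psychopathology",
            loadings={"a": 0.9, "b": 0.7}, uniqueness={"a": 1e-6, "b": 0.51})
        ind = tl.emit_indicators(_standardize_panel(panel), mp, seed=11)
        spec = tl.TraitSpec(name="psychopathology", indicators=("a", "b"), anchor="a")
        fit = tl.fit_general_factor(ind, spec)
        scores = tl.factor_scores(fit, ind)
        s = scores.df[column_name("psychopathology", 1, 1)]
        x = ind.df[column_name("a", 1, 1)]
        assert abs(abs(np.corrcoef(s, x)[0, 1]) - 1.0) < 1e-3

    def test_score_validity_matches_closed_form_determinacy(self):
        panel, ind = indicator_panel(5000, 5000, seed=12)
        spec = default_trait_specs()[1]
        fit = tl.fit_general_factor(ind, spec)
        scores = tl.factor_scores(fit, ind)
        sigma1 = np.outer(fit.lam, fit.lam) + np.diag(fit.psi[:, 0])
        determinacy = float(np.sqrt(fit.lam @ np.linalg.solve(sigma1, fit.lam)))
        s = scores.df[column_name("psychopathology", 1, 1)].to_numpy()
        f = panel.df[column_name("psychopathology", 1, 1)].to_numpy()
        r = np.corrcoef(s, f)[0, 1]
        assert abs(r - determinacy) < 3 / np.sqrt(len(s))
        assert abs(s.mean()) < 3 / np.sqrt(len(s))  # centred by construction

    def test_missing_wave_gives_missing_score_only_for_that_wave(self):
        _, ind = indicator_panel(30, 30, seed=13)
        spec = default_trait_specs()[1]
        # blank all wave-2 indicators for twin 1 of every pair
        repl = {(i, 2, 1): np.full(ind.n_pairs, np.nan) for i in spec.indicators}
        holed = ind.replace_values(repl)
        fit = tl.fit_general_factor(ind, spec)
        scores = tl.factor_scores(fit, holed)
        assert scores.df[column_name("psychopathology", 2, 1)].isna().all()
        assert scores.df[column_name("psychopathology", 1, 1)].notna().all()
        assert scores.df[column_name("psychopathology", 2, 2)].notna().all()

    def test_scores_invariant_to_pair_order(self):
        _, ind = indicator_panel(50, 50, seed=14)
        spec = default_trait_specs()[1]
        fit = tl.fit_general_factor(ind, spec)
        direct = tl.factor_scores(fit, ind)
        swapped = tl.factor_scores(fit, ind.swap_twins())
        np.testing.assert_allclose(
            direct.df[column_name("psychopathology", 1, 1)],
            swapped.df[column_name("psychopathology", 1, 2)], atol=1e-12)


class TestAggregateComposite:
    def _scores(self, n_mz, n_dz, seed):
        _, ind = indicator_panel(n_mz, n_dz, seed=seed)
        spec = default_trait_specs()[1]
        fit = tl.fit_general_factor(ind, spec)
        return tl.factor_scores(fit, ind)

    def test_perfectly_correlated_waves_give_identical_composite(self, study_params):
        panel = tl.simulate_riclpm_panel(study_params, 100, 100, seed=15)
        base = panel.df[column_name("personality", 1, 1)].to_numpy()
        base2 = panel.df[column_name("personality", 1, 2)].to_numpy()
        repl = {("personality", t, 1): base for t in (1, 2, 3)}
        repl |= {("personality", t, 2): base2 for t in (1, 2, 3)}
        const = panel.replace_values(repl)
        comp = tl.aggregate_composite(const, "personality")
        c = comp.df[column_name("personality_composite", 1, 1)]
        assert abs(np.corrcoef(c, base)[0, 1] - 1.0) < 1e-8

    def test_independent_waves_flag_degenerate_composite(self, rng):
        n = 6000
        df = pd.DataFrame({"pair_id": [f"p{i}" for i in range(n)],
                           "zygosity": ["MZ", "DZ"] * (n // 2),
                           "sex_t1": 0, "sex_t2": 1})
        for t in (1, 2, 3):
            df[column_name("x", t, 1)] = rng.standard_normal(n)
            df[column_name("x", t, 2)] = rng.standard_normal(n)
        panel = tl.TwinPanelData(df, ("x",), (1, 2, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            tl.aggregate_composite(panel, "x")

    def test_fewer_than_two_waves_gives_missing_composite(self):
        scores = self._scores(30, 30, seed=16)
        repl = {("psychopathology", t, 1): np.full(scores.n_pairs, np.nan)
                for t in (2, 3)}
        holed = scores.replace_values(repl)
        comp = tl.aggregate_composite(holed, "psychopathology")
        assert comp.df[column_name("psychopathology_composite", 1, 1)].isna().all()
        assert comp.df[column_name("psychopathology_composite", 1, 2)].notna().all()

    def test_composite_attenuates_occasion_noise(self):
        # MZ cross-twin correlation of the composite exceeds any single wave
        scores = self._scores(1500, 500, seed=17)
        comp = tl.aggregate_composite(scores, "psychopathology")
        wave = tl.cross_twin_correlations(scores, "MZ").cross_twin["MZ"]
        comp_r = tl.cross_twin_correlations(comp, "MZ").cross_twin["MZ"].iloc[0, 0]
        assert comp_r > np.diag(wave.to_numpy()).max()
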