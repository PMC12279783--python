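"""Synthetic twin-panel generators: degenerate cases, determinism,
genetic cross-twin structure and missingness mechanics."""

import numpy as np
import pandas as pd
import pytest

import twinlag as tl
from twinlag import calibration as cal
from twinlag.data import column_name
from twinlag.simulate import MissingnessSpec, RiclpmParams

Z2 = np.zeros((2, 2))


def degenerate_params(**kwargs):
    base = dict(
        sigma_a_ri=Z2, sigma_e_ri=Z2, B=np.zeros((2, 2, 2)),
        sigma_a_w1=Z2, sigma_e_w1=Z2,
        sigma_a_u=np.zeros((2, 2, 2)), sigma_e_u=np.zeros((2, 2, 2)),
        mu=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
    )
    base.update(kwargs)
    return RiclpmParams(**base)


class TestRiclpmGenerator:
    def test_zero_variance_yields_means_plus_sex_effect(self):
        p = degenerate_params(sex_effect=np.array([0.5, -0.5]))
        panel = tl.simulate_riclpm_panel(p, 5, 5, seed=0)
        for k, trait in enumerate(p.traits):
            for t in range(3):
                for j in (1, 2):
                    got = panel.df[column_name(trait, t + 1, j)].to_numpy()
                    sex = panel.df[f"sex_t{j}"].to_numpy()
                    np.testing.assert_allclose(
                        got, p.mu[k, t] + p.sex_effect[k] * sex, atol=1e-12)

    def test_mz_pairs_identical_when_e_is_zero(self, study_params):
        p = study_params.copy_with(
            sigma_e_ri=Z2, sigma_e_w1=Z2, sigma_e_u=np.zeros((2, 2, 2)),
            sex_effect=np.zeros(2))
        panel = tl.simulate_riclpm_panel(p, 50, 0, seed=1)
        for trait in p.traits:
            for t in (1, 2, 3):
                np.testing.assert_allclose(
                    panel.df[column_name(trait, t, 1)],
                    panel.df[column_name(trait, t, 2)], atol=1e-10)

    def test_fixed_seed_is_bit_reproducible(self, study_params):
        a = tl.simulate_riclpm_panel(study_params, 30, 40, seed=11)
        b = tl.simulate_riclpm_panel(study_params, 30, 40, seed=11)
        pd.testing.assert_frame_equal(a.df, b.df)
        c = tl.simulate_riclpm_panel(study_params, 30, 40, seed=12)
        assert not a.df.equals(c.df)

    def test_non_psd_block_rejected_before_sampling(self, study_params):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # corr 2: not PSD
        with pytest.raises(ValueError, match="positive semidefinite"):
            study_params.copy_with(sigma_a_ri=bad)


class TestIndicatorEmission:
    def test_unit_loading_zero_uniqueness_reproduces_factor(self, study_params):
        panel = tl.simulate_riclpm_panel(study_params, 10, 10, seed=2)
        mp = tl.MeasurementParams(
            trait="personality", loadings={"ind": 1.0}, uniqueness={"ind": 0.0})
        out = tl.emit_indicators(panel, mp, seed=0)
        for t in (1, 2, 3):
            np.testing.assert_allclose(
                out.df[column_name("ind", t, 1)],
                panel.df[column_name("personality", t, 1)], atol=1e-12)

    def test_loading_recovers_indicator_factor_correlation(self, study_params):
        # depressive-symptoms-style loading 0.80, uniqueness 0.36
        panel = tl.simulate_riclpm_panel(
            cal.study_riclpm_params(sex_effect=(0, 0)), 12500, 12500, seed=3)
        from twinlag.pipeline import _standardize_panel

        std = _standardize_panel(panel)
        mp = tl.MeasurementParams(
            trait="psychopathology", loadings={"dep": 0.80}, uniqueness={"dep": 0.36})
        out = tl.emit_indicators(std, mp, seed=1)
        f = std.df[column_name("psychopathology", 1, 1)]
        x = out.df[column_name("dep", 1, 1)]
        r = np.corrcoef(f, x)[0, 1]
        se = (1 - 0.8 ** 2) / np.sqrt(len(f))
        assert abs(r - 0.80) < 3 * se + 0.005

    def test_unknown_factor_raises(self, study_params):
        panel = tl.simulate_riclpm_panel(study_params, 3, 3, seed=0)
        mp = tl.MeasurementParams(trait="nope", loadings={"x": 1.0}, uniqueness={"x": 0.1})
        with pytest.raises(ValueError, match="nope"):
            tl.emit_indicators(panel, mp, seed=0)


class TestCholeskyGenerator:
    def test_e_only_model_has_no_cross_twin_covariance(self):
        p = tl.CholeskyParams(labels=("x", "y"), a=Z2, c=Z2,
                              e=np.linalg.cholesky(np.eye(2)))
        panel = tl.simulate_cholesky_panel(p, 20000, 20000, seed=4)
        for z in ("MZ", "DZ"):
            rep = tl.cross_twin_correlations(panel, z)
            # pairs (not double-entered rows) are the independent units
            assert np.abs(rep.cross_twin[z].to_numpy()).max() < 3 / np.sqrt(20000)

    def test_pure_additive_dz_correlation_is_half(self):
        p = tl.CholeskyParams(labels=("x",), a=[[1.0]], c=[[0.0]], e=[[0.0]])
        panel = tl.simulate_cholesky_panel(p, 10000, 20000, seed=5)
        r_mz = tl.cross_twin_correlations(panel, "MZ").cross_twin["MZ"].iloc[0, 0]
        r_dz = tl.cross_twin_correlations(panel, "DZ").cross_twin["DZ"].iloc[0, 0]
        assert abs(r_mz - 1.0) < 1e-10
        assert abs(r_dz - 0.5) < 3 * 0.75 / np.sqrt(20000)

    def test_dimension_mismatch_raises(self):
        p = tl.CholeskyParams(labels=("x", "y"), a=Z2, c=Z2, e=np.eye(2))
        p.a = np.eye(3)
        with pytest.raises(ValueError, match="dimension"):
            p.validate()


class TestMissingness:
    def test_zero_probabilities_are_identity(self, study_params):
        panel = tl.simulate_riclpm_panel(study_params, 20, 20, seed=6)
        out = tl.apply_missingness(panel, MissingnessSpec(), seed=0)
        pd.testing.assert_frame_equal(out.df, panel.df)

    def test_certain_cell_mcar_masks_everything(self, study_params):
        panel = tl.simulate_riclpm_panel(study_params, 10, 10, seed=6)
        out = tl.apply_missingness(
            panel, MissingnessSpec(cell_mcar_prob=1.0), seed=0)
        assert out.df[out.value_columns()].isna().all().all()
        # pre-mask values preserved for truth comparison
        assert out.complete_values[panel.value_columns()].notna().all().all()

    def test_wave_dropout_fractions_match_binomial_expectation(self, study_params):
        probs = (0.0, 0.24, 0.37)
        panel = tl.simulate_riclpm_panel(study_params, 2500, 2500, seed=7)
        out = tl.apply_missingness(panel, MissingnessSpec(wave_dropout_prob=probs), seed=1)
        n = 2 * out.n_pairs
        for t, p_drop in zip((1, 2, 3), probs):
            observed = np.concatenate([
                out.df[column_name(out.traits[0], t, j)].notna() for j in (1, 2)])
            frac = observed.mean()
            se = np.sqrt(p_drop * (1 - p_drop) / n) if p_drop else 0.0
            assert abs(frac - (1 - p_drop)) <= 3 * se + 1e-12

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            MissingnessSpec(wave_dropout_prob=(0.0, 1.2, 0.0))


def test_study_missingness_mirrors_participation_rates():
    spec = cal.study_missingness()
    np.testing.assert_allclose(
        1 - np.array(spec.wave_dropout_prob),
        np.array([1393, 1065, 883]) / 1538, atol=1e-12)
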