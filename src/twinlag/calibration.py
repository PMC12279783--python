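"""Study-calibrated generator parameter sets.

Builds the default synthetic-data conditions from the quantities the
analysis chain is designed to recover: random-intercept (RI) variance
shares per wave, A/E splits of the RI variance, the RI genetic
correlation, standardized Cholesky variance components, and the
measurement loadings. Quantities the source tables do not pin down
(within-process autoregression, within-process cross-trait correlation
and A-share, the RI E-correlation) are explicit keyword defaults chosen
to land the implied phenotypic and twin correlations in realistic
ranges; see docs/methods.md for the rationale behind each default.
"""

from __future__ import annotations

import numpy as np

from .cholesky import CholeskyParams
from .data import default_trait_specs
from .simulate import MeasurementParams, MissingnessSpec, RiclpmParams

__all__ = [
    "study_riclpm_params",
    "study_measurement_params",
    "study_cholesky_params",
    "study_missingness",
    "calibrate_cross_lag",
    "STUDY_N_MZ",
    "STUDY_N_DZ",
]

#: study composition: 577 MZ and 961 DZ pairs
STUDY_N_MZ = 577
STUDY_N_DZ = 961

#: default recovery targets (trait order: personality, psychopathology)
RI_SHARES = ((0.53, 0.58, 0.64), (0.39, 0.38, 0.45))
A_SHARE_RI = (0.70, 0.83)
R_A_RI = -0.55

#: standardized factor loadings of the two general factors
PERSONALITY_LOADINGS = {
    "neuroticism": -0.55,
    "extraversion": 0.71,
    "openness": 0.65,
    "agreeableness": 0.25,
    "conscientiousness": 0.53,
}
PSYCHOPATHOLOGY_LOADINGS = {
    "depressive": 0.80,
    "anxiety": 0.67,
    "somatic": 0.73,
    "eating": 0.58,
    "delinquency": 0.41,
    "conduct": 0.41,
    "substance": 0.40,
}


def _split_cov(total: np.ndarray, shares: tuple[float, float]):
    """Split a 2×2 covariance into A and E parts with given diagonal
    A-shares, dividing the off-diagonal proportionally to the geometric
    mean of the shares so both parts stay positive semidefinite."""
    sA = np.asarray(shares, dtype=float)
    sE = 1.0 - sA
    gA, gE = np.sqrt(sA[0] * sA[1]), np.sqrt(sE[0] * sE[1])
    off = total[0, 1]
    offA = off * gA / (gA + gE)
    A = np.array([[sA[0] * total[0, 0], offA], [offA, sA[1] * total[1, 1]]])
    E = total - A
    return A, E


def study_riclpm_params(
    ri_shares=RI_SHARES,
    a_share_ri=A_SHARE_RI,
    r_a_ri: float = R_A_RI,
    r_e_ri: float = -0.30,
    var_ri=(1.0, 1.0),
    autoregression=(0.35, 0.45),
    within_a_share=(0.30, 0.40),
    within_cross_corr: float = -0.40,
    sex_effect=(0.15, -0.25),
) -> RiclpmParams:
    """Biometric RI-CLPM generating parameters at the study conditions.

    The wave-specific innovation covariances are solved so the
    within-process variances reproduce the requested RI variance shares
    exactly, given the autoregressive coefficients (cross-lags zero; use
    :func:`calibrate_cross_lag` to inject one). Raises if the requested
    shares are unattainable (non-PSD innovations).
    """
    var_ri = np.asarray(var_ri, dtype=float)
    sA = np.asarray(a_share_ri, dtype=float)
    varA = sA * var_ri
    varE = (1 - sA) * var_ri
    sigma_a_ri = np.array([
        [varA[0], r_a_ri * np.sqrt(varA[0] * varA[1])],
        [r_a_ri * np.sqrt(varA[0] * varA[1]), varA[1]],
    ])
    sigma_e_ri = np.array([
        [varE[0], r_e_ri * np.sqrt(varE[0] * varE[1])],
        [r_e_ri * np.sqrt(varE[0] * varE[1]), varE[1]],
    ])
    shares = np.asarray(ri_shares, dtype=float)          # (2 traits, 3 waves)
    var_w = var_ri[:, None] * (1 - shares) / shares      # within variance per wave
    B = np.stack([np.diag(autoregression), np.diag(autoregression)])
    cw = []
    for t in range(3):
        off = within_cross_corr * np.sqrt(var_w[0, t] * var_w[1, t])
        cw.append(np.array([[var_w[0, t], off], [off, var_w[1, t]]]))
    su = []
    for t in range(2):
        S = cw[t + 1] - B[t] @ cw[t] @ B[t].T
        if np.linalg.eigvalsh(S).min() < 0:
            raise ValueError(
                "requested RI shares/autoregression imply non-PSD innovations")
        su.append(S)
    sigma_a_w1, sigma_e_w1 = _split_cov(cw[0], within_a_share)
    splits = [_split_cov(s, within_a_share) for s in su]
    return RiclpmParams(
        sigma_a_ri=sigma_a_ri, sigma_e_ri=sigma_e_ri,
        B=B,
        sigma_a_w1=sigma_a_w1, sigma_e_w1=sigma_e_w1,
        sigma_a_u=np.stack([s[0] for s in splits]),
        sigma_e_u=np.stack([s[1] for s in splits]),
        sex_effect=np.asarray(sex_effect, dtype=float),
    )


def calibrate_cross_lag(
    params: RiclpmParams,
    interval: int = 1,
    target: int = 1,
    source: int = 0,
    std_value: float = 0.10,
    n_iter: int = 50,
) -> RiclpmParams:
    """Return params with one cross-lagged path set so its *standardized*
    value equals ``std_value``, solving the fixed point that the target
    trait's within-process variance itself depends on the path."""
    from .riclpm import within_covariances

    p = params
    b = 0.0
    for _ in range(n_iter):
        B = p.B.copy()
        B[interval, target, source] = b
        p = params.copy_with(B=B)
        cw, _, _ = within_covariances(p)
        sd_src = np.sqrt(cw[interval][source, source])
        sd_tgt = np.sqrt(cw[interval + 1][target, target])
        b_new = std_value * sd_tgt / sd_src
        if abs(b_new - b) < 1e-12:
            b = b_new
            break
        b = b_new
    B = params.B.copy()
    B[interval, target, source] = b
    return params.copy_with(B=B)


def study_measurement_params() -> list[MeasurementParams]:
    """Measurement layer at the printed standardized loadings, with
    uniqueness 1 − λ² so unit-variance factors yield unit-variance
    standardized indicators."""
    pers, psych = default_trait_specs()
    out = []
    for spec, loadings in (
        (pers, PERSONALITY_LOADINGS),
        (psych, PSYCHOPATHOLOGY_LOADINGS),
    ):
        lam = {ind: loadings[ind] for ind in spec.indicators}
        psi = {ind: 1.0 - loadings[ind] ** 2 for ind in spec.indicators}
        out.append(MeasurementParams(trait=spec.name, loadings=lam, uniqueness=psi))
    return out


def study_cholesky_params(
    a2=(0.63, 0.57),
    e2=(0.37, 0.43),
    r_a: float = -0.513,
    r_e: float = -0.374,
    labels=("psychopathology_composite", "personality_composite"),
    total_var=(1.0, 1.0),
    sex_means=((0.0, 0.0), (0.0, 0.0)),
) -> CholeskyParams:
    """Bivariate AE Cholesky generating parameters for the composite
    phenotypes (first label ordered first in the decomposition)."""
    a2 = np.asarray(a2, float) * np.asarray(total_var, float)
    e2 = np.asarray(e2, float) * np.asarray(total_var, float)
    A = np.array([[a2[0], r_a * np.sqrt(a2[0] * a2[1])],
                  [r_a * np.sqrt(a2[0] * a2[1]), a2[1]]])
    E = np.array([[e2[0], r_e * np.sqrt(e2[0] * e2[1])],
                  [r_e * np.sqrt(e2[0] * e2[1]), e2[1]]])
    return CholeskyParams(
        labels=tuple(labels),
        a=np.linalg.cholesky(A),
        c=np.zeros((2, 2)),
        e=np.linalg.cholesky(E),
        means=np.asarray(sex_means, float),
    )


def study_missingness() -> MissingnessSpec:
    """Wave-level dropout matching the study's participation counts
    (1393 / 1065 / 883 of 1538 pairs across the three waves)."""
    participation = np.array([1393, 1065, 883]) / 1538
    return MissingnessSpec(wave_dropout_prob=tuple(1 - participation))
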