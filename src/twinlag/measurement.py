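"""General-factor measurement stage.

Imputation of missing scale scores, maximum-likelihood one-factor models
with loadings constrained equal across the three measurement waves
(conceptual consistency: observed change in the general factor reflects
change in the construct, not shifting indicator weights), regression
(Thurstone) factor scores, and cross-wave aggregation into composite
scores capturing the shared variance across waves.

Indicators are z-standardized before factor analysis because the
constituent scales have heterogeneous ranges. Factor variances are fixed
at 1; the factor sign is oriented so a designated anchor indicator loads
positively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fiml
from .data import TraitSpec, TwinPanelData, column_name

__all__ = [
    "FactorModelFit",
    "impute_fcs",
    "fit_general_factor",
    "factor_scores",
    "aggregate_composite",
]

_N_WAVES = 3


@dataclass
class FactorModelFit:
    """Constrained one-factor-per-wave measurement model.

    One factor per wave, factors correlated (``phi``), loadings ``lam``
    shared bit-identically across waves by parameterization, uniquenesses
    ``psi`` free per indicator and wave, factor variances fixed at 1.
    """

    spec: TraitSpec
    lam: np.ndarray              # (k,)
    psi: np.ndarray              # (k, 3)
    phi: np.ndarray              # (3, 3) inter-wave factor correlations
    explained_variance: float
    loglik: float
    n_params: int
    n_obs: int
    scaler_mean: np.ndarray      # (3k,) column means used for z-scoring
    scaler_sd: np.ndarray
    converged: bool
    heywood: bool = False

    @property
    def waves(self):
        return (1, 2, 3)

    def lambda_matrix(self) -> np.ndarray:
        """(3k × 3) loading matrix in wave-major column order."""
        k = len(self.lam)
        L = np.zeros((3 * k, 3))
        for t in range(3):
            L[t * k:(t + 1) * k, t] = self.lam
        return L

    def implied_cov(self) -> np.ndarray:
        L = self.lambda_matrix()
        return L @ self.phi @ L.T + np.diag(self.psi.T.reshape(-1))

    def loading_table(self) -> pd.DataFrame:
        rows = [{"indicator": ind, "loading": self.lam[i],
                 **{f"uniqueness_w{t + 1}": self.psi[i, t] for t in range(3)}}
                for i, ind in enumerate(self.spec.indicators)]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_fcs(
    data: TwinPanelData,
    n_imputations: int = 10,
    n_iterations: int = 10,
    seed: int = 0,
) -> TwinPanelData:
    """Chained-equation (FCS) imputation, averaged over completed datasets.

    Each variable is imputed by a Bayesian linear regression on all other
    individual-level variables with posterior sampling; the cell-wise mean
    over ``n_imputations`` completed datasets is returned, so downstream
    stages receive mean scores. Co-twin variables are deliberately not
    used as predictors (twin models downstream handle pairs by FIML).
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    variables = [(k, t) for k in data.traits for t in data.waves]
    cols1 = [column_name(k, t, 1) for k, t in variables]
    cols2 = [column_name(k, t, 2) for k, t in variables]
    X = np.vstack([data.df[cols1].to_numpy(float), data.df[cols2].to_numpy(float)])
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [f"{k}_{t}" for (k, t), b in zip(variables, all_missing) if b]
        raise ValueError(f"variables with zero observed values: {bad}")
    if not np.isnan(X).any():
        return TwinPanelData(data.df.copy(), data.traits, data.waves)
    acc = np.zeros_like(X)
    for i in range(n_imputations):
        imputer = IterativeImputer(
            max_iter=n_iterations, sample_posterior=True,
            random_state=seed + i, tol=1e-4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            acc += imputer.fit_transform(X)
    X_imp = acc / n_imputations
    n = data.n_pairs
    df = data.df.copy()
    for j, c in enumerate(cols1):
        df[c] = X_imp[:n, j]
    for j, c in enumerate(cols2):
        df[c] = X_imp[n:, j]
    return TwinPanelData(df, data.traits, data.waves)


# ---------------------------------------------------------------------------
# constrained one-factor model
# ---------------------------------------------------------------------------

def _phi_from_raw(z: np.ndarray) -> np.ndarray:
    L = np.array([[1.0, 0.0, 0.0], [z[0], 1.0, 0.0], [z[1], z[2], 1.0]])
    L /= np.linalg.norm(L, axis=1, keepdims=True)
    return L @ L.T


def _indicator_columns(spec: TraitSpec) -> list[tuple[str, int]]:
    # wave-major order: all indicators at wave 1, then wave 2, wave 3
    return [(ind, t) for t in (1, 2, 3) for ind in spec.indicators]


def _individual_matrix(data: TwinPanelData, variables) -> np.ndarray:
    cols1 = [column_name(k, t, 1) for k, t in variables]
    cols2 = [column_name(k, t, 2) for k, t in variables]
    return np.vstack([data.df[cols1].to_numpy(float), data.df[cols2].to_numpy(float)])


def fit_general_factor(
    data: TwinPanelData,
    spec: TraitSpec,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 4000,
) -> FactorModelFit:
    """ML fit of the cross-wave loading-constrained one-factor model.

    All individual twins are pooled, indicators z-scored, and a 3-factor
    model (one correlated factor per wave) fitted to the 3k × 3k sample
    covariance with wave-invariant loadings. Uniquenesses are kept
    nonnegative by a log parameterization; a uniqueness driven to the
    boundary is flagged as a Heywood case.
    """
    variables = _indicator_columns(spec)
    k = len(spec.indicators)
    X = _individual_matrix(data, variables)
    X = X[~np.isnan(X).all(axis=1)]
    n_obs = len(X)
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    if np.any(sd <= 0):
        raise ValueError("constant indicator column")
    Z = (X - mean) / sd
    if np.isnan(Z).any():
        S = np.ma.cov(np.ma.masked_invalid(Z), rowvar=False).filled(0.0)
        S = np.atleast_2d(S)
        w, V = np.linalg.eigh((S + S.T) / 2)
        S = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
    else:
        S = np.cov(Z, rowvar=False, ddof=0)
    p = 3 * k
    sign_s, logdet_S = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample covariance not positive definite")

    def unpack(x):
        lam = x[:k]
        psi = np.exp(x[k:k + p]).reshape(3, k).T     # (k, 3)
        phi = _phi_from_raw(x[k + p:k + p + 3])
        return lam, psi, phi

    def objective(x):
        lam, psi, phi = unpack(x)
        L = np.zeros((p, 3))
        for t in range(3):
            L[t * k:(t + 1) * k, t] = lam
        sigma = L @ phi @ L.T + np.diag(psi.T.reshape(-1))
        try:
            cf = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2 * np.sum(np.log(np.diag(cf)))
        sol = np.linalg.solve(sigma, S)
        return logdet + np.trace(sol) - logdet_S - p

    # principal-component start averaged over waves
    lam0 = np.zeros(k)
    for t in range(3):
        block = S[t * k:(t + 1) * k, t * k:(t + 1) * k]
        w, V = np.linalg.eigh(block)
        v = V[:, -1] * np.sqrt(w[-1])
        if t == 0:
            ref = v
        v = v if v @ ref >= 0 else -v
        lam0 += v / 3
    psi0 = np.clip(1 - lam0 ** 2, 0.05, None)
    x0 = np.concatenate([lam0, np.log(np.tile(psi0, 3)), [0.6, 0.6, 0.6]])
    bounds = ([(None, None)] * k + [(-8.0, 8.0)] * p + [(None, None)] * 3)
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + 0.1 * rng.standard_normal(x0.size) for _ in range(n_starts - 1)]
    res = _fiml.minimize_multistart(objective, starts, bounds=bounds, maxiter=maxiter)
    if res.fun >= 1e11:
        raise RuntimeError(f"factor model failed to converge: {res.message}")
    lam, psi, phi = unpack(res.x)
    anchor = spec.anchor or spec.indicators[0]
    if lam[spec.indicators.index(anchor)] < 0:
        lam = -lam
    heywood = bool((psi < 1e-3).any())
    if heywood:
        warnings.warn("uniqueness at lower bound (Heywood case)", stacklevel=2)
    explained = float(np.mean(lam[:, None] ** 2 / (lam[:, None] ** 2 + psi)))
    fml = res.fun
    loglik = -0.5 * n_obs * (p * np.log(2 * np.pi) + fml + logdet_S + p)
    return FactorModelFit(
        spec=spec, lam=lam, psi=psi, phi=phi,
        explained_variance=explained,
        loglik=float(loglik), n_params=k + p + 3, n_obs=n_obs,
        scaler_mean=mean, scaler_sd=sd,
        converged=bool(res.success), heywood=heywood,
    )


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def factor_scores(fit: FactorModelFit, data: TwinPanelData) -> TwinPanelData:
    """Regression-method (Thurstone) factor scores per trait and wave.

    The wave-t score is λᵀ Σ_t⁻¹ z_t over that wave's z-scored indicators
    with Σ_t = λλᵀ + Ψ_t the wave's model-implied covariance: each wave is
    scored from its own indicators only, so the occasion-specific
    information in the scores is not contaminated by other waves (the
    within/between decomposition downstream depends on this). Missing
    indicators are handled through the observed sub-vector's implied
    covariance; a wave with no observed indicator yields a missing score.
    """
    spec = fit.spec
    variables = _indicator_columns(spec)
    k = len(spec.indicators)
    n = data.n_pairs
    scores = {}
    for j in (1, 2):
        cols = [column_name(kk, t, j) for kk, t in variables]
        X = data.df[cols].to_numpy(float)
        Z = (X - fit.scaler_mean) / fit.scaler_sd
        out = np.full((n, 3), np.nan)
        for t in range(3):
            Zt = Z[:, t * k:(t + 1) * k]
            sigma_t = np.outer(fit.lam, fit.lam) + np.diag(fit.psi[:, t])
            mask = ~np.isnan(Zt)
            codes = mask @ (1 << np.arange(k, dtype=np.int64))
            for code in np.unique(codes):
                rows = np.flatnonzero(codes == code)
                obs = np.flatnonzero(mask[rows[0]])
                if obs.size == 0:
                    continue
                w = np.linalg.solve(sigma_t[np.ix_(obs, obs)], fit.lam[obs])
                out[rows, t] = Zt[np.ix_(rows, obs)] @ w
        scores[j] = out
    df = data.df[["pair_id", "zygosity", "sex_t1", "sex_t2"]].copy()
    for j in (1, 2):
        for t in range(3):
            df[column_name(spec.name, t + 1, j)] = scores[j][:, t]
    return TwinPanelData(df, (spec.name,), (1, 2, 3))


# ---------------------------------------------------------------------------
# cross-wave composite
# ---------------------------------------------------------------------------

def aggregate_composite(scores: TwinPanelData, trait: str) -> TwinPanelData:
    """One-factor composite over the three wave scores of ``trait``.

    An ML one-factor model over the wave-1..3 scores captures their
    shared variance; the regression factor score is the composite. Twins
    with fewer than two observed waves get a missing composite. Near-zero
    loadings (no shared variance) raise a degenerate-composite warning.
    """
    if trait not in scores.traits:
        raise ValueError(f"unknown trait {trait!r}")
    variables = [(trait, t) for t in scores.waves]
    X = _individual_matrix(scores, variables)
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    Z = (X - mean) / sd
    if np.isnan(Z).any():
        S = np.atleast_2d(np.ma.cov(np.ma.masked_invalid(Z), rowvar=False).filled(0.0))
    else:
        S = np.cov(Z, rowvar=False, ddof=0)
    sign_s, logdet_S = np.linalg.slogdet(S)
    if sign_s <= 0:
        # perfectly collinear wave scores: logdet(S) is an additive
        # constant in the ML discrepancy, so a singular S is harmless
        logdet_S = 0.0

    def objective(x):
        lam = x[:3]
        psi = np.exp(x[3:])
        sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            cf = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        return (2 * np.sum(np.log(np.diag(cf)))
                + np.trace(np.linalg.solve(sigma, S)) - logdet_S - 3)

    w, V = np.linalg.eigh(S)
    # equal-loading one-factor model on a correlation matrix has top
    # eigenvalue 1 + (p−1)λ²; invert that for the start
    lam0 = V[:, -1] * np.sqrt(3 * max((w[-1] - 1) / 2, 1e-4))
    if lam0.sum() < 0:
        lam0 = -lam0
    x0 = np.concatenate([lam0, np.log(np.clip(1 - lam0 ** 2, 0.05, None))])
    res = _fiml.minimize_multistart(
        objective, [x0], bounds=[(None, None)] * 3 + [(-8, 8)] * 3)
    lam = res.x[:3]
    psi = np.exp(res.x[3:])
    if lam.sum() < 0:
        lam = -lam
    # degenerate when the factor implies (almost) no shared variance
    # between any pair of waves: |λᵢλⱼ| is the implied cross-wave
    # covariance of the standardized scores
    cross = np.abs(np.outer(lam, lam))
    if cross[~np.eye(3, dtype=bool)].max() < 0.15 ** 2:
        warnings.warn(f"degenerate composite for {trait!r}: wave scores share "
                      "almost no variance", stacklevel=2)
    sigma = np.outer(lam, lam) + np.diag(psi)
    n = scores.n_pairs
    comp = {}
    for j in (1, 2):
        cols = [column_name(trait, t, j) for t in scores.waves]
        Zj = (scores.df[cols].to_numpy(float) - mean) / sd
        out = np.full(n, np.nan)
        mask = ~np.isnan(Zj)
        enough = mask.sum(axis=1) >= 2
        codes = mask @ np.array([1, 2, 4])
        for code in np.unique(codes[enough]):
            rows = np.flatnonzero(enough & (codes == code))
            obs = np.flatnonzero(mask[rows[0]])
            wvec = np.linalg.solve(sigma[np.ix_(obs, obs)], lam[obs])
            out[rows] = Zj[np.ix_(rows, obs)] @ wvec
        comp[j] = out
    name = f"{trait}_composite"
    df = scores.df[["pair_id", "zygosity", "sex_t1", "sex_t2"]].copy()
    df[column_name(name, 1, 1)] = comp[1]
    df[column_name(name, 1, 2)] = comp[2]
    return TwinPanelData(df, (name,), (1,))
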