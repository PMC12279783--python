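"""Genetically informative random-intercept cross-lagged panel model.

Two traits observed at three waves in twin pairs. Each twin's score
decomposes into a time-invariant random intercept (RI, between-person
stability) and a within-person process with per-interval autoregressive
and cross-lagged dynamics. Both components split into an additive-genetic
part A (cross-twin correlation 1 for MZ, 0.5 for DZ pairs — the A parts
of the within-process innovations receive the same genetic correlation as
the RI A parts) and a non-shared-environment part E (independent between
co-twins). The A and E streams of the within-person process share the
same dynamics matrix B: a single process observed as an A + E mixture.

Estimation is two-group full-information maximum likelihood on the
12-dimensional pair vector (2 twins × 2 traits × 3 waves), on an
unconstrained log-Cholesky parameterization of every 2×2 covariance
block. Shared-environment (C) influences are intentionally absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _fiml
from .data import TwinPanelData
from .simulate import GENETIC_CORRELATION, RiclpmParams

__all__ = [
    "RiclpmFit",
    "DerivedStability",
    "CrossLagTest",
    "riclpm_implied_moments",
    "within_covariances",
    "fit_riclpm",
    "fit_indices",
    "test_cross_lags",
    "derived_stability",
]

N_WAVES = 3
N_PARAMS_FULL = 38  # 8 blocks × 3 + 2 dynamics × 4 + 6 means

# packed-vector layout
_BLOCK_NAMES = (
    "sigma_a_ri", "sigma_e_ri", "sigma_a_w1", "sigma_e_w1",
    "sigma_a_u0", "sigma_a_u1", "sigma_e_u0", "sigma_e_u1",
)
_B_OFFSET = 24
_MU_OFFSET = 32

#: packed index of each cross-lagged coefficient B[t][target, source]
CROSS_LAG_INDEX = {
    (0, 0, 1): _B_OFFSET + 1,
    (0, 1, 0): _B_OFFSET + 2,
    (1, 0, 1): _B_OFFSET + 4 + 1,
    (1, 1, 0): _B_OFFSET + 4 + 2,
}


@dataclass
class RiclpmFit:
    params: RiclpmParams
    minus2lnl: float
    n_params: int
    n_pairs: int
    converged: bool
    x: np.ndarray                       # packed parameter vector
    fixed: dict[int, float] = field(default_factory=dict)
    data_fingerprint: int = 0
    optimizer_message: str = ""
    # filled in by fit_indices()
    chi2_model: float | None = None
    df_model: int | None = None
    cfi: float | None = None
    tli: float | None = None
    rmsea: float | None = None

    @property
    def aic(self) -> float:
        return self.minus2lnl + 2 * self.n_params

    @property
    def bic(self) -> float:
        return self.minus2lnl + self.n_params * np.log(self.n_pairs)


@dataclass
class DerivedStability:
    """Variance-share and correlation summaries derived from a fit."""

    traits: tuple[str, str]
    ri_share: np.ndarray        # (2, 3): RI variance / total, per trait & wave
    a_share_ri: np.ndarray      # (2,): A share of RI variance
    e_share_ri: np.ndarray
    r_a_ri: float               # genetic correlation between the two RIs
    r_e_ri: float
    std_paths: pd.DataFrame     # interval, source, target, unstd, std
    zero_ri_flag: tuple[bool, bool] = (False, False)


@dataclass
class CrossLagTest:
    label: str
    interval: int               # 0: wave1->2, 1: wave2->3
    target: int
    source: int
    chi2_diff: float
    df: int
    p_value: float
    available: bool = True


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def _wave_idx(t: int) -> list[int]:
    # trait-major variable order: index(trait k, wave t) = 3k + t
    return [t, N_WAVES + t]


def _stream_moments(sigma_ri, sigma_w1, sigma_u, B) -> np.ndarray:
    """6×6 covariance contribution of one (A or E) stream within a twin."""
    # the RI is constant over waves: its covariance tiles every wave block
    M = np.kron(sigma_ri, np.ones((N_WAVES, N_WAVES)))
    Cw = [np.asarray(sigma_w1, dtype=float)]
    for t in range(N_WAVES - 1):
        Cw.append(B[t] @ Cw[t] @ B[t].T + sigma_u[t])
    for t in range(N_WAVES):
        M[np.ix_(_wave_idx(t), _wave_idx(t))] += Cw[t]
    for t in range(N_WAVES):
        P = np.eye(2)
        for s in range(t + 1, N_WAVES):
            P = B[s - 1] @ P
            block = Cw[t] @ P.T          # Cov(w_t, w_s)
            M[np.ix_(_wave_idx(t), _wave_idx(s))] += block
            M[np.ix_(_wave_idx(s), _wave_idx(t))] += block.T
    return M


def stream_covariances(params: RiclpmParams) -> tuple[np.ndarray, np.ndarray]:
    """(M_A, M_E): 6×6 within-twin covariance of the A and E streams."""
    MA = _stream_moments(params.sigma_a_ri, params.sigma_a_w1, params.sigma_a_u, params.B)
    ME = _stream_moments(params.sigma_e_ri, params.sigma_e_w1, params.sigma_e_u, params.B)
    return MA, ME


def within_covariances(params: RiclpmParams):
    """Per-wave 2×2 covariances of the within-person process.

    Returns ``(total, a_part, e_part)``, each a list of three 2×2 arrays
    obtained by propagating the wave-1 covariance and innovations through
    the dynamics B.
    """
    def prop(s1, su):
        out = [np.asarray(s1, dtype=float)]
        for t in range(N_WAVES - 1):
            out.append(params.B[t] @ out[t] @ params.B[t].T + su[t])
        return out

    a = prop(params.sigma_a_w1, params.sigma_a_u)
    e = prop(params.sigma_e_w1, params.sigma_e_u)
    tot = [a[t] + e[t] for t in range(N_WAVES)]
    return tot, a, e


def riclpm_implied_moments(params: RiclpmParams, zygosity: str):
    """Model-implied mean (12,) and covariance (12, 12) of the pair vector.

    Variable order: twin 1 (trait-major: personality waves 1–3, then
    psychopathology waves 1–3), then twin 2. The cross-twin block is the
    A-stream covariance scaled by the zygosity genetic correlation; the E
    stream contributes only within twins. Means exclude sex effects (the
    model is meant for sex-residualized scores).
    """
    params.validate()
    r = GENETIC_CORRELATION[zygosity]
    MA, ME = stream_covariances(params)
    within = MA + ME
    cross = r * MA
    sigma = np.block([[within, cross], [cross, within]])
    mu = np.tile(params.mu.reshape(-1), 2)
    return mu, sigma


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _cov_to_logchol(S: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(np.asarray(S, float) + 1e-10 * np.eye(2))
    return np.array([np.log(max(L[0, 0], 1e-6)), L[1, 0], np.log(max(L[1, 1], 1e-6))])

def _logchol_to_cov(p) -> np.ndarray:
    L = np.array([[np.exp(p[0]), 0.0], [p[1], np.exp(p[2])]])
    return L @ L.T


def pack_params(params: RiclpmParams) -> np.ndarray:
    blocks = [params.sigma_a_ri, params.sigma_e_ri, params.sigma_a_w1,
              params.sigma_e_w1, params.sigma_a_u[0], params.sigma_a_u[1],
              params.sigma_e_u[0], params.sigma_e_u[1]]
    x = np.concatenate([_cov_to_logchol(b) for b in blocks]
                       + [params.B[0].reshape(-1), params.B[1].reshape(-1),
                          params.mu.reshape(-1)])
    return x


def _moments_from_x(x: np.ndarray):
    """(M_A, M_E, mu6) straight from the packed vector.

    Hot path for the optimizer: the log-Cholesky parameterization makes
    every block PSD by construction, so the dataclass validation is
    skipped.
    """
    covs = [_logchol_to_cov(x[3 * i:3 * i + 3]) for i in range(8)]
    B = (x[_B_OFFSET:_B_OFFSET + 4].reshape(2, 2),
         x[_B_OFFSET + 4:_B_OFFSET + 8].reshape(2, 2))
    MA = _stream_moments(covs[0], covs[2], (covs[4], covs[5]), B)
    ME = _stream_moments(covs[1], covs[3], (covs[6], covs[7]), B)
    return MA, ME, x[_MU_OFFSET:_MU_OFFSET + 6]


def unpack_params(x: np.ndarray, traits=("personality", "psychopathology")) -> RiclpmParams:
    covs = [_logchol_to_cov(x[3 * i:3 * i + 3]) for i in range(8)]
    B = np.stack([x[_B_OFFSET:_B_OFFSET + 4].reshape(2, 2),
                  x[_B_OFFSET + 4:_B_OFFSET + 8].reshape(2, 2)])
    mu = x[_MU_OFFSET:_MU_OFFSET + 6].reshape(2, 3)
    return RiclpmParams(
        sigma_a_ri=covs[0], sigma_e_ri=covs[1], sigma_a_w1=covs[2],
        sigma_e_w1=covs[3], sigma_a_u=np.stack([covs[4], covs[5]]),
        sigma_e_u=np.stack([covs[6], covs[7]]), B=B, mu=mu, traits=tuple(traits),
    )


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _psd_floor(M: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    M = (M + M.T) / 2
    w, V = np.linalg.eigh(M)
    return V @ np.diag(np.clip(w, floor, None)) @ V.T


def _nancov(X: np.ndarray) -> np.ndarray:
    C = np.ma.cov(np.ma.masked_invalid(X), rowvar=False).filled(0.0)
    return np.atleast_2d(np.asarray(C))


def _block(M: np.ndarray, t: int, s: int) -> np.ndarray:
    return M[np.ix_(_wave_idx(t), _wave_idx(s))]


def _moment_start(Y: np.ndarray, zyg: np.ndarray) -> np.ndarray:
    """Method-of-moments start: double-entry MZ cross-twin covariance
    estimates the A stream (AE model), the pooled within-twin covariance
    the total; RI blocks from the lag-2 wave block, dynamics by regression."""
    d = 2 * N_WAVES
    Y1, Y2 = Y[:, :d], Y[:, d:]
    within = _nancov(np.vstack([Y1, Y2]))
    mz = zyg == "MZ"
    stacked = np.hstack([np.vstack([Y1[mz], Y2[mz]]), np.vstack([Y2[mz], Y1[mz]])])
    C = _nancov(stacked)
    MA = (C[:d, d:] + C[:d, d:].T) / 2

    sig_ri_tot = _psd_floor((_block(within, 0, 2) + _block(within, 0, 2).T) / 2, 1e-3)
    sig_a_ri = _psd_floor((_block(MA, 0, 2) + _block(MA, 0, 2).T) / 2, 1e-3)
    sig_e_ri = _psd_floor(sig_ri_tot - sig_a_ri, 1e-3)
    cw_tot = [_psd_floor(_block(within, t, t) - sig_ri_tot, 5e-3) for t in range(3)]
    cw_a = [_psd_floor(_block(MA, t, t) - sig_a_ri, 5e-3) for t in range(3)]
    cw_e = [_psd_floor(cw_tot[t] - cw_a[t], 5e-3) for t in range(3)]
    B = []
    for t in range(2):
        lag = _block(within, t + 1, t) - sig_ri_tot
        B.append(lag @ np.linalg.pinv(cw_tot[t]))
    su_a = [_psd_floor(cw_a[t + 1] - B[t] @ cw_a[t] @ B[t].T, 5e-3) for t in range(2)]
    su_e = [_psd_floor(cw_e[t + 1] - B[t] @ cw_e[t] @ B[t].T, 5e-3) for t in range(2)]
    mu = np.nanmean(np.vstack([Y1, Y2]), axis=0).reshape(2, 3)
    start = RiclpmParams(
        sigma_a_ri=sig_a_ri, sigma_e_ri=sig_e_ri, sigma_a_w1=cw_a[0],
        sigma_e_w1=cw_e[0], sigma_a_u=np.stack(su_a), sigma_e_u=np.stack(su_e),
        B=np.stack([np.clip(b, -0.95, 0.95) for b in B]), mu=mu,
    )
    return pack_params(start)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fingerprint(Y: np.ndarray) -> int:
    return hash((Y.shape, np.nansum(Y).round(8), int(np.isnan(Y).sum())))


def _prepare(data: TwinPanelData, traits):
    variables = [(k, t) for k in traits for t in data.waves]
    Y = data.pair_matrix(variables)
    keep = ~np.isnan(Y).all(axis=1)
    Y = Y[keep]
    zyg = data.df["zygosity"].to_numpy()[keep]
    if set(zyg) != {"MZ", "DZ"}:
        raise ValueError("both zygosity groups required")
    groups = _fiml.pattern_groups(Y, zyg)
    return Y, zyg, groups


def fit_riclpm(
    data: TwinPanelData,
    traits: tuple[str, str] | None = None,
    fixed: dict[int, float] | None = None,
    start: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 5000,
) -> RiclpmFit:
    """Fit the biometric RI-CLPM by two-group FIML.

    ``fixed`` maps packed-parameter indices to fixed values (used for the
    cross-lag likelihood-ratio tests); ``start`` optionally supplies a
    packed warm-start vector. Pairs with a missing entry contribute the
    density of their observed sub-vector. Means are free per variable,
    equal across twins and zygosity groups (inputs are assumed
    sex-residualized). Raises on non-convergence after all starts.
    """
    if traits is None:
        traits = tuple(data.traits[:2])
    if len(traits) != 2 or len(data.waves) != 3:
        raise ValueError("the model requires exactly 2 traits and 3 waves")
    fixed = dict(fixed or {})
    Y, zyg, groups = _prepare(data, traits)
    free = np.array([i for i in range(N_PARAMS_FULL) if i not in fixed])

    def expand(xf):
        x = np.empty(N_PARAMS_FULL)
        x[free] = xf
        for i, v in fixed.items():
            x[i] = v
        return x

    def objective(xf):
        MA, ME, mu6 = _moments_from_x(expand(xf))
        within = MA + ME
        mu = np.tile(mu6, 2)
        sigmas = {}
        for z, r in GENETIC_CORRELATION.items():
            sig = np.empty((12, 12))
            sig[:6, :6] = within
            sig[6:, 6:] = within
            sig[:6, 6:] = r * MA
            sig[6:, :6] = sig[:6, 6:]
            sigmas[z] = sig
        return _fiml.group_m2ll(groups, lambda k: mu, lambda k: sigmas[k])

    if start is None:
        x0 = _moment_start(Y, zyg)
    else:
        x0 = np.asarray(start, dtype=float).copy()
    for i, v in fixed.items():
        x0[i] = v
    rng = np.random.default_rng(seed)
    starts = [x0[free]]
    for _ in range(n_starts - 1):
        starts.append(x0[free] + 0.1 * rng.standard_normal(free.size))
    res = _fiml.minimize_multistart(objective, starts, maxiter=maxiter)
    if res.fun >= 1e11:
        raise RuntimeError(f"RI-CLPM fit failed to find a finite optimum: {res.message}")
    x_hat = expand(res.x)
    params = unpack_params(x_hat, traits)
    return RiclpmFit(
        params=params,
        minus2lnl=float(res.fun),
        n_params=int(free.size),
        n_pairs=int(len(Y)),
        converged=bool(res.success),
        x=x_hat,
        fixed=fixed,
        data_fingerprint=_fingerprint(Y),
        optimizer_message=str(res.message),
    )


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def fit_indices(fit: RiclpmFit, data: TwinPanelData, traits=None):
    """CFI, TLI and RMSEA from model, saturated and baseline chi-squares.

    Saturated: unstructured mean vector and covariance per zygosity group
    (EM over missing patterns). Baseline: independence — free means and
    variances per group, zero covariances. χ²_M = −2lnL_M − (−2lnL_sat);
    RMSEA uses the two-group convention sqrt(G·max(χ²−df,0)/(df·N)) with
    G = 2 groups and N the total number of pairs. Results are cached on
    the fit object. Indices are floored/capped into [0, 1] with the usual
    conventions when the model underperforms the baseline.
    """
    if traits is None:
        traits = fit.params.traits
    Y, zyg, _ = _prepare(data, traits)
    m2ll_sat = 0.0
    m2ll_base = 0.0
    k_sat = k_base = 0
    for z in ("MZ", "DZ"):
        Yz = Y[zyg == z]
        _, _, m2, k = _fiml.saturated_mvn(Yz)
        m2ll_sat += m2
        k_sat += k
        _, _, m2b, kb = _fiml.independence_mvn(Yz)
        m2ll_base += m2b
        k_base += kb
    chi2_m = max(fit.minus2lnl - m2ll_sat, 0.0)
    df_m = k_sat - fit.n_params
    chi2_b = max(m2ll_base - m2ll_sat, 0.0)
    df_b = k_sat - k_base
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 1e-12)
    cfi = 1.0 - num / den
    rb = chi2_b / df_b
    rm = chi2_m / df_m
    tli = (rb - rm) / (rb - 1.0) if rb > 1.0 else 1.0
    tli = min(tli, 1.0)
    n_total = len(Y)
    rmsea = float(np.sqrt(2.0 * max(chi2_m - df_m, 0.0) / (df_m * n_total)))
    fit.chi2_model, fit.df_model = chi2_m, df_m
    fit.cfi, fit.tli, fit.rmsea = float(cfi), float(tli), rmsea
    return float(cfi), float(tli), rmsea


# ---------------------------------------------------------------------------
# cross-lag likelihood-ratio tests
# ---------------------------------------------------------------------------

def cross_lag_label(traits, interval, target, source) -> str:
    return f"{traits[source]}_w{interval + 1}->{traits[target]}_w{interval + 2}"


def test_cross_lags(
    data: TwinPanelData, full_fit: RiclpmFit, n_starts: int = 2, seed: int = 0
) -> list[CrossLagTest]:
    """Likelihood-ratio test of each of the four cross-lagged paths.

    Each path is fixed to zero in turn and the model refit (warm-started
    from the full estimates); the χ² difference on 1 df gives the test. A
    restricted fit that fails is reported as unavailable without blocking
    the others.
    """
    out = []
    traits = full_fit.params.traits
    for (interval, target, source), idx in CROSS_LAG_INDEX.items():
        label = cross_lag_label(traits, interval, target, source)
        try:
            restricted = fit_riclpm(
                data, traits=traits, fixed={**full_fit.fixed, idx: 0.0},
                start=full_fit.x, n_starts=n_starts, seed=seed,
            )
            chi2 = max(restricted.minus2lnl - full_fit.minus2lnl, 0.0)
            out.append(CrossLagTest(
                label=label, interval=interval, target=target, source=source,
                chi2_diff=float(chi2), df=1, p_value=float(sps.chi2.sf(chi2, 1)),
            ))
        except RuntimeError:
            out.append(CrossLagTest(
                label=label, interval=interval, target=target, source=source,
                chi2_diff=np.nan, df=1, p_value=np.nan, available=False,
            ))
    return out


# ---------------------------------------------------------------------------
# derived stability quantities
# ---------------------------------------------------------------------------

def derived_stability(fit: RiclpmFit | RiclpmParams) -> DerivedStability:
    """Random-intercept variance shares, A/E shares of the RI variance,
    RI genetic/environmental correlations, and standardized paths.

    ri_share[k, t] = Var(RI_k) / (Var(RI_k) + Var(w_k(t))) with the
    within-process variance propagated through B; the standardized path
    from source s at wave t to target g at t+1 is
    B[t][g, s]·SD(w_s(t))/SD(w_g(t+1)).
    """
    params = fit.params if isinstance(fit, RiclpmFit) else fit
    var_a = np.diag(params.sigma_a_ri)
    var_e = np.diag(params.sigma_e_ri)
    var_ri = var_a + var_e
    cw_tot, _, _ = within_covariances(params)
    ri_share = np.zeros((2, N_WAVES))
    zero_flags = [False, False]
    for k in range(2):
        if var_ri[k] <= 0:
            zero_flags[k] = True
            continue
        for t in range(N_WAVES):
            ri_share[k, t] = var_ri[k] / (var_ri[k] + cw_tot[t][k, k])
    with np.errstate(divide="ignore", invalid="ignore"):
        a_share = np.where(var_ri > 0, var_a / var_ri, 0.0)
        r_a = params.sigma_a_ri[0, 1] / np.sqrt(var_a[0] * var_a[1])
        r_e = params.sigma_e_ri[0, 1] / np.sqrt(var_e[0] * var_e[1])
    rows = []
    for t in range(2):
        for g in range(2):
            for s in range(2):
                sd_s = np.sqrt(cw_tot[t][s, s])
                sd_g = np.sqrt(cw_tot[t + 1][g, g])
                unstd = params.B[t][g, s]
                rows.append({
                    "interval": t + 1,
                    "source": f"{params.traits[s]}_w{t + 1}",
                    "target": f"{params.traits[g]}_w{t + 2}",
                    "kind": "autoregressive" if g == s else "cross-lagged",
                    "unstandardized": unstd,
                    "standardized": unstd * sd_s / sd_g if sd_g > 0 else np.nan,
                })
    return DerivedStability(
        traits=params.traits,
        ri_share=ri_share,
        a_share_ri=a_share,
        e_share_ri=1.0 - a_share,
        r_a_ri=float(r_a),
        r_e_ri=float(r_e),
        std_paths=pd.DataFrame(rows),
        zero_ri_flag=tuple(zero_flags),
    )
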