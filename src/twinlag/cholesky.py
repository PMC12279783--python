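"""Multivariate Cholesky ACE/AE twin modeling by two-group FIML.

The biometric Cholesky decomposition parameterizes the additive-genetic
(A), shared-environment (C) and non-shared-environment (E) covariance
matrices of m phenotypes through lower-triangular path matrices a, c, e
(A = aaᵀ etc.), which keeps every component positive semidefinite. The
two-group likelihood exploits that MZ co-twins share all additive genetic
influences while DZ co-twins share half on average: the cross-twin
covariance block is A + C for MZ pairs and 0.5·A + C for DZ pairs. Sex
differences in mean level are absorbed by sex-specific means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fiml
from .data import TwinPanelData

__all__ = [
    "CholeskyParams",
    "ModelFit",
    "VarianceComponents",
    "implied_pair_moments",
    "fit_cholesky",
    "compare_models",
    "variance_components",
]


@dataclass
class CholeskyParams:
    """Lower-triangular a/c/e path matrices plus per-sex mean vectors.

    ``means`` has shape (2, m): row 0 holds the male means, row 1 the
    female means (sex coded 0 = male, 1 = female).
    """

    labels: tuple[str, ...]
    a: np.ndarray
    c: np.ndarray
    e: np.ndarray
    means: np.ndarray = None

    def __post_init__(self):
        m = len(self.labels)
        self.a = np.tril(np.asarray(self.a, dtype=float).reshape(m, m))
        self.c = np.tril(np.asarray(self.c, dtype=float).reshape(m, m))
        self.e = np.tril(np.asarray(self.e, dtype=float).reshape(m, m))
        if self.means is None:
            self.means = np.zeros((2, m))
        self.means = np.asarray(self.means, dtype=float).reshape(2, m)

    def validate(self) -> None:
        m = len(self.labels)
        for name, M in (("a", self.a), ("c", self.c), ("e", self.e)):
            if M.shape != (m, m):
                raise ValueError(f"{name}: dimension mismatch with labels")

    @property
    def A(self) -> np.ndarray:
        return self.a @ self.a.T

    @property
    def C(self) -> np.ndarray:
        return self.c @ self.c.T

    @property
    def E(self) -> np.ndarray:
        return self.e @ self.e.T


@dataclass
class ModelFit:
    """Converged likelihood fit with information criteria.

    AIC = −2lnL + 2k; BIC = −2lnL + k·ln(N) with N the number of twin
    pairs (the independent sampling units).
    """

    model: str
    params: CholeskyParams
    minus2lnl: float
    n_params: int
    n_pairs: int
    converged: bool
    data_fingerprint: int = 0
    standard_errors: np.ndarray | None = None
    optimizer_message: str = ""

    @property
    def aic(self) -> float:
        return self.minus2lnl + 2 * self.n_params

    @property
    def bic(self) -> float:
        return self.minus2lnl + self.n_params * np.log(self.n_pairs)


@dataclass
class VarianceComponents:
    """Standardized variance shares and component correlation matrices."""

    labels: tuple[str, ...]
    a2: np.ndarray
    c2: np.ndarray
    e2: np.ndarray
    rA: np.ndarray
    rC: np.ndarray
    rE: np.ndarray
    shared_pct_a: np.ndarray | None = None   # bivariate fits only
    shared_pct_e: np.ndarray | None = None


def implied_pair_moments(
    params: CholeskyParams, zygosity: str, sex_pair: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean (2m,) and covariance (2m, 2m) for one pair type."""
    from .simulate import GENETIC_CORRELATION  # local to avoid import cycle

    r = GENETIC_CORRELATION[zygosity]
    A, C, E = params.A, params.C, params.E
    within = A + C + E
    cross = r * A + C
    sigma = np.block([[within, cross], [cross, within]])
    mu = np.concatenate([params.means[sex_pair[0]], params.means[sex_pair[1]]])
    return mu, sigma


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _tril_indices(m):
    return np.tril_indices(m)


def _fingerprint(Y: np.ndarray) -> int:
    return hash((Y.shape, np.nansum(Y).round(8), int(np.isnan(Y).sum())))


def _prepare(data: TwinPanelData, variables):
    Y = data.pair_matrix(variables)
    zyg = data.df["zygosity"].to_numpy()
    sex = np.column_stack([
        data.df["sex_t1"].to_numpy(dtype=float),
        data.df["sex_t2"].to_numpy(dtype=float),
    ])
    # a fully-missing twin's sex never enters the mean vector; neutralize NaN
    m = len(variables)
    for j in (0, 1):
        sl = slice(j * m, (j + 1) * m)
        twin_all_missing = np.isnan(Y[:, sl]).all(axis=1)
        sex[twin_all_missing & np.isnan(sex[:, j]), j] = 0
    if np.isnan(sex).any():
        raise ValueError("sex missing for a twin with observed phenotypes")
    keys = np.empty(len(Y), dtype=object)
    keys[:] = [(z, int(s1), int(s2)) for z, (s1, s2) in zip(zyg, sex)]
    groups = _fiml.pattern_groups(Y, keys)
    return Y, groups


def _pooled_within_cov(Y: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    stacked = np.vstack([Y[:, :m], Y[:, m:]])
    mu = np.nanmean(stacked, axis=0)
    S = np.ma.cov(np.ma.masked_invalid(stacked), rowvar=False).filled(0.0)
    S = np.atleast_2d(S)
    w, V = np.linalg.eigh((S + S.T) / 2)
    S = V @ np.diag(np.clip(w, 1e-6, None)) @ V.T
    return mu, S


def fit_cholesky(
    data: TwinPanelData,
    variables: list[tuple[str, int]],
    model: str = "ACE",
    sex_means: bool = True,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 3000,
) -> ModelFit:
    """Fit an m-variate Cholesky ACE or AE model by two-group FIML.

    Pairs with missing entries contribute through the multivariate-normal
    density of their observed sub-vector. The AE model constrains c = 0.
    Both zygosity groups must be present (A and C are not separable from
    a single group).
    """
    model = model.upper()
    if model not in ("ACE", "AE"):
        raise ValueError(f"unknown model {model!r}")
    m = len(variables)
    if m > 6:
        raise ValueError("at most 6 variables supported")
    zyg = set(data.df["zygosity"])
    if zyg != {"MZ", "DZ"}:
        raise ValueError("both zygosity groups required to separate A from C")
    labels = tuple(f"{k}_{t}" for k, t in variables)
    Y, groups = _prepare(data, variables)
    tri = _tril_indices(m)
    n_tri = m * (m + 1) // 2
    with_c = model == "ACE"
    n_mean = 2 * m if sex_means else m

    def unpack(x) -> CholeskyParams:
        a = np.zeros((m, m))
        c = np.zeros((m, m))
        e = np.zeros((m, m))
        a[tri] = x[:n_tri]
        pos = n_tri
        if with_c:
            c[tri] = x[pos:pos + n_tri]
            pos += n_tri
        e[tri] = x[pos:pos + n_tri]
        pos += n_tri
        if sex_means:
            means = x[pos:pos + 2 * m].reshape(2, m)
        else:
            means = np.tile(x[pos:pos + m], (2, 1))
        return CholeskyParams(labels, a, c, e, means)

    def objective(x) -> float:
        p = unpack(x)
        within = p.A + p.C + p.E

        def sigma_of(key):
            from .simulate import GENETIC_CORRELATION

            r = GENETIC_CORRELATION[key[0]]
            cross = r * p.A + p.C
            return np.block([[within, cross], [cross, within]])

        def mu_of(key):
            return np.concatenate([p.means[key[1]], p.means[key[2]]])

        return _fiml.group_m2ll(groups, mu_of, sigma_of)

    # moment-based start: split the pooled within-twin covariance
    mu0, S0 = _pooled_within_cov(Y, m)
    shares = (0.45, 0.10, 0.45) if with_c else (0.5, 0.0, 0.5)
    parts = []
    for s, used in zip(shares, (True, with_c, True)):
        if used:
            parts.append(np.linalg.cholesky(s * S0 + 1e-8 * np.eye(m))[tri])
    mean0 = np.tile(mu0, 2) if sex_means else mu0
    x0 = np.concatenate(parts + [mean0])
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 * (1 + 0.2 * rng.standard_normal(x0.size)) +
                     0.05 * rng.standard_normal(x0.size) for _ in range(n_starts - 1)]
    res = _fiml.minimize_multistart(objective, starts, maxiter=maxiter)
    if not res.success and res.fun >= 1e11:
        raise RuntimeError(f"Cholesky {model} fit failed: {res.message}")
    params = unpack(res.x)
    n_params = (2 + with_c) * n_tri + n_mean
    return ModelFit(
        model=model,
        params=params,
        minus2lnl=float(res.fun),
        n_params=n_params,
        n_pairs=data.n_pairs,
        converged=bool(res.success),
        data_fingerprint=_fingerprint(Y),
        optimizer_message=str(res.message),
    )


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Side-by-side −2lnL / AIC / BIC table with deltas vs the best fit."""
    if len({f.data_fingerprint for f in fits}) > 1:
        raise ValueError("fits were computed on different data")
    rows = []
    for f in fits:
        rows.append({
            "model": f.model,
            "minus2lnl": f.minus2lnl,
            "n_params": f.n_params,
            "AIC": f.aic,
            "BIC": f.bic,
        })
    tab = pd.DataFrame(rows)
    tab["dAIC"] = tab["AIC"] - tab["AIC"].min()
    tab["dBIC"] = tab["BIC"] - tab["BIC"].min()
    tab["preferred_AIC"] = tab["dAIC"] == 0
    tab["preferred_BIC"] = tab["dBIC"] == 0
    return tab


def _component_correlation(M: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(M), 1e-300, None))
    R = M / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def variance_components(fit: ModelFit, convention: str = "rA2") -> VarianceComponents:
    """Standardized variance shares and A/C/E correlations.

    For bivariate fits the percentage of a trait's genetic variance shared
    with the other trait is 100·rA² under the (symmetric, default)
    ``"rA2"`` convention, or 100·a₂₁²/(a₂₁² + a₂₂²) for the second-ordered
    trait under the order-dependent ``"path"`` convention; analogously for
    E. Requires a converged fit and nonzero total variance per variable.
    """
    p = fit.params
    A, C, E = p.A, p.C, p.E
    total = np.diag(A + C + E)
    if np.any(total <= 0):
        raise ValueError("zero total variance for at least one variable")
    a2, c2, e2 = np.diag(A) / total, np.diag(C) / total, np.diag(E) / total
    rA, rC, rE = (_component_correlation(M) for M in (A, C, E))
    shared_a = shared_e = None
    if len(p.labels) == 2:
        if convention == "rA2":
            shared_a = np.array([100 * rA[0, 1] ** 2] * 2)
            shared_e = np.array([100 * rE[0, 1] ** 2] * 2)
        elif convention == "path":
            den_a = p.a[1, 0] ** 2 + p.a[1, 1] ** 2
            den_e = p.e[1, 0] ** 2 + p.e[1, 1] ** 2
            shared_a = np.array([100 * rA[0, 1] ** 2, 100 * p.a[1, 0] ** 2 / den_a])
            shared_e = np.array([100 * rE[0, 1] ** 2, 100 * p.e[1, 0] ** 2 / den_e])
        else:
            raise ValueError(f"unknown convention {convention!r}")
    if not fit.converged:
        warnings.warn("variance components from a non-converged fit", stacklevel=2)
    return VarianceComponents(p.labels, a2, c2, e2, rA, rC, rE, shared_a, shared_e)
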