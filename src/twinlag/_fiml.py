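"""Full-information maximum-likelihood machinery for pair-level data.

Under multivariate normality the log-likelihood of raw data with missing
entries depends on the data only through per-group sufficient statistics,
where a group collects rows sharing (a) the same model mean/covariance
(e.g. zygosity and sex pair) and (b) the same missing pattern. Grouping
once up front makes every objective evaluation O(#patterns · d³),
independent of sample size; this is an exact reformulation of the
per-row density sum.

Also provides the saturated (unstructured mean + covariance, fitted by
EM over missing patterns) and independence baseline models needed for
chi-square-based fit indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

_LOG_2PI = np.log(2.0 * np.pi)
_BIG = 1e12


@dataclass
class PatternGroup:
    """Sufficient statistics for rows sharing a key and missing pattern."""

    key: object
    obs: np.ndarray      # observed column indices (may be empty)
    n: int
    mean: np.ndarray     # sample mean of observed columns
    scatter: np.ndarray  # MLE covariance (/n) of observed columns


def pattern_groups(Y: np.ndarray, keys=None) -> list[PatternGroup]:
    """Group rows of ``Y`` (NaN = missing) by (key, missing pattern)."""
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    if keys is None:
        keys = np.zeros(n, dtype=int)
    keys = np.asarray(keys)
    mask = ~np.isnan(Y)
    # encode each row's (key, pattern) as a hashable token
    pat_codes = mask @ (1 << np.arange(d, dtype=np.int64))
    out: list[PatternGroup] = []
    key_codes = pd_factorize(keys)
    combo = key_codes.astype(np.int64) * (1 << d) + pat_codes
    order = np.argsort(combo, kind="stable")
    combo_sorted = combo[order]
    boundaries = np.flatnonzero(np.diff(combo_sorted)) + 1
    for rows in np.split(order, boundaries):
        i0 = rows[0]
        obs = np.flatnonzero(mask[i0])
        block = Y[np.ix_(rows, obs)]
        m = block.mean(axis=0) if obs.size else np.empty(0)
        if obs.size:
            dev = block - m
            S = dev.T @ dev / len(rows)
        else:
            S = np.empty((0, 0))
        out.append(PatternGroup(key=keys[i0], obs=obs, n=len(rows), mean=m, scatter=S))
    return out


def pd_factorize(keys: np.ndarray) -> np.ndarray:
    """Integer codes for an array of hashable keys (stable order)."""
    seen: dict = {}
    codes = np.empty(len(keys), dtype=np.int64)
    for i, k in enumerate(keys):
        kk = k if not isinstance(k, np.ndarray) else tuple(k)
        codes[i] = seen.setdefault(kk, len(seen))
    return codes


def group_m2ll(groups: list[PatternGroup], mu_of_key, sigma_of_key) -> float:
    """−2 log-likelihood given per-key model mean vector and covariance.

    ``mu_of_key(key) -> (d,)`` and ``sigma_of_key(key) -> (d, d)`` supply
    the full-dimension model moments; each group uses its observed
    sub-vector. Returns a large finite penalty for non-PD sub-covariances
    so optimizers can recover.
    """
    total = 0.0
    cache: dict = {}
    for g in groups:
        if g.obs.size == 0:
            continue
        kk = g.key if not isinstance(g.key, np.ndarray) else tuple(g.key)
        if kk not in cache:
            cache[kk] = (np.asarray(mu_of_key(g.key), dtype=float),
                         np.asarray(sigma_of_key(g.key), dtype=float))
        mu, sigma = cache[kk]
        sub = sigma[np.ix_(g.obs, g.obs)]
        try:
            c, low = linalg.cho_factor(sub, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return _BIG
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        delta = g.mean - mu[g.obs]
        sol_d = linalg.cho_solve((c, low), delta, check_finite=False)
        sol_S = linalg.cho_solve((c, low), g.scatter, check_finite=False)
        quad = float(delta @ sol_d) + float(np.trace(sol_S))
        total += g.n * (g.obs.size * _LOG_2PI + logdet + quad)
        if not np.isfinite(total):
            return _BIG
    return total


# ---------------------------------------------------------------------------
# Saturated and independence models (for fit indices)
# ---------------------------------------------------------------------------

def _initial_moments(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete start values, eigenvalue-clipped to PD."""
    mu = np.nanmean(Y, axis=0)
    d = Y.shape[1]
    masked = np.ma.masked_invalid(Y)
    S = np.ma.cov(masked, rowvar=False, allow_masked=True).filled(0.0)
    S = np.atleast_2d(S)
    w, V = np.linalg.eigh((S + S.T) / 2)
    floor = max(1e-6, 1e-6 * w.max()) if w.size else 1e-6
    S = V @ np.diag(np.clip(w, floor, None)) @ V.T
    return np.nan_to_num(mu), S


def saturated_mvn(Y: np.ndarray, max_iter: int = 500, tol: float = 1e-9):
    """Unstructured MVN MLE with missing data via EM.

    Returns ``(mu, sigma, minus2lnl, n_params)``. Complete data converges
    in a single sweep (the E-step is then the identity).
    """
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    groups = pattern_groups(Y)
    mu, sigma = _initial_moments(Y)
    prev = np.inf
    for _ in range(max_iter):
        T1 = np.zeros(d)
        T2 = np.zeros((d, d))
        for g in groups:
            obs = g.obs
            mis = np.setdiff1d(np.arange(d), obs, assume_unique=True)
            if obs.size == 0:
                # no information; conditional expectations are the marginals
                T1 += g.n * mu
                T2 += g.n * (sigma + np.outer(mu, mu))
                continue
            sum_o = g.n * g.mean
            ss_oo = g.n * (g.scatter + np.outer(g.mean, g.mean))
            T1[obs] += sum_o
            T2[np.ix_(obs, obs)] += ss_oo
            if mis.size:
                s_oo = sigma[np.ix_(obs, obs)]
                s_mo = sigma[np.ix_(mis, obs)]
                s_mm = sigma[np.ix_(mis, mis)]
                B = np.linalg.solve(s_oo, s_mo.T).T        # (mis, obs)
                a = mu[mis] - B @ mu[obs]
                C = s_mm - B @ s_mo.T
                sum_m = g.n * a + B @ sum_o
                ss_om = sum_o[:, None] * a[None, :] + ss_oo @ B.T
                ss_mm = (g.n * (C + np.outer(a, a))
                         + np.outer(a, B @ sum_o) + np.outer(B @ sum_o, a)
                         + B @ ss_oo @ B.T)
                T1[mis] += sum_m
                T2[np.ix_(obs, mis)] += ss_om
                T2[np.ix_(mis, obs)] += ss_om.T
                T2[np.ix_(mis, mis)] += ss_mm
        mu = T1 / n
        sigma = T2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        m2ll = group_m2ll(groups, lambda k: mu, lambda k: sigma)
        if abs(prev - m2ll) < tol * (1 + abs(m2ll)):
            prev = m2ll
            break
        prev = m2ll
    n_params = d + d * (d + 1) // 2
    return mu, sigma, prev, n_params


def independence_mvn(Y: np.ndarray):
    """Independence (diagonal-covariance) MLE: free means and variances.

    The likelihood factorizes over variables, so the MLE per variable is
    the observed-data mean and MLE variance. Returns
    ``(mu, sigma, minus2lnl, n_params)``.
    """
    Y = np.asarray(Y, dtype=float)
    d = Y.shape[1]
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)  # MLE (ddof=0)
    sigma = np.diag(np.clip(var, 1e-12, None))
    groups = pattern_groups(Y)
    m2ll = group_m2ll(groups, lambda k: mu, lambda k: sigma)
    return mu, sigma, m2ll, 2 * d


# ---------------------------------------------------------------------------
# Optimization helper
# ---------------------------------------------------------------------------

def minimize_multistart(objective, starts, bounds=None, maxiter=2000,
                        ftol=1e-11, gtol=1e-7):
    """L-BFGS-B from several start vectors; return the best OptimizeResult.

    Tolerances are deliberately tight: likelihood-ratio statistics
    downstream compare −2lnL values of nested fits, so each optimum must
    be resolved well below the χ² resolution of interest.
    """
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, np.asarray(x0, dtype=float), method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                     "ftol": ftol, "gtol": gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best
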