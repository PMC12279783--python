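"""Synthetic twin-pair panel generators.

Generates pair-level panels with the statistical structure the package's
models assume: additive-genetic (A) components correlate 1.0 across
monozygotic (MZ) co-twins and 0.5 across dizygotic (DZ) co-twins, while
non-shared-environment (E) components are independent between co-twins.
Three generators cover the analysis chain: a biometric random-intercept
cross-lagged panel (RI-CLPM) process at the factor level, a one-factor
measurement layer emitting scale indicators, and a Cholesky ACE process
for (composite) phenotypes. A missingness stage emulates wave attrition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cholesky import CholeskyParams
from .data import TwinPanelData, column_name

__all__ = [
    "RiclpmParams",
    "MeasurementParams",
    "MissingnessSpec",
    "simulate_riclpm_panel",
    "emit_indicators",
    "simulate_cholesky_panel",
    "apply_missingness",
]

#: cross-twin correlation of additive-genetic components, by zygosity
GENETIC_CORRELATION = {"MZ": 1.0, "DZ": 0.5}


def _check_psd(name: str, M: np.ndarray, dim: int) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (dim, dim):
        raise ValueError(f"{name}: expected {dim}x{dim}, got {M.shape}")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name}: not symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError(f"{name}: not positive semidefinite (min eig {w.min():.3g})")
    return M


@dataclass
class RiclpmParams:
    """Full parameter set of the biometric (AE) RI-CLPM for two traits.

    Trait index order is fixed by ``traits`` (default personality,
    psychopathology). Each twin's observed score is

        y[k, t] = mu[k, t] + sex_effect[k] * sex + RI[k] + w[k, t]

    where the random intercept RI and the within-person process w each
    decompose into an A part (cross-twin correlation 1 for MZ, 0.5 for DZ)
    and an E part (independent between co-twins). The within-person
    process follows w[t+1] = B[t] @ w[t] + u[t+1] with per-interval 2x2
    dynamics ``B[t]`` (rows = target trait, columns = source trait; the
    diagonal is autoregressive, the off-diagonal cross-lagged), shared by
    the A and E streams.
    """

    sigma_a_ri: np.ndarray                      # 2x2 A covariance of the RIs
    sigma_e_ri: np.ndarray                      # 2x2 E covariance of the RIs
    B: np.ndarray                               # (2, 2, 2): B[t], t -> t+1
    sigma_a_w1: np.ndarray                      # 2x2 A covariance, wave-1 within
    sigma_e_w1: np.ndarray
    sigma_a_u: np.ndarray                       # (2, 2, 2) A innovations, waves 2..3
    sigma_e_u: np.ndarray
    mu: np.ndarray = None                       # (2, 3) means [trait, wave]
    sex_effect: np.ndarray = None               # (2,) mean shift for sex = 1
    traits: tuple[str, str] = ("personality", "psychopathology")

    def __post_init__(self):
        if self.mu is None:
            self.mu = np.zeros((2, 3))
        if self.sex_effect is None:
            self.sex_effect = np.zeros(2)
        self.mu = np.asarray(self.mu, dtype=float).reshape(2, 3)
        self.sex_effect = np.asarray(self.sex_effect, dtype=float).reshape(2)
        self.B = np.asarray(self.B, dtype=float).reshape(2, 2, 2)
        self.sigma_a_u = np.asarray(self.sigma_a_u, dtype=float).reshape(2, 2, 2)
        self.sigma_e_u = np.asarray(self.sigma_e_u, dtype=float).reshape(2, 2, 2)
        self.validate()

    def validate(self) -> None:
        self.sigma_a_ri = _check_psd("sigma_a_ri", self.sigma_a_ri, 2)
        self.sigma_e_ri = _check_psd("sigma_e_ri", self.sigma_e_ri, 2)
        self.sigma_a_w1 = _check_psd("sigma_a_w1", self.sigma_a_w1, 2)
        self.sigma_e_w1 = _check_psd("sigma_e_w1", self.sigma_e_w1, 2)
        for t in range(2):
            _check_psd(f"sigma_a_u[{t}]", self.sigma_a_u[t], 2)
            _check_psd(f"sigma_e_u[{t}]", self.sigma_e_u[t], 2)

    def copy_with(self, **kwargs) -> "RiclpmParams":
        return replace(self, **kwargs)


@dataclass
class MeasurementParams:
    """One-factor measurement layer for a single general factor.

    ``loadings`` map each indicator to its (wave-invariant) factor
    loading; ``uniqueness`` maps to the unique-error variance, either a
    scalar (equal across waves) or a length-3 sequence.
    """

    trait: str
    loadings: dict[str, float]
    uniqueness: dict[str, float | tuple[float, float, float]]

    def uniqueness_at(self, indicator: str, wave_index: int) -> float:
        psi = self.uniqueness[indicator]
        psi = np.broadcast_to(np.asarray(psi, dtype=float), (3,))
        val = float(psi[wave_index])
        if val < 0:
            raise ValueError(f"uniqueness for {indicator!r} negative")
        return val


@dataclass
class MissingnessSpec:
    """Wave-level dropout plus cell-level MCAR masking probabilities."""

    wave_dropout_prob: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cell_mcar_prob: float = 0.0

    def __post_init__(self):
        probs = tuple(self.wave_dropout_prob) + (self.cell_mcar_prob,)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("missingness probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# paired normal draws
# ---------------------------------------------------------------------------

def _chol_psd(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((M + M.T) / 2)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _pair_normal(rng: np.random.Generator, cov: np.ndarray, n: int, r: float):
    """Draw n co-twin pairs of d-vectors, each marginally N(0, cov),
    with cross-twin covariance r·cov. Returns (z1, z2), each (n, d)."""
    d = cov.shape[0]
    L = _chol_psd(cov)
    gc = rng.standard_normal((n, d))
    g1 = rng.standard_normal((n, d))
    g2 = rng.standard_normal((n, d))
    a, b = np.sqrt(r), np.sqrt(max(0.0, 1.0 - r))
    return (a * gc + b * g1) @ L.T, (a * gc + b * g2) @ L.T


def _draw_sexes(rng: np.random.Generator, n: int, zygosity: str):
    """MZ pairs are same-sex; DZ pairs include same- and opposite-sex."""
    if zygosity == "MZ":
        s = rng.integers(0, 2, size=n)
        return s, s.copy()
    return rng.integers(0, 2, size=n), rng.integers(0, 2, size=n)


def _assemble_frame(blocks: dict[str, np.ndarray], zygosity_labels, sexes, start_id=0):
    df = pd.DataFrame(blocks)
    n = len(df)
    df.insert(0, "sex_t2", sexes[1])
    df.insert(0, "sex_t1", sexes[0])
    df.insert(0, "zygosity", zygosity_labels)
    df.insert(0, "pair_id", [f"p{start_id + i:06d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# RI-CLPM panel generator
# ---------------------------------------------------------------------------

def simulate_riclpm_panel(
    params: RiclpmParams, n_mz: int, n_dz: int, seed: int
) -> TwinPanelData:
    """Simulate a two-trait, three-wave twin panel from the biometric RI-CLPM.

    A components (random-intercept and within-process streams alike) are
    drawn with cross-twin correlation 1 (MZ) or 0.5 (DZ); E components are
    independent across co-twins. The within dynamics are propagated as
    w[t+1] = B[t] @ w[t] + u[t+1] separately for the A and E streams
    (which share B). Reproducible under a fixed seed.
    """
    params.validate()
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be nonnegative")
    rng = np.random.default_rng(seed)
    frames = []
    start = 0
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        if n == 0:
            continue
        r = GENETIC_CORRELATION[zyg]
        ri_a = _pair_normal(rng, params.sigma_a_ri, n, r)
        ri_e = _pair_normal(rng, params.sigma_e_ri, n, 0.0)
        wa = list(_pair_normal(rng, params.sigma_a_w1, n, r))
        we = list(_pair_normal(rng, params.sigma_e_w1, n, 0.0))
        w = [[wa[j] + we[j] for j in range(2)]]
        for t in range(2):
            ua = _pair_normal(rng, params.sigma_a_u[t], n, r)
            ue = _pair_normal(rng, params.sigma_e_u[t], n, 0.0)
            wa = [wa[j] @ params.B[t].T + ua[j] for j in range(2)]
            we = [we[j] @ params.B[t].T + ue[j] for j in range(2)]
            w.append([wa[j] + we[j] for j in range(2)])
        sexes = _draw_sexes(rng, n, zyg)
        blocks = {}
        for j in (0, 1):
            ri = ri_a[j] + ri_e[j]
            for k, trait in enumerate(params.traits):
                for t in range(3):
                    y = (params.mu[k, t]
                         + params.sex_effect[k] * sexes[j]
                         + ri[:, k] + w[t][j][:, k])
                    blocks[column_name(trait, t + 1, j + 1)] = y
        frames.append(_assemble_frame(blocks, [zyg] * n, sexes, start))
        start += n
    if not frames:
        raise ValueError("no pairs requested")
    df = pd.concat(frames, ignore_index=True)
    return TwinPanelData(df, params.traits, (1, 2, 3))


# ---------------------------------------------------------------------------
# measurement layer
# ---------------------------------------------------------------------------

def emit_indicators(
    factor_panel: TwinPanelData, mps: list[MeasurementParams] | MeasurementParams, seed: int
) -> TwinPanelData:
    """Emit scale indicators from true factor scores.

    indicator = λ·factor + unique error with variance ψ, independently per
    individual, wave and indicator. Unknown factor labels raise.
    """
    if isinstance(mps, MeasurementParams):
        mps = [mps]
    for mp in mps:
        if mp.trait not in factor_panel.traits:
            raise ValueError(f"unknown factor {mp.trait!r} in measurement params")
    rng = np.random.default_rng(seed)
    df = factor_panel.df[["pair_id", "zygosity", "sex_t1", "sex_t2"]].copy()
    indicators: list[str] = []
    for mp in mps:
        for ind, lam in mp.loadings.items():
            indicators.append(ind)
            for ti, t in enumerate(factor_panel.waves):
                psi = mp.uniqueness_at(ind, ti)
                for j in (1, 2):
                    f = factor_panel.df[column_name(mp.trait, t, j)].to_numpy(dtype=float)
                    noise = rng.standard_normal(len(f)) * np.sqrt(psi)
                    df[column_name(ind, t, j)] = lam * f + noise
    return TwinPanelData(df, tuple(indicators), factor_panel.waves)


# ---------------------------------------------------------------------------
# Cholesky ACE panel generator
# ---------------------------------------------------------------------------

def simulate_cholesky_panel(
    params: CholeskyParams, n_mz: int, n_dz: int, seed: int
) -> TwinPanelData:
    """Simulate single-occasion multivariate twin phenotypes under ACE.

    Within-twin covariance aaᵀ + ccᵀ + eeᵀ; cross-twin covariance
    aaᵀ + ccᵀ (MZ) or 0.5·aaᵀ + ccᵀ (DZ); sex-specific means applied.
    The resulting panel has one wave and ``params.labels`` as traits.
    """
    params.validate()
    m = len(params.labels)
    A, C, E = params.a @ params.a.T, params.c @ params.c.T, params.e @ params.e.T
    rng = np.random.default_rng(seed)
    frames = []
    start = 0
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        if n == 0:
            continue
        r = GENETIC_CORRELATION[zyg]
        xa = _pair_normal(rng, A, n, r)
        xc = _pair_normal(rng, C, n, 1.0)   # shared environment: identical draw
        xe = _pair_normal(rng, E, n, 0.0)
        sexes = _draw_sexes(rng, n, zyg)
        blocks = {}
        for j in (0, 1):
            mean = params.means[sexes[j]]            # (n, m)
            y = mean + xa[j] + xc[j] + xe[j]
            for v in range(m):
                blocks[column_name(params.labels[v], 1, j + 1)] = y[:, v]
        frames.append(_assemble_frame(blocks, [zyg] * n, sexes, start))
        start += n
    if not frames:
        raise ValueError("no pairs requested")
    df = pd.concat(frames, ignore_index=True)
    return TwinPanelData(df, tuple(params.labels), (1,))


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

def apply_missingness(
    data: TwinPanelData, spec: MissingnessSpec, seed: int
) -> TwinPanelData:
    """Mask cells per the missingness specification; the pre-mask values
    are kept on the result as ``complete_values`` for later truth
    comparison."""
    rng = np.random.default_rng(seed)
    df = data.df.copy()
    n = data.n_pairs
    probs = np.broadcast_to(np.asarray(spec.wave_dropout_prob, float), (len(data.waves),))
    for j in (1, 2):
        for ti, t in enumerate(data.waves):
            drop = rng.random(n) < probs[ti]
            for k in data.traits:
                col = column_name(k, t, j)
                vals = df[col].to_numpy(dtype=float).copy()
                vals[drop] = np.nan
                if spec.cell_mcar_prob > 0:
                    vals[rng.random(n) < spec.cell_mcar_prob] = np.nan
                df[col] = vals
    out = TwinPanelData(df, data.traits, data.waves)
    out.complete_values = data.df.copy()
    return out
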