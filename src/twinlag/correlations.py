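"""Descriptive correlation layer: phenotypic stability/cross-trait
correlations over pooled individuals and double-entry cross-twin
correlation matrices by zygosity.

Cross-twin correlations use the double-entry estimator: every pair
contributes twice, once in each twin order, which makes the estimate
exactly invariant to the arbitrary within-pair ordering. Under an AE
generator the expected cross-twin within-trait correlation is a² for MZ
pairs and a²/2 for DZ pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TwinPanelData, ZYGOSITIES, column_name

__all__ = ["CorrelationReport", "phenotypic_correlations", "cross_twin_correlations"]


@dataclass
class CorrelationReport:
    variables: list[str]
    phenotypic: pd.DataFrame | None = None
    phenotypic_n: pd.DataFrame | None = None
    cross_twin: dict[str, pd.DataFrame] = field(default_factory=dict)
    cross_twin_n: dict[str, pd.DataFrame] = field(default_factory=dict)


def _variable_list(data: TwinPanelData, variables):
    if variables is None:
        variables = [(k, t) for k in data.traits for t in data.waves]
    return variables, [f"{k}_{t}" for k, t in variables]


def phenotypic_correlations(
    data: TwinPanelData, variables: list[tuple[str, int]] | None = None,
    min_periods: int = 3,
) -> CorrelationReport:
    """Pairwise-complete Pearson correlations over pooled individual twins.

    Cells with fewer than ``min_periods`` complete observations are left
    missing; the effective n per cell is reported alongside.
    """
    variables, names = _variable_list(data, variables)
    frame = data.individual_frame(variables)[[f"{k}_{t}" for k, t in variables]]
    frame.columns = names
    corr = frame.corr(min_periods=min_periods)
    notna = frame.notna().astype(int)
    counts = pd.DataFrame(notna.T @ notna, index=names, columns=names)
    return CorrelationReport(variables=names, phenotypic=corr, phenotypic_n=counts)


def cross_twin_correlations(
    data: TwinPanelData, zygosity: str,
    variables: list[tuple[str, int]] | None = None,
    min_periods: int = 3,
) -> CorrelationReport:
    """Double-entry cross-twin correlation matrix for one zygosity group.

    Entry (i, j) correlates variable i in one twin with variable j in the
    co-twin, each pair entered in both orders. The matrix is therefore
    symmetric; the diagonal holds the cross-twin within-trait
    correlations that carry the classical twin-design signal.
    """
    if zygosity not in ZYGOSITIES:
        raise ValueError(f"unknown zygosity {zygosity!r}")
    variables, names = _variable_list(data, variables)
    sub = data.df[data.zygosity_mask(zygosity)]
    m = len(variables)
    Y1 = sub[[column_name(k, t, 1) for k, t in variables]].to_numpy(float)
    Y2 = sub[[column_name(k, t, 2) for k, t in variables]].to_numpy(float)
    A = np.vstack([Y1, Y2])
    B = np.vstack([Y2, Y1])
    both = pd.DataFrame(np.hstack([A, B]))
    corr_full = both.corr(min_periods=2 * min_periods)
    cross = corr_full.iloc[:m, m:].to_numpy()
    cross = (cross + cross.T) / 2  # numerically symmetric by construction
    notna_a = pd.DataFrame(A).notna().astype(int).to_numpy()
    notna_b = pd.DataFrame(B).notna().astype(int).to_numpy()
    counts = (notna_a.T @ notna_b) // 2  # pairs, not double-entered rows
    rep = CorrelationReport(variables=names)
    rep.cross_twin[zygosity] = pd.DataFrame(cross, index=names, columns=names)
    rep.cross_twin_n[zygosity] = pd.DataFrame(counts, index=names, columns=names)
    return rep
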