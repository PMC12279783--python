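"""Pair-level longitudinal twin phenotype data and CSV I/O.

The sampling unit throughout the package is the twin *pair*: one row per
pair, wide columns ``<trait>_<wave>_t<1|2>`` for the two co-twins, plus
zygosity (MZ/DZ) and per-twin sex. Missing entries are NaN. Twin order
within a pair is arbitrary; every downstream estimator is required to be
invariant to swapping twin 1 and twin 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZYGOSITIES = ("MZ", "DZ")
WAVES = (1, 2, 3)

#: sex coding used everywhere: 0 = male, 1 = female
SEX_CODES = {"male": 0, "female": 1}


@dataclass(frozen=True)
class TraitSpec:
    """Measurement blueprint for one general factor.

    Parameters
    ----------
    name
        Factor label, e.g. ``"psychopathology"``.
    indicators
        Ordered scale labels loading on the factor.
    reverse_keyed
        Indicators expected to load negatively (e.g. neuroticism on a
        positively oriented general personality factor).
    anchor
        Indicator whose loading fixes the factor's sign (forced positive).
    """

    name: str
    indicators: tuple[str, ...]
    reverse_keyed: tuple[str, ...] = ()
    anchor: str | None = None

    def __post_init__(self):
        if not self.indicators:
            raise ValueError(f"trait {self.name!r}: empty indicator list")
        if len(set(self.indicators)) != len(self.indicators):
            raise ValueError(f"trait {self.name!r}: duplicate indicators")
        unknown = set(self.reverse_keyed) - set(self.indicators)
        if unknown:
            raise ValueError(f"trait {self.name!r}: reverse-keyed {unknown} not in indicators")


def default_trait_specs() -> tuple[TraitSpec, TraitSpec]:
    """The two general factors of the study design.

    Five Big Five traits for the general personality factor (neuroticism
    reverse-keyed, extraversion anchors the sign) and seven symptom scales
    for the general psychopathology factor (depressive symptoms anchor).
    """
    personality = TraitSpec(
        name="personality",
        indicators=(
            "neuroticism",
            "extraversion",
            "openness",
            "agreeableness",
            "conscientiousness",
        ),
        reverse_keyed=("neuroticism",),
        anchor="extraversion",
    )
    psychopathology = TraitSpec(
        name="psychopathology",
        indicators=(
            "depressive",
            "anxiety",
            "somatic",
            "eating",
            "delinquency",
            "conduct",
            "substance",
        ),
        anchor="depressive",
    )
    return personality, psychopathology


def column_name(trait: str, wave: int, twin: int) -> str:
    return f"{trait}_{wave}_t{twin}"


@dataclass
class TwinPanelData:
    """Wide pair-level panel: one row per twin pair.

    ``df`` columns: ``pair_id``, ``zygosity``, ``sex_t1``, ``sex_t2`` and
    one numeric column per (trait, wave, twin). ``traits`` and ``waves``
    define the measurement grid shared by all pairs; a cell is missing iff
    it is NaN.
    """

    df: pd.DataFrame
    traits: tuple[str, ...]
    waves: tuple[int, ...] = WAVES
    #: optional pre-masking values (same shape) kept by apply_missingness
    complete_values: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.traits = tuple(self.traits)
        self.waves = tuple(self.waves)
        self.validate()

    # -- basic structure ---------------------------------------------------
    def validate(self) -> None:
        for col in ("pair_id", "zygosity", "sex_t1", "sex_t2"):
            if col not in self.df.columns:
                raise ValueError(f"missing mandatory column {col!r}")
        bad = ~self.df["zygosity"].isin(ZYGOSITIES)
        if bad.any():
            ids = self.df.loc[bad, "pair_id"].tolist()
            raise ValueError(f"unknown zygosity codes for pairs {ids}")
        for col in self.value_columns():
            if col not in self.df.columns:
                raise ValueError(f"missing phenotype column {col!r}")

    def value_columns(self, twin: int | None = None) -> list[str]:
        twins = (1, 2) if twin is None else (twin,)
        return [
            column_name(k, t, j) for j in twins for k in self.traits for t in self.waves
        ]

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    def zygosity_mask(self, zygosity: str) -> np.ndarray:
        if zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {zygosity!r}")
        return (self.df["zygosity"] == zygosity).to_numpy()

    # -- views -------------------------------------------------------------
    def pair_matrix(self, variables: list[tuple[str, int]]) -> np.ndarray:
        """n_pairs × 2m array: twin-1 values for ``variables`` then twin-2."""
        cols = [column_name(k, t, 1) for k, t in variables] + [
            column_name(k, t, 2) for k, t in variables
        ]
        return self.df[cols].to_numpy(dtype=float)

    def individual_frame(self, variables: list[tuple[str, int]] | None = None) -> pd.DataFrame:
        """Long-by-individual frame (two rows per pair): sex + one column
        per (trait, wave). Used by pooled operations (residualization,
        phenotypic correlations, factor analysis)."""
        if variables is None:
            variables = [(k, t) for k in self.traits for t in self.waves]
        frames = []
        for twin in (1, 2):
            cols = {f"{k}_{t}": self.df[column_name(k, t, twin)].to_numpy() for k, t in variables}
            f = pd.DataFrame(cols)
            f.insert(0, "sex", self.df[f"sex_t{twin}"].to_numpy())
            f.insert(0, "pair_id", self.df["pair_id"].to_numpy())
            f.insert(0, "twin", twin)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def replace_values(self, values: dict[tuple[str, int, int], np.ndarray]) -> "TwinPanelData":
        """Return a copy with the given (trait, wave, twin) columns replaced."""
        df = self.df.copy()
        for (k, t, j), v in values.items():
            df[column_name(k, t, j)] = v
        return TwinPanelData(df, self.traits, self.waves)

    def swap_twins(self) -> "TwinPanelData":
        """Exchange twin-1 and twin-2 slots (order is arbitrary by design)."""
        df = self.df.copy()
        df["sex_t1"], df["sex_t2"] = self.df["sex_t2"], self.df["sex_t1"]
        for k in self.traits:
            for t in self.waves:
                c1, c2 = column_name(k, t, 1), column_name(k, t, 2)
                df[c1], df[c2] = self.df[c2], self.df[c1]
        return TwinPanelData(df, self.traits, self.waves)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _infer_traits_waves(columns: list[str]) -> tuple[list[str], list[int]]:
    traits: list[str] = []
    waves: set[int] = set()
    for col in columns:
        parts = col.rsplit("_", 2)
        if len(parts) != 3 or parts[2] not in ("t1", "t2"):
            continue
        trait, wave = parts[0], parts[1]
        if not wave.isdigit():
            continue
        waves.add(int(wave))
        if trait not in traits:
            traits.append(trait)
    return traits, sorted(waves)


def read_twin_csv(path, schema: list[TraitSpec] | None = None) -> TwinPanelData:
    """Read a wide pair-level CSV into :class:`TwinPanelData`.

    Columns: ``pair_id, zygosity, sex_t1, sex_t2`` then ``<trait>_<wave>_t<1|2>``.
    Unparseable numeric cells become missing with a logged count. If
    ``schema`` is given, the traits are restricted to (and ordered by) the
    union of the schema names/indicators present in the file.
    """
    df = pd.read_csv(path, dtype={"pair_id": str, "zygosity": str})
    for col in ("pair_id", "zygosity", "sex_t1", "sex_t2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    value_cols = [c for c in df.columns if c not in ("pair_id", "zygosity", "sex_t1", "sex_t2")]
    traits, waves = _infer_traits_waves(value_cols)
    if schema is not None:
        wanted = []
        for spec in schema:
            wanted.append(spec.name)
            wanted.extend(spec.indicators)
        traits = [k for k in wanted if k in traits]
        if not traits:
            raise ValueError(f"{path}: no schema trait columns found")
    n_bad = 0
    for k in traits:
        for t in waves:
            for j in (1, 2):
                col = column_name(k, t, j)
                raw = df[col]
                parsed = pd.to_numeric(raw, errors="coerce")
                n_bad += int((parsed.isna() & raw.notna()).sum())
                df[col] = parsed
    if n_bad:
        logger.warning("%s: %d unparseable numeric cells set to missing", path, n_bad)
    for col in ("sex_t1", "sex_t2"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return TwinPanelData(df, tuple(traits), tuple(waves))


def write_twin_csv(data: TwinPanelData, path) -> None:
    """Write :class:`TwinPanelData` as RFC-4180 CSV; missing cells empty."""
    cols = ["pair_id", "zygosity", "sex_t1", "sex_t2"] + data.value_columns()
    out = data.df[cols].copy()
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sex residualization
# ---------------------------------------------------------------------------

def residualize_on_sex(data: TwinPanelData, traits: list[str] | None = None) -> TwinPanelData:
    """Regress out sex from each named trait (all waves), pooling twins.

    Each variable is replaced by OLS residuals from a regression on sex
    (0 = male, 1 = female) over all individual twins with both the value
    and sex observed; residual mean is 0 by construction. Missing cells
    stay missing. Idempotent up to numerical tolerance.
    """
    if traits is None:
        traits = list(data.traits)
    df = data.df.copy()
    sex = {j: df[f"sex_t{j}"].to_numpy(dtype=float) for j in (1, 2)}
    for k in traits:
        if k not in data.traits:
            raise ValueError(f"unknown trait {k!r}")
        for t in data.waves:
            y = np.concatenate([df[column_name(k, t, j)].to_numpy(dtype=float) for j in (1, 2)])
            s = np.concatenate([sex[1], sex[2]])
            ok = ~np.isnan(y)
            if not ok.any():
                raise ValueError(f"variable {k}_{t}: no observed values")
            if np.isnan(s[ok]).any():
                raise ValueError(f"variable {k}_{t}: sex missing for observed twins")
            X = np.column_stack([np.ones(ok.sum()), s[ok]])
            beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
            resid = np.full_like(y, np.nan)
            resid[ok] = y[ok] - X @ beta
            n = data.n_pairs
            df[column_name(k, t, 1)] = resid[:n]
            df[column_name(k, t, 2)] = resid[n:]
    return TwinPanelData(df, data.traits, data.waves)
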