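"""Trait variation summaries across populations.

For each seed trait the summary reports the minimum, maximum, Max/Min
ratio, mean and coefficient of variation (CV, 100 x sample SD / mean,
n-1 denominator), plus a one-way fixed-effects ANOVA with populations as
groups and replicates as observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

#: Table column order for reported summaries.
SUMMARY_COLUMNS = [
    "trait", "minimum", "maximum", "max_min_ratio", "mean", "cv_percent",
    "df_between", "df_within", "f_statistic", "p_value",
]

TRAIT_COLUMNS = [
    "length", "width", "LWR", "TGW", "CSP", "CSS", "CS", "CCF",
    "GDTI", "GCTI", "GSTI",
]


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    minimum: float
    maximum: float
    max_min_ratio: float
    mean: float
    cv_percent: float
    df_between: int
    df_within: int
    f_statistic: float
    p_value: float


def summarize_trait(values) -> tuple[float, float, float, float, float]:
    """(min, max, max/min, mean, CV%) of strictly positive trait values."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("need at least 2 values to summarize a trait")
    if np.any(arr <= 0):
        raise InvalidInputError("trait values must be strictly positive (CV undefined otherwise)")
    mn, mx = float(arr.min()), float(arr.max())
    mean = float(arr.mean())
    cv = 100.0 * float(arr.std(ddof=1)) / mean
    return mn, mx, mx / mn, mean, cv


def one_way_anova(groups) -> tuple[int, int, float, float]:
    """Classical one-way ANOVA: (df_between, df_within, F, p).

    ``groups`` is a sequence of per-population observation vectors; each
    must hold at least two observations.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InvalidInputError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("every group needs at least 2 observations")
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance
        f, p = float("inf"), 0.0
    return df_between, df_within, float(f), float(p)


def summarize_table(traits: pd.DataFrame, trait_columns=None) -> pd.DataFrame:
    """Per-trait summary table mirroring the reporting layout.

    ``traits`` holds one row per (population_id, replicate).  ANOVA groups
    observations by population_id.
    """
    trait_columns = list(trait_columns or [c for c in TRAIT_COLUMNS if c in traits.columns])
    if "population_id" not in traits.columns:
        raise InvalidInputError("traits table must carry a population_id column")
    rows = []
    for trait in trait_columns:
        values = traits[trait].to_numpy(dtype=float)
        mn, mx, ratio, mean, cv = summarize_trait(values)
        groups = [g.to_numpy(dtype=float) for _, g in traits.groupby("population_id")[trait]]
        dfb, dfw, f, p = one_way_anova(groups)
        rows.append(
            TraitSummary(trait, mn, mx, ratio, mean, cv, dfb, dfw, f, p).__dict__
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def format_summary(summary: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Round numeric summary columns for reporting; full precision stays upstream."""
    out = summary.copy()
    for col in ("minimum", "maximum", "max_min_ratio", "mean", "cv_percent", "f_statistic"):
        out[col] = out[col].round(decimals)
    return out
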