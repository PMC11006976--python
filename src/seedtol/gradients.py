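"""Simple linear regressions of traits on geographic gradients.

Each trait (population means by default) is regressed on latitude,
longitude and altitude separately; fits report slope, intercept, R2, the
slope t-test p-value and a significance class at the 0.05/0.01/0.001
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, JoinError

GRADIENTS = ["latitude", "longitude", "altitude"]


def significance_class(p: float, tiers=(0.001, 0.01, 0.05)) -> str:
    for tier in tiers:
        if p < tier:
            return f"p<{tier}"
    return "ns"


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    significance_class: str


def fit_simple_regression(y, x) -> RegressionFit:
    """Ordinary least squares of y on a single gradient x.

    Constant y is a degenerate but legal input (slope 0, R2 0, p 1), so a
    flat synthetic trait does not halt a panel; constant x is an error.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and equal length")
    n = y.size
    if n < 3:
        raise InvalidInputError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise InvalidInputError("gradient x is constant")
    if np.ptp(y) == 0:
        return RegressionFit(0.0, float(y[0]), 0.0, 1.0, n, "ns")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    return RegressionFit(float(res.slope), float(res.intercept), r2, p, n,
                         significance_class(p))


def gradient_panel(
    traits: pd.DataFrame,
    sites: pd.DataFrame,
    trait_columns=None,
    aggregate: bool = True,
) -> pd.DataFrame:
    """One OLS fit per trait x gradient.

    With ``aggregate=True`` traits are averaged to population means before
    joining to sites (one point per population); ``aggregate=False``
    regresses replicate-level values against their population's gradient.
    """
    from .descriptives import TRAIT_COLUMNS

    trait_columns = list(trait_columns or [c for c in TRAIT_COLUMNS if c in traits.columns])
    if aggregate:
        data = traits.groupby("population_id", as_index=False)[trait_columns].mean()
    else:
        data = traits[["population_id", *trait_columns]]
    unmatched = set(data["population_id"]) ^ set(sites["population_id"])
    if unmatched:
        raise JoinError(unmatched, "traits and sites disagree on population ids")
    merged = data.merge(sites[["population_id", *GRADIENTS]], on="population_id")

    rows = []
    for trait in trait_columns:
        for gradient in GRADIENTS:
            fit = fit_simple_regression(merged[trait], merged[gradient])
            rows.append(
                {
                    "trait": trait,
                    "gradient": gradient,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.r_squared,
                    "p": fit.p_value,
                    "n": fit.n,
                    "class": fit.significance_class,
                }
            )
    return pd.DataFrame(rows)
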