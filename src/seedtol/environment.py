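"""Standardized multiple regressions of traits on climate and soil.

Each trait is regressed simultaneously on the six environmental predictors
(MAT, MAP, SOC, AN, AP, pH).  Both the response and the predictors are
z-scored, so coefficients are standardized effect sizes comparable across
predictors and traits; significance classes include the marginal p<0.1
tier used for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InvalidInputError, JoinError
from .gradients import significance_class

PREDICTORS = ["MAT", "MAP", "SOC", "AN", "AP", "pH"]


def standardize(values) -> np.ndarray:
    """z-scores with sample (n-1) SD; errors on constant input."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("need at least 2 values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise InvalidInputError("cannot standardize a constant vector")
    return (arr - arr.mean()) / sd


@dataclass(frozen=True)
class MultiRegressionFit:
    trait: str
    predictors: tuple[str, ...]
    standardized_coefficients: np.ndarray
    coefficient_p_values: np.ndarray
    model_r_squared: float
    significance_classes: tuple[str, ...] = field(default=())


def fit_multiple_regression(
    y, X: pd.DataFrame, trait: str = "y", standardized: bool = True
) -> MultiRegressionFit:
    """OLS of one trait on all predictors at once (no selection).

    ``standardized=True`` (the default) z-scores y and every column of X
    first; ``standardized=False`` fits raw units with an intercept.
    """
    names = tuple(X.columns)
    Xm = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n <= p + 1:
        raise InvalidInputError(f"need more than {p + 1} observations, got {n}")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), Xm]))
    if rank < p + 1:
        # identify columns involved in the dependency for the error message
        dependent = []
        for j in range(p):
            others = np.column_stack([np.ones(n), np.delete(Xm, j, axis=1)])
            resid = Xm[:, j] - others @ np.linalg.lstsq(others, Xm[:, j], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, np.abs(Xm[:, j]).max())):
                dependent.append(names[j])
        raise CollinearityError(dependent or list(names))

    if standardized:
        y_fit = standardize(y)
        X_fit = np.column_stack([standardize(Xm[:, j]) for j in range(p)])
    else:
        y_fit, X_fit = y, Xm
    model = sm.OLS(y_fit, sm.add_constant(X_fit)).fit()
    coefs = model.params[1:]
    pvals = model.pvalues[1:]
    classes = tuple(significance_class(pv, tiers=(0.001, 0.01, 0.05, 0.1)) for pv in pvals)
    return MultiRegressionFit(
        trait=trait,
        predictors=names,
        standardized_coefficients=np.asarray(coefs, dtype=float),
        coefficient_p_values=np.asarray(pvals, dtype=float),
        model_r_squared=float(model.rsquared),
        significance_classes=classes,
    )


def attribution_panel(
    traits: pd.DataFrame,
    sites: pd.DataFrame,
    trait_columns=None,
    predictors=None,
    standardized: bool = True,
) -> pd.DataFrame:
    """Long table (trait, predictor, beta, p, class, model_r2) over all traits.

    Traits are aggregated to population means and joined to the site table
    on population_id.
    """
    from .descriptives import TRAIT_COLUMNS

    predictors = list(predictors or PREDICTORS)
    trait_columns = list(trait_columns or [c for c in TRAIT_COLUMNS if c in traits.columns])
    means = traits.groupby("population_id", as_index=False)[trait_columns].mean()
    unmatched = set(means["population_id"]) ^ set(sites["population_id"])
    if unmatched:
        raise JoinError(unmatched, "traits and sites disagree on population ids")
    merged = means.merge(sites[["population_id", *predictors]], on="population_id")

    rows = []
    for trait in trait_columns:
        fit = fit_multiple_regression(
            merged[trait], merged[predictors], trait=trait, standardized=standardized
        )
        for name, beta, p, cls in zip(
            fit.predictors, fit.standardized_coefficients,
            fit.coefficient_p_values, fit.significance_classes,
        ):
            rows.append(
                {
                    "trait": trait,
                    "predictor": name,
                    "beta": beta,
                    "p": p,
                    "class": cls,
                    "model_r2": fit.model_r_squared,
                }
            )
    return pd.DataFrame(rows)
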