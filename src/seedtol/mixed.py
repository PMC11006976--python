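"""Random-intercept linear mixed models by profile REML.

The model is ``y = X beta + Z b + e`` with one random intercept per
population (``b ~ N(0, sigma2_group)``, ``e ~ N(0, sigma2_resid)``).
Estimation profiles the REML criterion over the single variance ratio
``lambda = sigma2_group / sigma2_resid``: at each lambda the fixed effects
are the GLS solution and the residual variance has a closed form, so the
problem reduces to a bounded one-dimensional optimization over
``log10(lambda)`` plus an explicit check of the ``lambda = 0`` boundary
(the OLS limit).  Boundary fits are reported with zero group variance,
never as an error.

Fixed-effect p-values use t statistics on ``n - p - g + 1`` residual
degrees of freedom (g groups, p fixed-effect columns including the
intercept) — a deliberately simple approximation; Satterthwaite or
Kenward-Roger corrections are out of scope.

``block_effect_decomposition`` splits the fixed-effect (marginal) R2
between two predictor blocks by commonality analysis: each block keeps the
R2 it uniquely contributes plus half of the portion shared with the other
block, and the two shares are normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CollinearityError, InvalidInputError

MORPHOLOGY_BLOCK = ["length", "width", "LWR", "TGW"]
NUTRIENT_BLOCK = ["CSP", "CSS", "CS", "CCF"]


@dataclass(frozen=True)
class LMMFit:
    feature_names: tuple[str, ...]
    fixed_effect_estimates: np.ndarray
    fixed_effect_se: np.ndarray
    fixed_effect_p_values: np.ndarray
    random_intercept_variance: float
    residual_variance: float
    variance_ratio: float
    reml_criterion: float
    boundary_fit: bool
    n_obs: int
    n_groups: int
    #: retained for block decomposition at the fitted variance ratio
    _y: np.ndarray
    _X: np.ndarray
    _group_sizes: np.ndarray
    _group_index: np.ndarray


def _group_structures(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes)
    return codes, sizes


def _gls_pieces(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                sizes: np.ndarray, lam: float):
    """X'V0^-1 X, X'V0^-1 y, y'V0^-1 y and log|V0| for V0 = I + lam*ZZ'.

    Uses the per-group Woodbury form V0^-1 = I - (lam / (1 + lam*n_i)) J.
    """
    shrink = lam / (1.0 + lam * sizes)  # per group
    # group sums of X columns and y
    g = sizes.size
    Xg = np.zeros((g, X.shape[1]))
    yg = np.zeros(g)
    np.add.at(Xg, codes, X)
    np.add.at(yg, codes, y)
    XtX = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    Xty = X.T @ y - Xg.T @ (shrink * yg)
    yty = y @ y - shrink @ (yg**2)
    logdet = float(np.sum(np.log1p(lam * sizes)))
    return XtX, Xty, yty, logdet


def reml_criterion(lam: float, y, X, groups) -> float:
    """-2 x restricted log-likelihood (up to an additive constant).

    Exposed so the profile optimum can be checked against a grid search.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, sizes = _group_structures(groups)
    n, p = X.shape
    XtX, Xty, yty, logdet = _gls_pieces(y, X, codes, sizes, lam)
    beta = np.linalg.solve(XtX, Xty)
    rss = yty - beta @ Xty
    sigma2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(XtX)
    if sign <= 0:
        return np.inf
    return logdet + logdet_xtx + (n - p) * np.log(sigma2)


def fit_random_intercept_lmm(
    y, X: pd.DataFrame, groups, add_intercept: bool = True,
    log10_bounds: tuple[float, float] = (-8.0, 8.0),
) -> LMMFit:
    """REML fit of a random-intercept model via 1-D profile optimization."""
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(
        f"x{j}" for j in range(np.asarray(X).shape[1])
    )
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, sizes = _group_structures(groups)
    g = sizes.size
    if g < 2:
        raise InvalidInputError("need at least 2 groups")
    if sizes.max() < 2:
        raise InvalidInputError("need at least one group with >= 2 observations")
    if add_intercept:
        Xm = np.column_stack([np.ones(len(y)), Xm])
        names = ("(intercept)", *names)
    n, p = Xm.shape
    if np.linalg.matrix_rank(Xm) < p:
        raise CollinearityError(list(names), "fixed-effect design is rank deficient")
    if n - p - g + 1 <= 0:
        raise InvalidInputError("not enough residual degrees of freedom")

    crit = lambda u: reml_criterion(10.0**u, y, Xm, codes)
    res = optimize.minimize_scalar(crit, bounds=log10_bounds, method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat, best = 10.0**res.x, res.fun
    boundary = False
    c0 = reml_criterion(0.0, y, Xm, codes)
    # treat an interior optimum pinned at the lower bound as the boundary too
    if c0 <= best or res.x <= log10_bounds[0] + 1e-6:
        if c0 <= best:
            lam_hat, best, boundary = 0.0, c0, True
        else:
            lam_hat, boundary = 10.0**res.x, True

    XtX, Xty, yty, _ = _gls_pieces(y, Xm, codes, sizes, lam_hat)
    beta = np.linalg.solve(XtX, Xty)
    rss = yty - beta @ Xty
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    ddf = n - p - g + 1
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), ddf)
    return LMMFit(
        feature_names=names,
        fixed_effect_estimates=beta,
        fixed_effect_se=se,
        fixed_effect_p_values=pvals,
        random_intercept_variance=float(max(lam_hat, 0.0) * sigma2),
        residual_variance=float(sigma2),
        variance_ratio=float(lam_hat),
        reml_criterion=float(best),
        boundary_fit=boundary,
        n_obs=n,
        n_groups=g,
        _y=y,
        _X=Xm,
        _group_sizes=sizes,
        _group_index=codes,
    )


def _whiten(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
            sizes: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Apply V0^{-1/2} for V0 = I + lam ZZ' (per-group deflation of the mean)."""
    factor = (1.0 - 1.0 / np.sqrt(1.0 + lam * sizes)) / sizes
    g = sizes.size
    Xg = np.zeros((g, X.shape[1]))
    yg = np.zeros(g)
    np.add.at(Xg, codes, X)
    np.add.at(yg, codes, y)
    return y - factor[codes] * yg[codes], X - factor[codes, None] * Xg[codes]


def _ols_r2(yw: np.ndarray, Xw: np.ndarray, const: np.ndarray) -> float:
    """R2 of whitened y on whitened predictors, relative to the whitened mean."""
    base = np.column_stack([const])
    full = np.column_stack([const, Xw])
    rss0 = np.sum((yw - base @ np.linalg.lstsq(base, yw, rcond=None)[0]) ** 2)
    rss1 = np.sum((yw - full @ np.linalg.lstsq(full, yw, rcond=None)[0]) ** 2)
    if rss0 == 0:
        return 0.0
    return float(1.0 - rss1 / rss0)


def block_effect_decomposition(
    fit: LMMFit,
    blocks: dict[str, list[str]] | None = None,
    method: str = "commonality",
) -> dict[str, float]:
    """Share of explained (marginal) variation attributed to each block.

    ``commonality`` (default) partitions the fixed-effect R2 — computed on
    GLS-whitened data at the fitted variance ratio — into portions unique
    to each block plus a shared portion split equally.  ``abs_beta`` is a
    cruder alternative: normalized sums of |estimate| per block.
    """
    blocks = blocks or {"morphology": MORPHOLOGY_BLOCK, "nutrients": NUTRIENT_BLOCK}
    if len(blocks) != 2:
        raise InvalidInputError("decomposition is defined for exactly 2 blocks")
    (name_a, cols_a), (name_b, cols_b) = blocks.items()
    if not cols_a or not cols_b:
        raise InvalidInputError("both blocks must name at least one predictor")
    idx = {name: j for j, name in enumerate(fit.feature_names)}
    missing = [c for c in (*cols_a, *cols_b) if c not in idx]
    if missing:
        raise InvalidInputError(f"block predictors not in the fit: {missing}")

    if method == "abs_beta":
        a = sum(abs(fit.fixed_effect_estimates[idx[c]]) for c in cols_a)
        b = sum(abs(fit.fixed_effect_estimates[idx[c]]) for c in cols_b)
        total = a + b
        if total == 0:
            return {name_a: 0.5, name_b: 0.5}
        return {name_a: a / total, name_b: b / total}
    if method != "commonality":
        raise InvalidInputError(f"unknown decomposition method {method!r}")

    yw, Xw = _whiten(fit._y, fit._X, fit._group_index, fit._group_sizes,
                     fit.variance_ratio)
    has_const = fit.feature_names[0] == "(intercept)"
    const = Xw[:, 0] if has_const else np.ones_like(yw)
    ja = [idx[c] for c in cols_a]
    jb = [idx[c] for c in cols_b]
    r2_full = _ols_r2(yw, Xw[:, ja + jb], const)
    r2_a = _ols_r2(yw, Xw[:, ja], const)
    r2_b = _ols_r2(yw, Xw[:, jb], const)
    unique_a = r2_full - r2_b
    unique_b = r2_full - r2_a
    common = r2_a + r2_b - r2_full
    raw_a = unique_a + common / 2.0
    raw_b = unique_b + common / 2.0
    total = raw_a + raw_b  # equals r2_full
    if total <= 0:
        return {name_a: 0.5, name_b: 0.5}
    share_a = min(max(raw_a / total, 0.0), 1.0)
    return {name_a: share_a, name_b: 1.0 - share_a}


def balanced_anova_variance_components(y, groups) -> tuple[float, float]:
    """Closed-form method-of-moments components for balanced one-way data.

    Returns (group variance, residual variance) from the classical mean
    squares: sigma2_resid = MSW, sigma2_group = (MSB - MSW) / n_per,
    clipped at zero.  Used as the independent oracle for REML in the
    balanced intercept-only case, where the two coincide.
    """
    y = np.asarray(y, dtype=float)
    codes, sizes = _group_structures(groups)
    if sizes.min() != sizes.max():
        raise InvalidInputError("closed form requires balanced groups")
    n_per = int(sizes[0])
    g = sizes.size
    means = np.bincount(codes, weights=y) / n_per
    grand = y.mean()
    msb = n_per * np.sum((means - grand) ** 2) / (g - 1)
    msw = np.sum((y - means[codes]) ** 2) / (g * (n_per - 1))
    return max((msb - msw) / n_per, 0.0), msw
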