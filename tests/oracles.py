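"""Independent flat-loop / closed-form oracles used by the tests.

Deliberately primitive implementations (plain loops, explicit normal
equations, power iteration) so they share no code path with the package.
"""

import math

import numpy as np


def flat_loop_indices(trials, reference_temperature=25.0):
    """{(population, replicate): (GDTI, GCTI, GSTI)} by brute enumeration."""
    gi = {}
    for t in trials:
        total = 0.0
        for day, n in enumerate(t.daily_counts):
            total += n / (day + 1)
        gi[(t.population_id, t.experiment, t.level_index, t.replicate)] = (
            total,
            t.level_value,
        )
    out = {}
    pops = sorted({k[0] for k in gi})
    reps = sorted({k[3] for k in gi})
    for pop in pops:
        for rep in reps:
            sums = {}
            for exp in ("drought", "cold", "saline"):
                acc = 0.0
                for level in (1, 2, 3, 4, 5):
                    g, value = gi[(pop, exp, level, rep)]
                    if exp == "drought":
                        w = 1 + abs(value)
                    elif exp == "cold":
                        w = reference_temperature / value
                    else:
                        w = 1.0 if level == 1 else value / 10.0
                    acc += g * w
                sums[exp] = acc / 5.0
            out[(pop, rep)] = (sums["drought"], sums["cold"], sums["saline"])
    return out


def anova_f_by_sums_of_squares(groups):
    """(df_between, df_within, F) from explicit sums of squares."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb = len(groups) - 1
    dfw = len(all_values) - len(groups)
    return dfb, dfw, (ss_between / dfb) / (ss_within / dfw)


def ols_by_normal_equations(y, X, intercept=True):
    """Coefficients via explicit (X'X)^-1 X'y."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return np.linalg.inv(X.T @ X) @ X.T @ np.asarray(y, dtype=float)


def first_pc_power_iteration(corr, n_iter=10_000, tol=1e-14):
    """Leading eigenvector/eigenvalue of a small symmetric matrix."""
    corr = np.asarray(corr, dtype=float)
    v = np.ones(corr.shape[0]) / math.sqrt(corr.shape[0])
    lam = 0.0
    for _ in range(n_iter):
        w = corr @ v
        lam_new = float(np.linalg.norm(w))
        w = w / lam_new
        if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
            v, lam = w, lam_new
            break
        v, lam = w, lam_new
    return lam, v


def balanced_mom_components(y, codes, n_per):
    """Method-of-moments variance components for balanced one-way data."""
    y = np.asarray(y, dtype=float)
    g = codes.max() + 1
    means = np.array([y[codes == j].mean() for j in range(g)])
    grand = y.mean()
    msb = n_per * np.sum((means - grand) ** 2) / (g - 1)
    msw = sum(np.sum((y[codes == j] - means[j]) ** 2) for j in range(g)) / (g * (n_per - 1))
    return max((msb - msw) / n_per, 0.0), msw


def ml_discrepancy_by_hand(S, sigma):
    """F_ML via explicit determinants and traces."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = S.shape[0]
    return (
        math.log(np.linalg.det(sigma))
        + float(np.trace(S @ np.linalg.inv(sigma)))
        - math.log(np.linalg.det(S))
        - p
    )
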