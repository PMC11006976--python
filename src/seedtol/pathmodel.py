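"""Recursive path analysis over observed block composites.

Climate, soil, seed-morphology and seed-nutrient blocks are each collapsed
to the scores of their first principal component (computed on z-scored
variables, sign-oriented so the loading sum is positive).  A recursive
(acyclic) structural model is then fitted on the standardized composites
and tolerance indices: for a fully recursive system, equation-by-equation
least squares gives the maximum-likelihood estimates, so no iterative
covariance fitting is needed.  The model-implied covariance is assembled
from the path coefficients, the saturated exogenous covariance block, and
the residual variances, and the usual ML fit statistics (chi-square, GFI,
CFI against an independence baseline, RMSEA) are reported alongside
direct/indirect/total effect decompositions down every directed path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .environment import standardize
from .errors import InvalidInputError
from .gradients import significance_class

BLOCKS: dict[str, list[str]] = {
    "climate": ["MAT", "MAP"],
    "soil": ["SOC", "AN", "AP", "pH"],
    "morphology": ["length", "width", "LWR", "TGW"],
    "nutrients": ["CSP", "CSS", "CS", "CCF"],
}

#: default structural graph: climate and soil are exogenous drivers; soil
#: shapes seed morphology, both shape seed nutrients, and the tolerance
#: indices sit downstream of climate, soil and the seed attribute composites.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("climate", "nutrients"),
    ("soil", "morphology"),
    ("soil", "nutrients"),
    ("climate", "GDTI"),
    ("climate", "GCTI"),
    ("climate", "GSTI"),
    ("soil", "GCTI"),
    ("morphology", "GDTI"),
    ("morphology", "GSTI"),
    ("nutrients", "GCTI"),
)

DEFAULT_EXOGENOUS: tuple[str, ...] = ("climate", "soil")


@dataclass(frozen=True)
class CompositeScores:
    """First-principal-component summary of one variable block."""

    block: str
    variables: tuple[str, ...]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: float


@dataclass(frozen=True)
class PathModelSpec:
    """Directed acyclic edge list; exogenous nodes may freely covary."""

    edges: tuple[tuple[str, str], ...] = DEFAULT_EDGES
    exogenous: tuple[str, ...] = DEFAULT_EXOGENOUS

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple((str(a), str(b)) for a, b in self.edges))
        object.__setattr__(self, "exogenous", tuple(self.exogenous))
        order = self.topological_order()
        endo = [v for v in order if v not in self.exogenous]
        parents = {v: [a for a, b in self.edges if b == v] for v in order}
        for v in endo:
            if not parents[v]:
                raise InvalidInputError(f"endogenous node {v!r} has no parents")
        for v in self.exogenous:
            if parents[v]:
                raise InvalidInputError(f"exogenous node {v!r} cannot have parents")

    @property
    def nodes(self) -> tuple[str, ...]:
        seen = list(self.exogenous)
        for a, b in self.edges:
            for v in (a, b):
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def topological_order(self) -> tuple[str, ...]:
        """Kahn's algorithm; raises on a cycle."""
        nodes = list(self.nodes)
        indeg = {v: 0 for v in nodes}
        for _, b in self.edges:
            indeg[b] += 1
        queue = [v for v in nodes if indeg[v] == 0]
        order: list[str] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for a, b in self.edges:
                if a == v:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        queue.append(b)
        if len(order) != len(nodes):
            raise InvalidInputError("path model specification contains a cycle")
        return tuple(order)


@dataclass(frozen=True)
class PathFit:
    variables: tuple[str, ...]
    coefficients: pd.DataFrame  # source, target, coefficient, se, p, class
    residual_variances: dict[str, float]
    r_squared: dict[str, float]
    effects: pd.DataFrame  # source, target, direct, indirect, total
    chi_square: float
    df: int
    gfi: float
    cfi: float
    rmsea: float
    n: int
    sample_cov: np.ndarray
    implied_cov: np.ndarray


def block_pca_scores(block_matrix: pd.DataFrame, block: str = "block") -> CompositeScores:
    """Scores on the first principal component of one z-scored block.

    The component is oriented so its loading sum is positive (first
    loading's sign breaks ties), making scores deterministic and readable
    as "more of the block".
    """
    if block_matrix.shape[0] < 3:
        raise InvalidInputError("need at least 3 rows for PCA scores")
    if block_matrix.shape[1] < 1:
        raise InvalidInputError("block must contain at least one variable")
    for col in block_matrix.columns:
        if np.ptp(block_matrix[col].to_numpy(dtype=float)) == 0:
            raise InvalidInputError(f"constant column {col!r} in block {block!r}")
    Z = np.column_stack([standardize(block_matrix[c]) for c in block_matrix.columns])
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    if np.sum(v) < 0 or (np.sum(v) == 0 and v[0] < 0):
        v = -v
    return CompositeScores(
        block=block,
        variables=tuple(block_matrix.columns),
        scores=Z @ v,
        loadings=v,
        explained_variance_fraction=float(eigvals[-1] / eigvals.sum()),
    )


def composite_table(
    traits: pd.DataFrame, sites: pd.DataFrame, indices: pd.DataFrame | None = None,
    blocks: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-population composites (block PC1 scores) plus tolerance indices.

    Traits and indices are aggregated to population means and joined to the
    site table on population_id.
    """
    blocks = blocks or BLOCKS
    trait_cols = [c for cols in blocks.values() for c in cols if c in traits.columns]
    means = traits.groupby("population_id", as_index=False)[trait_cols].mean()
    merged = means.merge(sites, on="population_id")
    out = pd.DataFrame({"population_id": merged["population_id"]})
    for block, cols in blocks.items():
        present = [c for c in cols if c in merged.columns]
        if not present:
            raise InvalidInputError(f"no variables found for block {block!r}")
        out[block] = block_pca_scores(merged[present], block).scores
    if indices is not None:
        idx_means = indices.groupby("population_id", as_index=False)[
            ["GDTI", "GCTI", "GSTI"]
        ].mean()
        out = out.merge(idx_means, on="population_id")
    return out


def _free_parameters(spec: PathModelSpec, p: int) -> int:
    q = len(spec.exogenous)
    endo = p - q
    return q * (q + 1) // 2 + len(spec.edges) + endo


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec | None = None) -> PathFit:
    """ML fit of a recursive path model on z-scored observed variables."""
    spec = spec or PathModelSpec()
    order = spec.topological_order()
    missing = [v for v in order if v not in data.columns]
    if missing:
        raise InvalidInputError(f"data lacks model variables: {missing}")
    p = len(order)
    n = len(data)
    if n <= _free_parameters(spec, p):
        raise InvalidInputError(
            f"n={n} must exceed the {_free_parameters(spec, p)} free parameters"
        )

    Z = np.column_stack([standardize(data[v]) for v in order])
    pos = {v: j for j, v in enumerate(order)}
    S = (Z.T @ Z) / (n - 1)

    B = np.zeros((p, p))  # B[j, k] = coefficient of parent k in equation j
    psi = np.zeros(p)
    r2: dict[str, float] = {}
    coef_rows = []
    endo = [v for v in order if v not in spec.exogenous]
    for v in endo:
        parents = [a for a, b in spec.edges if b == v]
        jy = pos[v]
        jx = [pos[a] for a in parents]
        X = Z[:, jx]
        y = Z[:, jy]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        psi[jy] = rss / (n - 1)
        r2[v] = float(1.0 - rss / (y @ y))
        dof = n - len(parents) - 1
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        for a, b_hat, s in zip(parents, beta, se):
            B[jy, pos[a]] = b_hat
            pval = float(2 * stats.t.sf(abs(b_hat / s), dof)) if s > 0 else 0.0
            coef_rows.append(
                {
                    "source": a,
                    "target": v,
                    "coefficient": float(b_hat),
                    "se": float(s),
                    "p": pval,
                    "class": significance_class(pval),
                }
            )

    # implied covariance: x = B x + u, Sigma = (I-B)^-1 Omega (I-B)^-T
    omega = np.diag(psi)
    exo_idx = [pos[v] for v in spec.exogenous]
    omega[np.ix_(exo_idx, exo_idx)] = S[np.ix_(exo_idx, exo_idx)]
    inv_imb = np.linalg.inv(np.eye(p) - B)
    implied = inv_imb @ omega @ inv_imb.T

    total = inv_imb - np.eye(p)
    effect_rows = []
    for src in order:
        for dst in endo:
            d = B[pos[dst], pos[src]]
            t = total[pos[dst], pos[src]]
            if d == 0.0 and t == 0.0:
                continue
            effect_rows.append(
                {
                    "source": src,
                    "target": dst,
                    "direct": float(d),
                    "indirect": float(t - d),
                    "total": float(t),
                }
            )

    df = p * (p + 1) // 2 - _free_parameters(spec, p)
    base_chi2, base_df = independence_baseline(S, n)
    chi2, gfi, cfi, rmsea = fit_indices(S, implied, n, df, base_chi2, base_df)
    return PathFit(
        variables=order,
        coefficients=pd.DataFrame(
            coef_rows, columns=["source", "target", "coefficient", "se", "p", "class"]
        ),
        residual_variances={v: float(psi[pos[v]]) for v in endo},
        r_squared=r2,
        effects=pd.DataFrame(
            effect_rows, columns=["source", "target", "direct", "indirect", "total"]
        ),
        chi_square=chi2,
        df=df,
        gfi=gfi,
        cfi=cfi,
        rmsea=rmsea,
        n=n,
        sample_cov=S,
        implied_cov=implied,
    )


def ml_discrepancy(sample_cov: np.ndarray, implied_cov: np.ndarray) -> float:
    """ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p."""
    S = np.asarray(sample_cov, dtype=float)
    sigma = np.asarray(implied_cov, dtype=float)
    p = S.shape[0]
    for name, m in (("sample", S), ("implied", sigma)):
        if m.shape != (p, p) or not np.allclose(m, m.T, atol=1e-10):
            raise InvalidInputError(f"{name} covariance must be square symmetric")
        if np.linalg.eigvalsh(m).min() <= 0:
            raise InvalidInputError(f"{name} covariance is not positive definite")
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_i, logdet_i = np.linalg.slogdet(sigma)
    return float(logdet_i + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def independence_baseline(sample_cov: np.ndarray, n: int) -> tuple[float, int]:
    """Chi-square and df of the all-covariances-zero baseline model."""
    S = np.asarray(sample_cov, dtype=float)
    p = S.shape[0]
    chi2 = (n - 1) * ml_discrepancy(S, np.diag(np.diag(S)))
    return float(chi2), p * (p - 1) // 2


def fit_indices(
    sample_cov, implied_cov, n: int, df: int,
    baseline_chi_square: float, baseline_df: int,
) -> tuple[float, float, float, float]:
    """(chi_square, GFI, CFI, RMSEA) from the ML discrepancy."""
    S = np.asarray(sample_cov, dtype=float)
    sigma = np.asarray(implied_cov, dtype=float)
    chi2 = max((n - 1) * ml_discrepancy(S, sigma), 0.0)
    w = np.linalg.inv(sigma) @ S
    p = S.shape[0]
    resid = w - np.eye(p)
    gfi = float(1.0 - np.trace(resid @ resid) / np.trace(w @ w))
    denom = max(baseline_chi_square - baseline_df, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else float(1.0 - max(chi2 - df, 0.0) / denom)
    rmsea = 0.0 if df == 0 else float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    return float(chi2), gfi, cfi, rmsea
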