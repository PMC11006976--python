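import numpy as np
import pandas as pd
import pytest

from seedtol import (
    InvalidInputError,
    PathModelSpec,
    block_pca_scores,
    composite_table,
    fit_indices,
    fit_path_model,
    independence_baseline,
    ml_discrepancy,
    standardize,
)

from .oracles import first_pc_power_iteration, ml_discrepancy_by_hand, ols_by_normal_equations


class TestBlockPCA:
    def test_single_variable_block_is_its_zscore(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        scores = block_pca_scores(pd.DataFrame({"MAT": x}))
        assert scores.scores == pytest.approx(standardize(x))
        assert scores.explained_variance_fraction == pytest.approx(1.0)

    def test_two_perfectly_correlated_variables(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 9.0])
        scores = block_pca_scores(pd.DataFrame({"a": x, "b": 3 * x + 1}))
        assert scores.explained_variance_fraction == pytest.approx(1.0)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(size=(6, 3)), columns=["u", "v", "w"])
        scores = block_pca_scores(frame)
        Z = np.column_stack([standardize(frame[c]) for c in frame.columns])
        corr = Z.T @ Z / (len(frame) - 1)
        lam, vec = first_pc_power_iteration(corr)
        if vec.sum() < 0:
            vec = -vec
        assert scores.loadings == pytest.approx(vec, abs=1e-8)
        assert scores.scores == pytest.approx(Z @ vec, abs=1e-8)
        assert scores.explained_variance_fraction == pytest.approx(lam / 3.0, abs=1e-10)

    def test_orientation_is_deterministic(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        scores = block_pca_scores(frame)
        assert scores.loadings.sum() > 0

    def test_constant_column_named_in_error(self):
        frame = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(InvalidInputError, match="flat"):
            block_pca_scores(frame)


def chain_data(a=0.7, b=0.6, n=2000, seed=42):
    """climate -> nutrients -> GCTI with unit-variance construction."""
    rng = np.random.default_rng(seed)
    climate = rng.normal(size=n)
    nutrients = a * climate + np.sqrt(1 - a**2) * rng.normal(size=n)
    gcti = b * nutrients + np.sqrt(1 - b**2) * rng.normal(size=n)
    return pd.DataFrame({"climate": climate, "nutrients": nutrients, "GCTI": gcti})


CHAIN_SPEC = PathModelSpec(
    edges=(("climate", "nutrients"), ("nutrients", "GCTI")), exogenous=("climate",)
)


class TestPathModel:
    def test_saturated_model_reproduces_sample_covariance(self):
        rng = np.random.default_rng(3)
        n = 60
        climate = rng.normal(size=n)
        soil = 0.5 * climate + rng.normal(size=n)
        morph = 0.4 * soil + rng.normal(size=n)
        gdti = 0.3 * climate + 0.5 * morph + rng.normal(size=n)
        data = pd.DataFrame(
            {"climate": climate, "soil": soil, "morphology": morph, "GDTI": gdti}
        )
        spec = PathModelSpec(
            edges=(
                ("climate", "morphology"), ("soil", "morphology"),
                ("climate", "GDTI"), ("soil", "GDTI"), ("morphology", "GDTI"),
            ),
            exogenous=("climate", "soil"),
        )
        fit = fit_path_model(data, spec)
        assert fit.df == 0
        assert fit.chi_square <= 1e-8
        assert fit.rmsea == 0.0
        assert fit.gfi == pytest.approx(1.0, abs=1e-8)
        assert fit.cfi == pytest.approx(1.0)
        assert fit.implied_cov == pytest.approx(fit.sample_cov, abs=1e-10)

    def test_chain_indirect_effect_product_of_paths(self):
        fit = fit_path_model(chain_data(), CHAIN_SPEC)
        row = fit.effects.set_index(["source", "target"]).loc[("climate", "GCTI")]
        assert row["direct"] == 0.0
        assert row["indirect"] == pytest.approx(0.42, abs=0.05)
        # indirect equals the product of the two fitted path coefficients
        coefs = fit.coefficients.set_index(["source", "target"])["coefficient"]
        assert row["indirect"] == pytest.approx(
            coefs[("climate", "nutrients")] * coefs[("nutrients", "GCTI")], abs=1e-12
        )

    def test_total_equals_direct_plus_indirect(self):
        fit = fit_path_model(chain_data(n=200, seed=5), CHAIN_SPEC)
        assert fit.effects["total"].to_numpy() == pytest.approx(
            (fit.effects["direct"] + fit.effects["indirect"]).to_numpy(), abs=1e-10
        )

    def test_total_effects_match_reduced_form_regression(self):
        data = chain_data(n=2000, seed=6)
        fit = fit_path_model(data, CHAIN_SPEC)
        total = fit.effects.set_index(["source", "target"]).loc[("climate", "GCTI"), "total"]
        reduced = ols_by_normal_equations(
            standardize(data["GCTI"]), standardize(data["climate"])
        )[1]
        assert total == pytest.approx(reduced, abs=0.05)

    def test_coefficients_match_per_equation_ols_oracle(self):
        rng = np.random.default_rng(7)
        n = 21
        data = pd.DataFrame(
            {
                "climate": rng.normal(size=n),
                "nutrients": rng.normal(size=n),
                "GCTI": rng.normal(size=n),
            }
        )
        fit = fit_path_model(data, CHAIN_SPEC)
        coefs = fit.coefficients.set_index(["source", "target"])["coefficient"]
        b1 = ols_by_normal_equations(
            standardize(data["nutrients"]), standardize(data["climate"]), intercept=False
        )[0]
        b2 = ols_by_normal_equations(
            standardize(data["GCTI"]), standardize(data["nutrients"]), intercept=False
        )[0]
        assert coefs[("climate", "nutrients")] == pytest.approx(b1, abs=1e-10)
        assert coefs[("nutrients", "GCTI")] == pytest.approx(b2, abs=1e-10)
        # per-equation R2 equals the OLS R2 of that equation
        z = standardize(data["GCTI"])
        resid = z - b2 * standardize(data["nutrients"])
        r2 = 1 - (resid @ resid) / (z @ z)
        assert fit.r_squared["GCTI"] == pytest.approx(r2, abs=1e-10)

    def test_relabeling_invariance(self):
        data = chain_data(n=100, seed=8)
        fit = fit_path_model(data, CHAIN_SPEC)
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_path_model(shuffled, CHAIN_SPEC)
        assert fit2.chi_square == pytest.approx(fit.chi_square, abs=1e-9)
        assert fit2.rmsea == pytest.approx(fit.rmsea, abs=1e-9)

    def test_cycle_rejected(self):
        with pytest.raises(InvalidInputError, match="cycle"):
            PathModelSpec(edges=(("a", "b"), ("b", "a")), exogenous=())

    def test_too_small_n_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_path_model(chain_data(n=5), CHAIN_SPEC)


class TestFitIndices:
    def test_perfect_fit_limits(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 3))
        S = np.cov(X, rowvar=False)
        chi2, gfi, cfi, rmsea = fit_indices(S, S, 50, 2, 120.0, 3)
        assert chi2 == 0.0
        assert gfi == pytest.approx(1.0)
        assert cfi == pytest.approx(1.0)
        assert rmsea == 0.0

    def test_independence_baseline_positive_on_correlated_data(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=80)
        X = np.column_stack([x, 0.8 * x + rng.normal(0, 0.6, 80), rng.normal(size=80)])
        S = np.cov(X, rowvar=False)
        chi2, df = independence_baseline(S, 80)
        assert chi2 > 0
        assert df == 3
        # the baseline model evaluated against itself as baseline has CFI 0
        _, _, cfi, _ = fit_indices(S, np.diag(np.diag(S)), 80, df, chi2, df)
        assert cfi == pytest.approx(0.0, abs=1e-10)

    def test_discrepancy_matches_hand_computation(self):
        S = np.array([[2.0, 0.6, 0.3], [0.6, 1.5, 0.4], [0.3, 0.4, 1.2]])
        sigma = np.array([[2.0, 0.5, 0.2], [0.5, 1.5, 0.3], [0.2, 0.3, 1.2]])
        assert ml_discrepancy(S, sigma) == pytest.approx(
            ml_discrepancy_by_hand(S, sigma), abs=1e-8
        )

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        good = np.eye(2)
        with pytest.raises(InvalidInputError):
            ml_discrepancy(bad, good)


def test_composite_table_on_demo21(demo21_trait_table, demo21_sites, demo21_indices):
    table = composite_table(demo21_trait_table, demo21_sites, demo21_indices)
    assert set(table.columns) == {
        "population_id", "climate", "soil", "morphology", "nutrients",
        "GDTI", "GCTI", "GSTI",
    }
    for block in ("climate", "soil", "morphology", "nutrients"):
        assert table[block].mean() == pytest.approx(0.0, abs=1e-10)


def test_default_model_fits_demo21(demo21_trait_table, demo21_sites, demo21_indices):
    table = composite_table(demo21_trait_table, demo21_sites, demo21_indices)
    fit = fit_path_model(table)
    assert fit.df > 0
    assert fit.chi_square >= 0
    assert 0 <= fit.rmsea
    assert all(0 <= v <= 1 for v in fit.r_squared.values())
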