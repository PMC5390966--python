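import numpy as np
import pandas as pd
import pytest

from phylogeodiv.pgls import (
    PGLSError,
    aicc,
    drop_one_importance,
    lambda_transform,
    null_model_test,
    pgls_fit,
    phylo_covariance,
    sqrt_transform,
)
from phylogeodiv.simulate import simulate_backbone, simulate_traits, simulate_tree_set
from phylogeodiv.treeio import parse_newick


def _xy(n, seed, slope=0.5):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = 1.0 + slope * x + rng.normal(size=n)
    return y, np.column_stack([np.ones(n), x])


class TestTransforms:
    def test_sqrt_values(self):
        df = pd.DataFrame({"a": [4.0, 0.0, 9.0], "b": [1.0, 2.0, 3.0]})
        out = sqrt_transform(df, ["a"])
        np.testing.assert_allclose(out["a"], [2.0, 0.0, 3.0])
        pd.testing.assert_series_equal(out["b"], df["b"])
        assert out.attrs["sqrt_transformed"] == ["a"]

    def test_negative_value_names_row(self):
        df = pd.DataFrame({"a": [1.0, -2.0]})
        with pytest.raises(PGLSError, match="rows \\[1\\]"):
            sqrt_transform(df, ["a"])


class TestCovariance:
    def test_worked_example(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        cov = phylo_covariance(tree, ["a", "b", "c"])
        np.testing.assert_allclose(
            cov, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12)

    def test_star_tree_is_diagonal(self):
        tree = parse_newick("(a:3,b:3,c:3,d:3);")
        cov = phylo_covariance(tree, ["a", "b", "c", "d"])
        np.testing.assert_allclose(cov, 3 * np.eye(4), atol=1e-12)

    def test_lambda_zero_keeps_only_diagonal(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        cov = lambda_transform(phylo_covariance(tree, ["a", "b", "c"]), 0.0)
        np.testing.assert_allclose(cov, 2 * np.eye(3))

    def test_missing_species_listed(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        with pytest.raises(PGLSError, match="ghost"):
            phylo_covariance(tree, ["a", "ghost"])


class TestFit:
    def test_lambda_zero_reduces_to_ols(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        y, X = _xy(50, 3)
        fit = pgls_fit(y, X, cov=cov, lambda_mode=0.0)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)

    def test_star_tree_pgls_equals_ols_at_any_lambda(self):
        tree = parse_newick("(" + ",".join(f"s{i}:2" for i in range(30)) + ");")
        cov = phylo_covariance(tree, [f"s{i}" for i in range(30)])
        y, X = _xy(30, 4)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        for lam in (0.0, 0.5, "ml"):
            fit = pgls_fit(y, X, cov=cov, lambda_mode=lam)
            np.testing.assert_allclose(fit.params, beta, atol=1e-8)

    def test_gls_solution_matches_explicit_inverse(self, backbone_50):
        # independent route: beta = (X' V^-1 X)^-1 X' V^-1 y
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        y, X = _xy(50, 5)
        fit = pgls_fit(y, X, cov=cov, lambda_mode=0.6)
        V = lambda_transform(cov, 0.6)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)

    def test_aicc_identity_recomputed(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        y, X = _xy(50, 6)
        fit = pgls_fit(y, X, cov=cov)
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, fit.n), abs=1e-12)
        k = fit.k
        n = fit.n
        assert fit.aicc == pytest.approx(
            -2 * fit.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1), abs=1e-12)

    def test_profile_maximum_beats_endpoints(self, backbone_50):
        tree, lats = backbone_50
        tr = simulate_traits(tree, lats, beta_lat=-0.1, pagel_lambda_true=0.7,
                             trait_sigma2=0.4, seed=8)
        y = tr["response"].to_numpy()
        X = np.column_stack([np.ones(50), tr["abs_lat_midpoint"]])
        cov = phylo_covariance(tree, tr["species_id"].tolist())
        fit = pgls_fit(y, X, cov=cov)
        for lam in (1e-6, 1.0):
            assert fit.loglik >= pgls_fit(y, X, cov=cov,
                                          lambda_mode=lam).loglik - 1e-6

    def test_perfect_fit_adjusted_r2_is_one(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x])
        y = 2.0 + 3.0 * x
        fit = pgls_fit(y, X, cov=cov, lambda_mode=0.5)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_adjusted_r2_invariant_to_predictor_rescaling(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        y, X = _xy(50, 9)
        X2 = X.copy()
        X2[:, 1] *= 1000.0
        f1 = pgls_fit(y, X, cov=cov, lambda_mode=0.4)
        f2 = pgls_fit(y, X2, cov=cov, lambda_mode=0.4)
        assert f1.adj_r2 == pytest.approx(f2.adj_r2, abs=1e-10)

    def test_collinear_design_rejected(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(PGLSError, match="singular"):
            pgls_fit(rng.normal(size=50), X, cov=cov, lambda_mode=0.5)


class TestImportance:
    def _setup(self, seed, slope2=0.0, n=60, n_trees=15):
        trees = simulate_tree_set(n, n_trees, yule_rate=0.3, seed=seed)
        species = [f"sp{i + 1:03d}" for i in range(n)]
        covs = [phylo_covariance(t, species) for t in trees]
        rng = np.random.default_rng(seed + 1)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 1.0 + 1.0 * x1 + slope2 * x2 + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x1, x2])
        return y, X, covs

    def test_weights_sum_to_one(self):
        y, X, covs = self._setup(100)
        table = drop_one_importance(y, X, ["intercept", "x1", "x2"], covs,
                                    lambda_mode=0.0)
        assert sum(table.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_null_predictor_rarely_important(self):
        hits = 0
        for rep in range(12):
            y, X, covs = self._setup(200 + rep, slope2=0.0)
            table = drop_one_importance(y, X, ["intercept", "x1", "x2"], covs,
                                        lambda_mode=0.0)
            hits += table.delta_aicc["x2"] < 2.0
        assert hits >= 10

    def test_strong_predictor_flagged_important(self):
        hits = 0
        for rep in range(12):
            y, X, covs = self._setup(300 + rep, slope2=1.0)
            table = drop_one_importance(y, X, ["intercept", "x1", "x2"], covs,
                                        lambda_mode=0.0)
            hits += table.delta_aicc["x2"] > 2.0
        assert hits >= 11


class TestNullModel:
    def test_same_seed_same_p(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        rng = np.random.default_rng(0)
        y = rng.lognormal(0.0, 0.5, size=50)
        x = lats["lat_midpoint"].to_numpy()
        r1 = null_model_test(y, x, cov, n_rep=50, seed=7)
        r2 = null_model_test(y, x, cov, n_rep=50, seed=7)
        assert r1.p_value == r2.p_value
        assert len(r1.simulated_adj_r2) == 50

    def test_planted_strong_effect_gives_p_zero(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        x = lats["lat_midpoint"].to_numpy()
        rng = np.random.default_rng(1)
        y = np.exp(0.05 * x) * rng.lognormal(0.0, 0.05, size=50)
        res = null_model_test(y, x, cov, n_rep=100, seed=3)
        assert res.p_value == 0.0
        assert res.significant

    def test_lineage_loss_family_respects_unit_interval(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        rng = np.random.default_rng(2)
        y = rng.beta(2, 2, size=50)
        res = null_model_test(y, lats["lat_midpoint"].to_numpy(), cov,
                              n_rep=50, family="normal", seed=4)
        assert ((res.simulated_adj_r2 >= -1) & (res.simulated_adj_r2 <= 1)).all()

    def test_degenerate_response_rejected(self, backbone_50):
        tree, lats = backbone_50
        cov = phylo_covariance(tree, lats["species_id"].tolist())
        with pytest.raises(PGLSError):
            null_model_test(np.ones(50), lats["lat_midpoint"].to_numpy(), cov,
                            n_rep=10, seed=0)


def test_trait_simulation_pgls_type_one_error_calibrated(backbone_50):
    # beta_lat = 0: the PGLS latitude slope should reject at ~5%
    hits = 0
    reps = 400
    tree, lats = simulate_backbone(150, 0.2, seed=555)
    cov = phylo_covariance(tree, lats["species_id"].tolist())
    X = np.column_stack([np.ones(150), np.abs(lats["lat_midpoint"])])
    for rep in range(reps):
        tr = simulate_traits(tree, lats, beta_lat=0.0, pagel_lambda_true=0.5,
                             trait_sigma2=0.3, seed=rep)
        fit = pgls_fit(tr["response"].to_numpy(), X, cov=cov)
        hits += fit.pvalues[1] < 0.05
    assert 0.03 <= hits / reps <= 0.07
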