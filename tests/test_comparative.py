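"""Phylogenetic regressions: covariance, lambda GLS, Firth logistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import phylosym as ps
from phylosym.comparative import (
    count_enrichment_scan,
    enrichment_scan,
    lambda_transform,
    make_design,
    phylo_linear_fit,
    phylo_logistic_fit,
    trait_seed,
    vcv_from_tree,
)
from phylosym.tree import PhyloTree


def star_tree(n, length=1.0):
    return PhyloTree.from_newick(
        "(" + ",".join(f"t{i}:{length}" for i in range(n)) + ");"
    )


def firth_logistic_oracle(y, X):
    """Independent Firth-penalized logistic fit: direct maximization of
    loglik + 0.5*logdet(X'WX) with a generic optimizer (no IRLS, no tree)."""

    def neg_pen(beta):
        eta = np.clip(X @ beta, -30, 30)
        ll = np.sum(y * eta - np.log1p(np.exp(eta)))
        W = 1.0 / (1.0 + np.exp(-eta))
        W = W * (1 - W)
        sign, logdet = np.linalg.slogdet(X.T @ (X * W[:, None]))
        return -(ll + 0.5 * logdet)

    res = optimize.minimize(neg_pen, np.zeros(X.shape[1]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000})
    return res.x


class TestLambdaTransform:
    def test_identity_at_one(self):
        V = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert np.array_equal(lambda_transform(V, 1.0), V)

    def test_diagonal_at_zero(self):
        V = np.array([[2.0, 1.0], [1.0, 3.0]])
        assert np.array_equal(lambda_transform(V, 0.0), np.diag([2.0, 3.0]))

    def test_halves_offdiagonal(self):
        V = np.array([[2.0, 1.0], [1.0, 2.0]])
        out = lambda_transform(V, 0.5)
        assert out[0, 1] == 0.5 and out[0, 0] == 2.0

    def test_domain(self):
        with pytest.raises(ValueError):
            lambda_transform(np.eye(2), 1.5)


class TestLinear:
    def test_lambda_zero_reduces_to_ols(self):
        tree = ps.simulate_tree(40, seed=1)  # ultrametric
        rng = np.random.default_rng(0)
        n = 40
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = 1.0 + 0.5 * x + rng.standard_normal(n)  # independent noise
        fit = phylo_linear_fit(y, X, tree, B=10, seed=0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.lambda_ < 0.05
        # refit with lambda pinned at 0 via the transform directly
        V0 = lambda_transform(vcv_from_tree(tree), 0.0)
        L = np.linalg.cholesky(V0)
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        gls0 = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        assert np.allclose(gls0, ols, atol=1e-8)  # ultrametric: WLS == OLS

    def test_constant_response_duplicate_design(self):
        tree = ps.simulate_tree(20, seed=3)
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.full(20, 7.0)
        fit = phylo_linear_fit(y, X, tree, B=5, seed=0)
        assert fit.beta[0] == pytest.approx(7.0, abs=1e-8)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)

    def test_singular_design_rejected(self):
        tree = ps.simulate_tree(10, seed=0)
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="singular"):
            phylo_linear_fit(np.arange(10.0), X, tree)

    def test_tip_reorder_invariance(self):
        tree = ps.simulate_tree(30, seed=9)
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 30).astype(float)
        X = np.column_stack([np.ones(30), x])
        L = np.linalg.cholesky(vcv_from_tree(tree) + 1e-12 * np.eye(30))
        y = X @ [1.0, -0.5] + L @ rng.standard_normal(30)
        f1 = phylo_linear_fit(y, X, tree, B=5, seed=0)
        t2 = PhyloTree.from_newick(tree.to_newick())
        idx = [tree.tip_labels.index(l) for l in t2.tip_labels]
        f2 = phylo_linear_fit(y[idx], X[idx], t2, B=5, seed=0)
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)
        assert f1.lambda_ == pytest.approx(f2.lambda_, abs=1e-6)


class TestLogistic:
    def test_star_tree_matches_firth_oracle(self):
        n = 40
        tree = star_tree(n)
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), x])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 1.0 * x)))).astype(int)
        fit = phylo_logistic_fit(y, X, tree, B=5, seed=0)
        oracle = firth_logistic_oracle(y.astype(float), X)
        assert np.allclose(fit.beta, oracle, atol=1e-4)

    def test_constant_response_rejected(self):
        tree = star_tree(10)
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="variation"):
            phylo_logistic_fit(np.ones(10, dtype=int), X, tree)

    def test_nonbinary_rejected(self):
        tree = star_tree(4)
        with pytest.raises(ValueError, match="binary"):
            phylo_logistic_fit(np.array([0, 1, 2, 1]), np.ones((4, 1)), tree)

    def test_finite_under_complete_separation(self):
        n = 30
        tree = star_tree(n)
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        X = np.column_stack([np.ones(n), x])
        y = x.astype(int)  # perfectly separated
        fit = phylo_logistic_fit(y, X, tree, B=5, seed=0)
        assert np.all(np.isfinite(fit.beta))
        assert fit.separation

    def test_tip_reorder_invariance(self):
        # estimates agree to the numerical noise floor of the likelihood
        # (floating-point summation order shifts the optimum by ~1e-7)
        tree = ps.simulate_tree(40, seed=11)
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 40).astype(float)
        X = np.column_stack([np.ones(40), x])
        y = (rng.random(40) < 1 / (1 + np.exp(-(x - 0.4)))).astype(int)
        f1 = phylo_logistic_fit(y, X, tree, B=5, seed=0)
        t2 = PhyloTree.from_newick(tree.to_newick())
        idx = [tree.tip_labels.index(l) for l in t2.tip_labels]
        f2 = phylo_logistic_fit(y[idx], X[idx], t2, B=5, seed=0)
        assert np.allclose(f1.beta, f2.beta, atol=1e-6)

    def test_bootstrap_replicate_count(self):
        tree = star_tree(20)
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 20).astype(float)
        X = np.column_stack([np.ones(20), x])
        y = (rng.random(20) < 0.5).astype(int)
        fit = phylo_logistic_fit(y, X, tree, B=37, seed=0)
        assert fit.bootstrap_replicates.shape == (37, 2)
        assert np.all((fit.p_boot > 0) & (fit.p_boot <= 1))


class TestScans:
    def test_design_binary_lifestyle(self):
        pred = pd.Series({"a": "free-living", "b": "host-associated",
                          "c": "free-living"})
        X, names = make_design(pred, ["a", "b", "c"])
        assert names == ["intercept", "host-associated"]
        assert X[:, 1].tolist() == [0.0, 1.0, 0.0]

    def test_design_multilevel_baseline_free_living(self):
        pred = pd.Series({"a": "free-living", "b": "lichen", "c": "cycad"})
        X, names = make_design(pred, ["a", "b", "c"])
        assert names == ["intercept", "cycad", "lichen"]

    def test_design_constant_rejected(self):
        pred = pd.Series({"a": "x", "b": "x"})
        with pytest.raises(ValueError, match="constant"):
            make_design(pred, ["a", "b"])

    def test_trait_equal_to_predictor_on_star_tree(self):
        n = 40
        tree = star_tree(n)
        rng = np.random.default_rng(0)
        host = np.zeros(n, dtype=int)
        host[rng.choice(n, n // 2, replace=False)] = 1
        tm = pd.DataFrame({"t": host}, index=tree.tip_labels)
        pred = pd.Series(
            np.where(host == 1, "host-associated", "free-living"),
            index=tree.tip_labels,
        )
        out = enrichment_scan(tm, pred, tree, B=100, seed=0)
        row = out.iloc[0]
        assert row["estimate"] > 2
        assert row["p_boot"] < 0.05
        assert row["significant"]
        assert row["direction"] == "enriched"

    def test_degenerate_trait_flagged_not_dropped(self):
        tree = star_tree(10)
        tm = pd.DataFrame({"const": np.zeros(10, dtype=int)},
                          index=tree.tip_labels)
        pred = pd.Series(["free-living"] * 5 + ["host-associated"] * 5,
                         index=tree.tip_labels)
        out = enrichment_scan(tm, pred, tree, B=10, seed=0)
        assert len(out) == 1
        assert not out.iloc[0]["converged"]
        assert out.iloc[0]["direction"] == "none"

    def test_count_scan_excludes_constant_columns(self):
        tree = ps.simulate_tree(30, seed=2)
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({
            "total": rng.poisson(5, 30),
            "empty": np.zeros(30, dtype=int),
        }, index=tree.tip_labels)
        pred = pd.Series(rng.choice(["free-living", "host-associated"], 30),
                         index=tree.tip_labels)
        out = count_enrichment_scan(counts, pred, tree, B=10, seed=0)
        empty_row = out[out.trait_id == "empty"].iloc[0]
        assert not empty_row["converged"]
        assert empty_row["note"] == "constant response"
        total_row = out[out.trait_id == "total"].iloc[0]
        assert np.isfinite(total_row["estimate"])

    def test_trait_seed_stable(self):
        assert trait_seed(1, "F001") == trait_seed(1, "F001")
        assert trait_seed(1, "F001") != trait_seed(2, "F001")
        assert 0 <= trait_seed(3, "x") < 2**31
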