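"""Phylogenetic covariance models, PGLS, PIC, Mantel and phylogenetic PCA."""

import dendropy
import numpy as np
import pytest

from tradescape import aicc, fit_trait_model, mantel, model_vcv, pgls, pic, ppca, rate_association
from tradescape.phylo import pgls_design_comparison, tree_tmrca
from tradescape.synthetic import gen_tree


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def _star_tree(n):
    tips = ",".join(f"t{i}:1.0" for i in range(n))
    return _tree(f"({tips});")


class TestModelVCV:
    def test_two_independent_tips_bm(self):
        labels, V = model_vcv(_tree("(A:1,B:1);"), "BM")
        assert np.allclose(V, np.eye(2))

    def test_eb_limit_reduces_to_bm(self):
        tree = gen_tree(30, seed=2)
        _, Vbm = model_vcv(tree, "BM")
        _, Veb = model_vcv(tree, "EB", {"r": -1e-9})
        assert np.abs(Veb - Vbm).max() < 1e-8

    def test_ou_matches_simulated_stationary_process(self):
        """Monte-Carlo oracle: covariance of simulated OU paths on a 4-tip tree."""
        tree = _tree("((A:0.6,B:0.6):0.4,(C:0.3,D:0.3):0.7);")
        alpha = 1.5
        labels, V = model_vcv(tree, "OU", {"alpha": alpha})
        rng = np.random.default_rng(0)
        n = 200_000
        vals = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                vals[node] = rng.normal(0, np.sqrt(1 / (2 * alpha)), n)
            else:
                decay = np.exp(-alpha * node.edge.length)
                sd = np.sqrt((1 - decay**2) / (2 * alpha))
                vals[node] = vals[node.parent_node] * decay + rng.normal(0, sd, n)
        sims = np.array([vals[leaf] for leaf in tree.leaf_node_iter()])
        assert np.abs(np.cov(sims) - V).max() < 0.005

    def test_ou_requires_ultrametric_tree(self):
        with pytest.raises(ValueError, match="ultrametric"):
            model_vcv(_tree("(A:2,B:1);"), "OU", {"alpha": 1.0})

    def test_bm_vcv_symmetric_psd(self):
        _, V = model_vcv(gen_tree(40, seed=3), "BM")
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-10


class TestTraitModels:
    def test_aicc_arithmetic(self):
        assert aicc(-10.0, 2, 20) == pytest.approx(24.7059, abs=1e-4)

    def test_star_tree_bm_sigma2_closed_form(self):
        tree = _star_tree(12)
        rng = np.random.default_rng(4)
        y = rng.normal(size=12)
        trait = {f"t{i}": y[i] for i in range(12)}
        fit = fit_trait_model(trait, tree, "BM")
        assert fit.params["root"] == pytest.approx(y.mean())
        assert fit.params["sigma2"] == pytest.approx(((y - y.mean()) ** 2).mean())

    def test_bm_preferred_and_rate_recovered_on_bm_data(self):
        """Replicated BM simulations: AICc prefers BM, sigma2 near truth."""
        tree = gen_tree(60, seed=9)
        labels, M = tree_tmrca(tree)
        L = np.linalg.cholesky(M)
        preferred, s2 = 0, []
        n_rep = 20
        for rep in range(n_rep):
            y = L @ np.random.default_rng(rep).normal(size=60)
            trait = dict(zip(labels, y))
            fits = {m: fit_trait_model(trait, tree, m) for m in ("BM", "OU", "EB")}
            preferred += min(fits, key=lambda m: fits[m].aicc) == "BM"
            s2.append(fits["BM"].params["sigma2"])
        assert preferred > n_rep / 2
        assert abs(np.mean(s2) - 1.0) < 0.2


class TestPGLS:
    def test_star_tree_equals_ols(self):
        tree = _star_tree(15)
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = 2 + 0.5 * x + rng.normal(0, 0.3, 15)
        fit = pgls(y, x, tree=tree, n_perm=9, seed=0)
        X = np.column_stack([np.ones(15), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.coefficients.ravel(), beta_ols, atol=1e-8)

    def test_perfect_fit(self):
        tree = gen_tree(12, seed=1)
        labels, _ = tree_tmrca(tree)
        x = np.linspace(0, 1, 12)
        fit = pgls(x, x, tree=tree, n_perm=9, seed=0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients.ravel()[1] == pytest.approx(1.0)

    def test_matches_explicit_gls_formula(self):
        tree = gen_tree(10, seed=6)
        labels, V = model_vcv(tree, "BM")
        rng = np.random.default_rng(6)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        fit = pgls(y, x, vcv=V, n_perm=9, seed=0)
        X = np.column_stack([np.ones(10), x])
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(fit.coefficients.ravel(), beta, atol=1e-10)

    def test_singular_design_errors(self):
        tree = _star_tree(8)
        x = np.ones(8)
        with pytest.raises(ValueError, match="singular"):
            pgls(np.arange(8.0), np.column_stack([x, x]), tree=tree, n_perm=9)

    def test_design_comparison_reports_three_models(self):
        tree = gen_tree(20, seed=7)
        labels, _ = tree_tmrca(tree)
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        table = pgls_design_comparison(y, x, tree=tree)
        assert set(table["design"]) == {"intercept", "linear", "quadratic"}
        assert table["aicc"].is_monotonic_increasing


class TestPIC:
    def test_two_tip_contrast(self):
        contrasts = pic({"A": 0.0, "B": 2.0}, _tree("(A:1,B:1);"))
        assert abs(contrasts[0]) == pytest.approx(2 / np.sqrt(2))

    def test_constant_trait_zero_contrasts(self):
        tree = gen_tree(20, seed=8)
        labels, _ = tree_tmrca(tree)
        contrasts = pic({lab: 3.14 for lab in labels}, tree)
        assert np.allclose(contrasts, 0)
        assert len(contrasts) == 19

    def test_bm_rate_recovered_from_contrasts(self):
        tree = gen_tree(200, seed=10)
        labels, M = tree_tmrca(tree)
        L = np.linalg.cholesky(M)
        y = L @ np.random.default_rng(10).normal(size=200) * np.sqrt(2.0)
        contrasts = pic(dict(zip(labels, y)), tree)
        assert abs((contrasts**2).mean() - 2.0) / 2.0 < 0.15


class TestMantel:
    def test_hand_computed_statistic(self):
        d1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        d2 = np.array([[0, 4, 5], [4, 0, 6], [5, 6, 0]], float)
        assert mantel(d1, d2, n_perm=9, seed=0)["z"] == pytest.approx(32.0)

    def test_self_association_minimal_p(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        d = np.abs(x[:, None] - x[None, :])
        res = mantel(d, d, n_perm=199, seed=0)
        assert res["p"] <= 0.02

    def test_permutation_p_matches_exhaustive_enumeration(self):
        from itertools import permutations

        rng = np.random.default_rng(12)
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        d1 = np.abs(a[:, None] - a[None, :])
        d2 = np.abs(b[:, None] - b[None, :])
        iu = np.triu_indices(4, 1)
        z = (d1[iu] * d2[iu]).sum()
        exact = np.mean(
            [
                (d1[iu] * d2[np.ix_(p, p)][iu]).sum() >= z - 1e-12
                for p in permutations(range(4))
            ]
        )
        res = mantel(d1, d2, n_perm=4999, seed=1)
        assert res["p"] == pytest.approx(exact, abs=0.05)

    def test_z_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        d1 = np.abs(a[:, None] - a[None, :])
        d2 = np.abs(b[:, None] - b[None, :])
        p = rng.permutation(6)
        z1 = mantel(d1, d2, n_perm=9, seed=0)["z"]
        z2 = mantel(d1[np.ix_(p, p)], d2[np.ix_(p, p)], n_perm=9, seed=0)["z"]
        assert z1 == pytest.approx(z2)


class TestPhylogeneticPCA:
    def test_star_tree_reduces_to_ordinary_pca(self):
        tree = _star_tree(20)
        rng = np.random.default_rng(14)
        X = rng.normal(size=(20, 5))
        labels, _ = tree_tmrca(tree)
        res = ppca(X, tree)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        assert np.allclose(res["eigenvalues"], evals, atol=1e-8)
        assert np.allclose(np.abs(res["scores"]), np.abs(Xc @ res["eigenvectors"]), atol=1e-8)

    def test_scores_back_transform_to_data(self):
        tree = gen_tree(15, seed=15)
        rng = np.random.default_rng(15)
        X = rng.normal(size=(15, 4))
        res = ppca(X, tree)
        rebuilt = res["scores"] @ res["eigenvectors"].T + res["mean"]
        assert np.allclose(rebuilt, X, atol=1e-8)

    def test_evolutionary_covariance_matches_gls_formula(self):
        tree = gen_tree(6, seed=16)
        labels, V = model_vcv(tree, "BM")
        rng = np.random.default_rng(16)
        X = rng.normal(size=(6, 3))
        res = ppca(X, tree)
        Vi = np.linalg.inv(V)
        ones = np.ones((6, 1))
        a = np.linalg.solve(ones.T @ Vi @ ones, ones.T @ Vi @ X)
        C = (X - a).T @ Vi @ (X - a) / 5
        assert np.allclose(np.sort(res["eigenvalues"]), np.sort(np.linalg.eigvalsh(C)), atol=1e-10)


class TestRateAssociation:
    def test_identical_tables_give_unit_correlations(self):
        tree = gen_tree(20, seed=17)
        labels, _ = tree_tmrca(tree)
        rates = dict(zip(labels, np.random.default_rng(17).lognormal(size=20)))
        table = rate_association(rates, rates, tree)
        assert np.allclose(table["estimate"], 1.0)

    def test_independent_rates_mostly_uncorrelated(self):
        tree = gen_tree(100, seed=18)
        labels, _ = tree_tmrca(tree)
        small = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            ra = dict(zip(labels, rng.lognormal(size=100)))
            rb = dict(zip(labels, rng.lognormal(size=100)))
            table = rate_association(ra, rb, tree=None, level="branch")
            r = table.loc[table.method == "pearson", "estimate"].iloc[0]
            small += abs(r) < 0.2
        assert small >= 0.9 * n_seeds

    def test_pic_correlation_consistent_with_contrasts(self):
        tree = gen_tree(30, seed=19)
        labels, _ = tree_tmrca(tree)
        rng = np.random.default_rng(19)
        ra = dict(zip(labels, rng.lognormal(size=30)))
        rb = dict(zip(labels, rng.lognormal(size=30)))
        table = rate_association(ra, rb, tree)
        ca = pic(ra, tree)
        cb = pic(rb, tree)
        expected = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
        got = table.loc[table.level == "pic", "estimate"].iloc[0]
        assert got == pytest.approx(expected)

    def test_disjoint_tables_error(self):
        with pytest.raises(ValueError, match="shared"):
            rate_association({"a": 1.0}, {"b": 2.0}, tree=None, level="branch")
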