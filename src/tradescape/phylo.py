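"""Phylogeny-aware statistics: trait-model fitting, PGLS, PIC, Mantel, pPCA.

Trees are `dendropy` objects read from newick.  Trait evolution models are
the standard trio for continuous characters:

* BM — Brownian motion; tip covariance is the shared root-to-MRCA path length;
* OU — Ornstein-Uhlenbeck with pull alpha toward an optimum, in its
  stationary form, which requires an ultrametric tree (non-ultrametric input
  is an error, not a silent approximation);
* EB — early burst, BM with rate decaying as exp(r*t), r <= 0.

Maximum likelihood profiles out the rate and root state analytically and
optimizes the single remaining shape parameter (alpha or r) numerically with
deterministic multi-start.  Model support is compared by AICc.  Branch-rate
tables produced by external variable-rates software are ingested and related
by correlation (raw, tip-level and PIC-transformed) and Mantel tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "load_tree",
    "tree_tmrca",
    "model_vcv",
    "fit_trait_model",
    "pgls",
    "pgls_design_comparison",
    "pic",
    "mantel",
    "ppca",
    "rate_association",
    "aicc",
]


def load_tree(path: str) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree has branches without lengths")
    return tree


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_tmrca(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Matrix of root-to-MRCA depths; diagonal holds root-to-tip distances."""
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = _tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [index[node.taxon.label]]
            M[node._tipset[0], node._tipset[0]] = node.root_distance
            continue
        children = node.child_nodes()
        depth = node.root_distance
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]._tipset:
                    for j in children[b]._tipset:
                        M[i, j] = M[j, i] = depth
        node._tipset = [i for c in children for i in c._tipset]
    return labels, M


def _is_ultrametric(M: np.ndarray, rtol: float = 1e-6) -> bool:
    depths = np.diag(M)
    return np.ptp(depths) <= rtol * max(depths.max(), 1e-12)


def model_vcv(tree: dendropy.Tree, model: str = "BM", params: Mapping[str, float] | None = None) -> tuple[list[str], np.ndarray]:
    """Unit-rate tip covariance matrix under BM, OU or EB.

    BM needs no parameter; OU needs ``alpha`` (> 0, ultrametric tree only,
    stationary covariance exp(-alpha*d_ij)/(2*alpha)); EB needs ``r`` (<= 0,
    branch lengths rescaled through (exp(r*t)-1)/r).
    """
    params = dict(params or {})
    labels, M = tree_tmrca(tree)
    if model == "BM":
        V = M.copy()
    elif model == "EB":
        r = float(params.get("r", 0.0))
        if r > 0:
            raise ValueError("EB rate parameter r must be <= 0")
        V = M.copy() if abs(r) < 1e-12 else np.expm1(r * M) / r
    elif model == "OU":
        alpha = float(params.get("alpha", 0.0))
        if alpha <= 0:
            raise ValueError("OU requires alpha > 0")
        if not _is_ultrametric(M):
            raise ValueError("stationary OU covariance requires an ultrametric tree")
        depths = np.diag(M)
        d = depths[:, None] + depths[None, :] - 2.0 * M  # patristic distances
        V = np.exp(-alpha * d) / (2.0 * alpha)
    else:
        raise ValueError(f"unknown model {model!r}")
    return labels, V


def _mvn_profile_loglik(y: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """Profile ML over rate and root state: returns (loglik, sigma2_hat, root_hat)."""
    n = len(y)
    L = np.linalg.cholesky(V)
    ones = np.ones(n)
    wy = np.linalg.solve(L, y)
    w1 = np.linalg.solve(L, ones)
    mu = float(w1 @ wy / (w1 @ w1))
    resid = wy - mu * w1
    sigma2 = float(resid @ resid / n)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, sigma2, mu


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2LL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("n too small for AICc")
    return -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class TraitModelFit:
    model: str
    params: dict
    loglik: float
    aicc: float
    converged: bool = True
    message: str = ""


def fit_trait_model(trait: Mapping[str, float] | pd.Series, tree: dendropy.Tree, model: str = "BM") -> TraitModelFit:
    """ML fit of a univariate trait-evolution model with AICc.

    Free parameters: BM has (sigma2, root) -> k=2; OU adds alpha and EB adds
    r -> k=3.  The shape parameter is optimized by bounded L-BFGS-B from five
    deterministic starts spaning the bound range.
    """
    trait = pd.Series(dict(trait))
    labels, M = tree_tmrca(tree)
    if len(labels) < 4:
        raise ValueError("need at least 4 tips")
    missing = set(labels) - set(trait.index)
    if missing:
        raise ValueError(f"trait missing for tips: {sorted(missing)[:5]}")
    y = trait.loc[labels].to_numpy(float)
    depth = float(np.diag(M).max())

    if model == "BM":
        ll, s2, mu = _mvn_profile_loglik(y, M)
        return TraitModelFit("BM", {"sigma2": s2, "root": mu}, ll, aicc(ll, 2, len(y)))

    if model == "OU":
        if not _is_ultrametric(M):
            raise ValueError("OU fitting requires an ultrametric tree")
        lo, hi = 1e-8, 50.0 / depth

        def neg_ll(theta):
            alpha = float(theta[0])
            depths = np.diag(M)
            d = depths[:, None] + depths[None, :] - 2.0 * M
            V = np.exp(-alpha * d) / (2.0 * alpha)
            try:
                return -_mvn_profile_loglik(y, V)[0]
            except np.linalg.LinAlgError:
                return 1e10

        param_name = "alpha"
    elif model == "EB":
        lo, hi = -10.0 / depth, -1e-10

        def neg_ll(theta):
            r = float(theta[0])
            V = np.expm1(r * M) / r
            try:
                return -_mvn_profile_loglik(y, V)[0]
            except np.linalg.LinAlgError:
                return 1e10

        param_name = "r"
    else:
        raise ValueError(f"unknown model {model!r}")

    starts = np.linspace(lo, hi, 7)[1:-1]
    best = None
    ok = False
    for x0 in starts:
        res = optimize.minimize(neg_ll, [x0], method="L-BFGS-B", bounds=[(lo, hi)])
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    theta = float(best.x[0])
    # rebuild V at the optimum to extract sigma2/root
    if model == "OU":
        depths = np.diag(M)
        d = depths[:, None] + depths[None, :] - 2.0 * M
        V = np.exp(-theta * d) / (2.0 * theta)
    else:
        V = np.expm1(theta * M) / theta
    ll, s2, mu = _mvn_profile_loglik(y, V)
    params = {param_name: theta, "sigma2": s2, "root": mu}
    return TraitModelFit(model, params, ll, aicc(ll, 3, len(y)), converged=ok, message=best.message if not ok else "")


# ---------------------------------------------------------------------------
# PGLS


@dataclass
class PGLSResult:
    coefficients: np.ndarray
    r2: float
    p: float
    loglik: float
    aicc: float
    n_perm: int


def _as_matrix(a) -> np.ndarray:
    x = np.asarray(a, float)
    return x[:, None] if x.ndim == 1 else x


def pgls(
    response,
    predictors,
    tree: dendropy.Tree | None = None,
    vcv: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
    add_intercept: bool = True,
) -> PGLSResult:
    """GLS regression under a BM correlation structure with permutation p.

    The response may be uni- or multivariate (r-squared then pools sums of
    squares over columns).  Significance is by seeded permutation of the
    phylogenetically whitened residuals of the intercept-only null model.
    Rows must be ordered to match the tree's tip order when ``vcv`` is not
    supplied.
    """
    y = _as_matrix(response)
    X = _as_matrix(predictors)
    if vcv is None:
        if tree is None:
            raise ValueError("provide a tree or a vcv matrix")
        _, vcv = model_vcv(tree, "BM")
    n = y.shape[0]
    if vcv.shape != (n, n):
        raise ValueError("vcv size does not match the data")
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    L = np.linalg.cholesky(vcv)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
        raise ValueError("singular design")
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    onew = np.linalg.solve(L, np.ones((n, 1)))
    mu0, *_ = np.linalg.lstsq(onew, yw, rcond=None)
    resid0 = yw - onew @ mu0
    rss = float((resid**2).sum())
    tss = float((resid0**2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0

    # ML loglik (multivariate responses pool an isotropic sigma2)
    sigma2 = rss / (n * y.shape[1])
    logdet = 2.0 * np.log(np.diag(L)).sum() * y.shape[1]
    ll = -0.5 * (n * y.shape[1] * np.log(2 * np.pi * sigma2) + logdet + n * y.shape[1])
    k = X.shape[1] + 1
    ic = aicc(ll, k, n)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = onew @ mu0 + resid0[rng.permutation(n)]
        bp, *_ = np.linalg.lstsq(Xw, yp, rcond=None)
        rp = 1.0 - float(((yp - Xw @ bp) ** 2).sum()) / float(((yp - onew @ mu0) ** 2).sum())
        if rp >= r2 - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PGLSResult(beta, r2, p, ll, ic, n_perm)


def pgls_design_comparison(response, predictor, tree=None, vcv=None, n_perm: int = 0, seed: int = 0) -> pd.DataFrame:
    """AICc comparison of intercept-only, linear and quadratic PGLS designs."""
    x = np.asarray(predictor, float).ravel()
    n = len(x)
    designs = {
        "intercept": np.empty((n, 0)),
        "linear": x[:, None],
        "quadratic": np.column_stack([x, x**2]),
    }
    rows = []
    for name, X in designs.items():
        fit = pgls(response, X, tree=tree, vcv=vcv, n_perm=max(n_perm, 1), seed=seed)
        rows.append({"design": name, "aicc": fit.aicc, "r2": fit.r2, "loglik": fit.loglik,
                     "p": fit.p if n_perm > 0 else np.nan})
    return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)


# ---------------------------------------------------------------------------
# PIC, Mantel, pPCA, rate associations


def pic(trait: Mapping[str, float] | pd.Series, tree: dendropy.Tree) -> np.ndarray:
    """Standardized phylogenetic independent contrasts (pruning recursion).

    Polytomies are resolved arbitrarily with zero-length branches first (a
    standard, logged convention); returns n_tips - 1 contrasts in postorder.
    """
    trait = pd.Series(dict(trait))
    work = tree.clone(depth=1)
    work.resolve_polytomies()
    contrasts = []
    for node in work.postorder_node_iter():
        if node.is_leaf():
            node._val = float(trait[node.taxon.label])
            node._len = float(node.edge.length or 0.0)
            continue
        c1, c2 = node.child_nodes()
        v1, v2 = c1._len, c2._len
        contrasts.append((c1._val - c2._val) / np.sqrt(v1 + v2))
        node._val = (c1._val / v1 + c2._val / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 else 0.5 * (c1._val + c2._val)
        extra = v1 * v2 / (v1 + v2) if v1 + v2 > 0 else 0.0
        node._len = float(node.edge.length or 0.0) + extra
    return np.array(contrasts)


def mantel(d1: np.ndarray, d2: np.ndarray, n_perm: int = 999, seed: int = 0, alternative: str = "greater") -> dict:
    """Mantel test with the unnormalized cross-product statistic.

    Z = sum over i<j of d1_ij * d2_ij; the p-value permutes the labels of the
    second matrix (rows and columns together).
    """
    A = np.asarray(d1, float)
    B = np.asarray(d2, float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    z = float((A[iu] * B[iu]).sum())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        zp = float((A[iu] * B[p][:, p][iu]).sum())
        if alternative == "greater":
            count += zp >= z - 1e-12
        elif alternative == "less":
            count += zp <= z + 1e-12
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
    return {"z": z, "p": (count + 1) / (n_perm + 1), "n_perm": n_perm}


def ppca(trait_matrix: pd.DataFrame | np.ndarray, tree: dendropy.Tree) -> dict:
    """Phylogenetic PCA: eigen-decomposition of the BM-weighted covariance.

    Scores are computed on data centered at the phylogenetic (GLS) mean.  On
    a star tree this reduces to ordinary PCA of the centered data.
    """
    if isinstance(trait_matrix, pd.DataFrame):
        labels, V = model_vcv(tree, "BM")
        X = trait_matrix.loc[labels].to_numpy(float)
    else:
        labels, V = model_vcv(tree, "BM")
        X = np.asarray(trait_matrix, float)
    n = X.shape[0]
    Vi = np.linalg.inv(V)
    ones = np.ones((n, 1))
    a = np.linalg.solve(ones.T @ Vi @ ones, ones.T @ Vi @ X)  # phylogenetic mean
    Xc = X - a
    C = Xc.T @ Vi @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    return {"eigenvalues": evals, "eigenvectors": evecs, "scores": Xc @ evecs, "mean": a.ravel(), "labels": labels}


def _corr_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))


def rate_association(
    ratesA: pd.Series | Mapping[str, float],
    ratesB: pd.Series | Mapping[str, float],
    tree: dendropy.Tree | None = None,
    level: str = "tip",
) -> pd.DataFrame:
    """Correlations between two rate tables (e.g. shape vs trade-off rates).

    At ``level='tip'`` with a tree, also reports the correlation of
    PIC-transformed tip rates using the through-origin convention for
    contrasts.  At ``level='branch'`` only raw Pearson/Spearman are reported.
    """
    a = pd.Series(dict(ratesA))
    b = pd.Series(dict(ratesB))
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared identifiers between rate tables")
    x, y = a.loc[shared].to_numpy(float), b.loc[shared].to_numpy(float)
    rows = []
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    rows.append({"level": level, "method": "pearson", "estimate": pr.statistic, "p": pr.pvalue})
    rows.append({"level": level, "method": "spearman", "estimate": sr.statistic, "p": sr.pvalue})
    if level == "tip" and tree is not None:
        ca = pic(a.loc[shared], tree)
        cb = pic(b.loc[shared], tree)
        r = _corr_through_origin(ca, cb)
        nc = len(ca)
        t = r * np.sqrt(max(nc - 1, 1) / max(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(abs(t), max(nc - 1, 1))
        rows.append({"level": "pic", "method": "pearson_origin", "estimate": r, "p": p})
    return pd.DataFrame(rows)
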