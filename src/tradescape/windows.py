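"""Sliding-window analysis of trade-off weight vs. morphological disparity.

Overlapping windows slide along the trade-off weight axis.  Per window the
analysis reports (i) the "weight-w volume": how many cells of a dense
w-surface fall in the window — a measure of how much theoretical shape space
supports that functional balance — and (ii) the observed disparity of the
real species whose w falls in the window.  Because similar w values can occur
in distant regions of the morphospace, species in a window are first
clustered on their 2D landscape positions (Gaussian mixtures, BIC-selected K)
and disparity — the multivariate variance, i.e. the trace of the sample
covariance of the FULL shape variables — is summed across clusters, which
removes the between-cluster component that would otherwise inflate it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "WindowSpec",
    "WindowResult",
    "make_windows",
    "w_volume",
    "multivariate_variance",
    "cluster_positions",
    "windowed_disparity",
    "association",
    "xi_coefficient",
]

_EPS = 1e-12


@dataclass
class WindowSpec:
    start: float
    size: float = 0.011
    step: float = 0.0002

    @property
    def stop(self) -> float:
        return self.start + self.size

    @property
    def center(self) -> float:
        return self.start + 0.5 * self.size


def make_windows(w_min: float, w_max: float, step: float = 0.0002, size: float = 0.011) -> list[WindowSpec]:
    """Consecutive overlapping windows: starts w_min, w_min+step, ... while start+size <= w_max."""
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if w_max - w_min < size - _EPS:
        raise ValueError("range smaller than one window")
    count = int(np.floor((w_max - w_min - size + _EPS) / step)) + 1
    return [WindowSpec(start=w_min + i * step, size=size, step=step) for i in range(count)]


def w_volume(w_grid_values: np.ndarray, window: WindowSpec) -> int:
    """Count of w-surface cells with w in [start, start+size) (half-open)."""
    w = np.asarray(w_grid_values, float).ravel()
    return int(np.sum((w >= window.start) & (w < window.stop)))


def multivariate_variance(data_matrix: np.ndarray) -> float:
    """Sum of per-column unbiased variances = trace of the sample covariance."""
    x = np.atleast_2d(np.asarray(data_matrix, float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    return float(x.var(axis=0, ddof=1).sum())


def cluster_positions(points_2d: np.ndarray, max_k: int = 5, seed: int = 0) -> np.ndarray:
    """BIC-selected Gaussian-mixture clustering of 2D landscape positions.

    Fits full-covariance mixtures for K = 1..min(max_k, n-1) with seeded
    initialization and keeps the K with the lowest BIC.  The covariance
    diagonal is regularized by 1e-6 plus 1e-3 of the mean coordinate
    variance: the absolute term absorbs identical-point degeneracies, the
    relative term keeps two- and three-point components from collapsing onto
    near-singular covariances (whose inflated likelihood would otherwise let
    BIC split clean clusters) at any coordinate scale.
    """
    x = np.asarray(points_2d, float)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need at least 2 two-dimensional points")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    reg = 1e-6 + 1e-3 * float(x.var(axis=0).mean())
    best_labels, best_bic = None, np.inf
    for k in range(1, min(max_k, len(x) - 1) + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", reg_covar=reg,
            random_state=seed, n_init=3, max_iter=200,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic, best_labels = bic, gm.predict(x)
    return best_labels


@dataclass
class WindowResult:
    w_center: float
    volume: int
    n_species: int
    n_clusters: int
    disparity: float  # NaN when fewer than 2 species fall in the window


def windowed_disparity(
    species_w: np.ndarray,
    species_positions_2d: np.ndarray,
    species_shapes: np.ndarray,
    windows: list[WindowSpec],
    w_grid_values: np.ndarray,
    seed: int = 0,
    max_k: int = 5,
) -> pd.DataFrame:
    """Per-window volume and cluster-summed observed disparity.

    ``species_w``, ``species_positions_2d`` (n x 2) and ``species_shapes``
    (n x p full shape variables) must be row-aligned.  Windows with fewer
    than two species get NaN disparity; clusters of size one contribute 0.
    """
    w = np.asarray(species_w, float).ravel()
    pos = np.asarray(species_positions_2d, float)
    shapes = np.asarray(species_shapes, float)
    if not (len(w) == len(pos) == len(shapes)):
        raise ValueError("misaligned species tables")

    rows = []
    for win in windows:
        inside = (w >= win.start) & (w < win.stop)
        n_sp = int(inside.sum())
        vol = w_volume(w_grid_values, win)
        if n_sp < 2:
            rows.append(WindowResult(win.center, vol, n_sp, n_clusters=n_sp, disparity=np.nan))
            continue
        labels = cluster_positions(pos[inside], max_k=max_k, seed=seed)
        disp = 0.0
        for lab in np.unique(labels):
            members = shapes[inside][labels == lab]
            if len(members) >= 2:
                disp += multivariate_variance(members)
        rows.append(WindowResult(win.center, vol, n_sp, int(len(np.unique(labels))), disp))
    return pd.DataFrame([r.__dict__ for r in rows])


def xi_coefficient(x: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[float, float]:
    """Rank-based dependence coefficient xi with its asymptotic p-value.

    Sort by x (ties broken uniformly at random with ``seed``), take ranks
    r_i = #{j : y_j <= y_i}, and compute 1 - 3*sum|r_{i+1} - r_i| / (n^2-1).
    Under independence sqrt(n)*xi is asymptotically N(0, 2/5) (continuous y);
    the p-value is right-tailed, xi being a measure of dependence strength.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need equal-length vectors with n >= 3")
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(n)
    order = np.lexsort((jitter, x))
    y_sorted = y[order]
    ranks = np.array([np.sum(y <= yi) for yi in y_sorted], dtype=float)
    xi = 1.0 - 3.0 * np.abs(np.diff(ranks)).sum() / (n**2 - 1)
    p = float(stats.norm.sf(xi * np.sqrt(n / 0.4)))
    return float(xi), p


def association(x: np.ndarray, y: np.ndarray, seed: int = 0) -> dict:
    """Pearson r, Spearman rho and xi between two profiles, with p-values.

    Pairs where either value is NaN (e.g. undefined window disparity) are
    dropped before computing any coefficient.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    xi, xi_p = xi_coefficient(x, y, seed=seed)
    return {
        "n": int(len(x)),
        "pearson": {"r": float(pearson.statistic), "p": float(pearson.pvalue)},
        "spearman": {"rho": float(spearman.statistic), "p": float(spearman.pvalue)},
        "xi": {"xi": xi, "p": xi_p},
    }
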