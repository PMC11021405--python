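"""Performance surfaces over the (PC1, PC2) morphospace plane.

A performance surface maps a morphospace position to a scalar functional
metric (here: bite-force and bite-velocity proxies, each min-max scaled to
[0, 1]).  Three surface families are supported:

* ``polynomial`` — bivariate least-squares polynomials, degree 1-5;
* ``tps``        — thin-plate splines (kernel r^2 log r) with polynomial
                   drift; "order" d means drift degree d-1, so order 2 has a
                   linear drift.  Smoothing is chosen by generalized
                   cross-validation (GCV) unless given explicitly;
* ``kriging``    — ordinary kriging with a variogram model (spherical,
                   exponential or Gaussian) fitted to the empirical
                   semivariogram by weighted least squares.

Candidates are compared by k-fold cross-validated RMSE; predictions are not
clipped, so values slightly outside [0, 1] can occur away from the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

__all__ = [
    "SurfaceModel",
    "CVReport",
    "trim_top_fraction_mean",
    "scale_unit_interval",
    "fit_surface",
    "predict_surface",
    "crossvalidate_surfaces",
    "default_candidates",
]

KRIGING_VARIOGRAMS = ("spherical", "exponential", "gaussian")


def trim_top_fraction_mean(values: Sequence[float], fraction: float = 0.02) -> float:
    """Mean after discarding the ceil(fraction*n) largest values.

    Used to summarise per-element stress fields while excluding artificially
    extreme values at constraint and loading points.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    n_drop = int(np.ceil(fraction * v.size))
    if n_drop == 0:
        return float(v.mean())
    kept = np.sort(v)[: v.size - n_drop]
    return float(kept.mean())


def scale_unit_interval(values: Sequence[float]) -> np.ndarray:
    """Min-max scale to [0, 1]: (v - min) / (max - min)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("constant vector: unit-interval scaling undefined")
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# polynomial surfaces


def _poly_design(xy: np.ndarray, degree: int) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    cols = [x**i * y**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.column_stack(cols)


def _poly_n_params(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


# ---------------------------------------------------------------------------
# thin-plate splines


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        k = r * r * np.log(r)
    return np.where(r > 0, k, 0.0)


class _TPSFit:
    """Thin-plate spline with polynomial drift and quadratic penalty.

    Solves the standard augmented system; with ``smoothing=None`` the penalty
    weight is chosen by minimizing the GCV score over a log-spaced grid.  The
    GCV trace term is computed exactly through an eigendecomposition of the
    kernel reduced to the complement of the drift space.
    """

    def __init__(self, xy: np.ndarray, z: np.ndarray, drift_degree: int, smoothing: float | None):
        self.xy = np.asarray(xy, float)
        z = np.asarray(z, float).ravel()
        n = len(z)
        P = _poly_design(self.xy, drift_degree)
        m = P.shape[1]
        if n <= m:
            raise ValueError("too few points for the requested drift degree")
        K = _tps_kernel(cdist(self.xy, self.xy))
        q, _ = np.linalg.qr(P, mode="complete")
        Q2 = q[:, m:]
        B = Q2.T @ K @ Q2
        B = 0.5 * (B + B.T)
        evals, evecs = np.linalg.eigh(B)
        zproj = evecs.T @ (Q2.T @ z)

        if smoothing is None:
            scale = max(np.abs(evals).max(), 1e-12)
            lams = np.concatenate([[0.0], np.logspace(-10, 2, 40) * scale])
            best, best_gcv = 0.0, np.inf
            for lam in lams[1:]:
                denom = evals + lam
                if np.any(denom <= 0):
                    continue
                rss = float(np.sum((lam * zproj / denom) ** 2))
                tr = n - float(np.sum(lam / denom))
                if n - tr <= 0:
                    continue
                gcv = n * rss / (n - tr) ** 2
                if gcv < best_gcv:
                    best_gcv, best = gcv, lam
            smoothing = best
        self.smoothing = float(smoothing)

        lam = self.smoothing
        denom = evals + lam
        if np.any(denom <= 0):
            raise ValueError("TPS system not positive definite (duplicate points?)")
        c = Q2 @ (evecs @ (zproj / denom))
        # drift coefficients from the least-squares residual of z - (K+lam I)c
        b, *_ = np.linalg.lstsq(P, z - (K + lam * np.eye(n)) @ c, rcond=None)
        self.coef_rbf = c
        self.coef_drift = b
        self.drift_degree = drift_degree

    def predict(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        K = _tps_kernel(cdist(xy, self.xy))
        return K @ self.coef_rbf + _poly_design(xy, self.drift_degree) @ self.coef_drift


# ---------------------------------------------------------------------------
# ordinary kriging


def _variogram_model(name: str, h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    h = np.asarray(h, float)
    rng = max(rng, 1e-12)
    if name == "spherical":
        ratio = np.clip(h / rng, 0, 1)
        g = psill * (1.5 * ratio - 0.5 * ratio**3)
    elif name == "exponential":
        g = psill * (1.0 - np.exp(-3.0 * h / rng))
    elif name == "gaussian":
        g = psill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))
    else:
        raise ValueError(f"unknown variogram model {name!r}")
    return np.where(h > 0, nugget + g, 0.0)


class _KrigingFit:
    """Ordinary kriging with a WLS-fitted variogram.

    The empirical semivariogram is binned up to half the maximum pairwise
    distance; candidate variogram families are fitted by weighted least
    squares (weights N_h / h^2, the automatic-variogram convention) and the
    family with the lowest weighted SSE is kept.
    """

    def __init__(self, xy: np.ndarray, z: np.ndarray, n_bins: int = 12):
        self.xy = np.asarray(xy, float)
        self.z = np.asarray(z, float).ravel()
        d = cdist(self.xy, self.xy)
        iu = np.triu_indices(len(self.z), k=1)
        h, gamma = d[iu], 0.5 * (self.z[iu[0]] - self.z[iu[1]]) ** 2
        hmax = h.max() * 0.5
        edges = np.linspace(0, hmax, n_bins + 1)
        centers, means, counts = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (h > lo) & (h <= hi)
            if sel.sum() > 0:
                centers.append(h[sel].mean())
                means.append(gamma[sel].mean())
                counts.append(sel.sum())
        hc, gc, nc = np.array(centers), np.array(means), np.array(counts)

        best = None
        var_z = self.z.var()
        for name in KRIGING_VARIOGRAMS:
            x0 = np.array([1e-6, max(var_z, 1e-9), max(hc.max() * 0.5, 1e-6)])

            def resid(p, name=name):
                w = np.sqrt(nc) / np.maximum(hc, 1e-12)
                return w * (_variogram_model(name, hc, *np.abs(p)) - gc)

            sol = least_squares(resid, x0, method="lm", max_nfev=2000)
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0]:
                best = (sse, name, np.abs(sol.x))
        self.variogram, self.params = best[1], best[2]

        n = len(self.z)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = _variogram_model(self.variogram, d, *self.params)
        A[n, :n] = 1.0
        A[:n, n] = 1.0
        A[n, n] = 0.0
        # tiny jitter keeps the system solvable when the nugget fit is ~0
        A[:n, :n] += np.eye(n) * 1e-10
        self._lu = np.linalg.inv(A)

    def predict(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        g = _variogram_model(self.variogram, cdist(xy, self.xy), *self.params)
        rhs = np.column_stack([g, np.ones(len(xy))])
        lam = rhs @ self._lu.T
        return lam[:, : len(self.z)] @ self.z


# ---------------------------------------------------------------------------
# public surface API


@dataclass
class SurfaceModel:
    """A fitted z = f(PC1, PC2) performance surface."""

    family: str  # polynomial | tps | kriging
    order: int
    training_rmse: float = np.nan
    _impl: object = field(default=None, repr=False, compare=False)
    coefficients: np.ndarray | None = None  # polynomial only

    def predict(self, positions: np.ndarray) -> np.ndarray:
        return predict_surface(self, positions)

    def n_params(self) -> int:
        if self.family == "polynomial":
            return _poly_n_params(self.order)
        if self.family == "tps":
            return _poly_n_params(self.order - 1) + 1  # drift + smoothing
        return 3  # variogram nugget/sill/range

    def to_json(self) -> str:
        payload = {"family": self.family, "order": self.order, "training_rmse": self.training_rmse}
        if self.family == "polynomial":
            payload["coefficients"] = self.coefficients.tolist()
        elif self.family == "tps":
            impl: _TPSFit = self._impl
            payload.update(
                xy=impl.xy.tolist(), coef_rbf=impl.coef_rbf.tolist(),
                coef_drift=impl.coef_drift.tolist(), smoothing=impl.smoothing,
            )
        else:
            impl: _KrigingFit = self._impl
            payload.update(
                xy=impl.xy.tolist(), z=impl.z.tolist(),
                variogram=impl.variogram, params=impl.params.tolist(),
            )
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SurfaceModel":
        d = json.loads(text)
        model = cls(family=d["family"], order=d["order"], training_rmse=d["training_rmse"])
        if model.family == "polynomial":
            model.coefficients = np.asarray(d["coefficients"])
        elif model.family == "tps":
            impl = _TPSFit.__new__(_TPSFit)
            impl.xy = np.asarray(d["xy"])
            impl.coef_rbf = np.asarray(d["coef_rbf"])
            impl.coef_drift = np.asarray(d["coef_drift"])
            impl.smoothing = d["smoothing"]
            impl.drift_degree = model.order - 1
            model._impl = impl
        else:
            model._impl = _KrigingFit(np.asarray(d["xy"]), np.asarray(d["z"]))
        return model


def fit_surface(
    positions: np.ndarray,
    values: Sequence[float],
    family: str,
    order: int = 1,
    tps_smoothing: float | None = None,
) -> SurfaceModel:
    """Fit one candidate surface.

    polynomial: ``order`` is the total degree (1-5).
    tps: ``order`` in 2-4 maps to drift degree ``order - 1``; ``tps_smoothing``
    of None selects the penalty by GCV, 0 interpolates.
    kriging: ``order`` is ignored (variogram family chosen internally).
    """
    xy = np.asarray(positions, float)
    z = np.asarray(values, float).ravel()
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    if len(z) != len(xy):
        raise ValueError("positions and values length mismatch")

    if family == "polynomial":
        if not 1 <= order <= 5:
            raise ValueError("polynomial degree must be 1-5")
        X = _poly_design(xy, order)
        if len(z) < X.shape[1]:
            raise ValueError("too few points for polynomial degree")
        coef, *_ = np.linalg.lstsq(X, z, rcond=None)
        model = SurfaceModel(family="polynomial", order=order, coefficients=coef)
        fitted = X @ coef
    elif family == "tps":
        if not 2 <= order <= 4:
            raise ValueError("TPS order must be 2-4")
        impl = _TPSFit(xy, z, drift_degree=order - 1, smoothing=tps_smoothing)
        model = SurfaceModel(family="tps", order=order, _impl=impl)
        fitted = impl.predict(xy)
    elif family == "kriging":
        impl = _KrigingFit(xy, z)
        model = SurfaceModel(family="kriging", order=order, _impl=impl)
        fitted = impl.predict(xy)
    else:
        raise ValueError(f"unknown surface family {family!r}")

    model.training_rmse = float(np.sqrt(np.mean((fitted - z) ** 2)))
    return model


def predict_surface(model: SurfaceModel, positions: np.ndarray) -> np.ndarray:
    """Evaluate a fitted surface; values are not clipped to [0, 1]."""
    xy = np.atleast_2d(np.asarray(positions, float))
    if model.family == "polynomial":
        if model.coefficients is None:
            raise ValueError("unfitted polynomial model")
        return _poly_design(xy, model.order) @ model.coefficients
    if model._impl is None:
        raise ValueError("unfitted model")
    return model._impl.predict(xy)


@dataclass
class CVReport:
    """Cross-validation summary over candidate surface families."""

    candidates: list[tuple[str, int]]
    rmse: np.ndarray
    folds: int
    seed: int
    best: tuple[str, int]
    failed: list[tuple[str, int]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "folds": self.folds,
            "seed": self.seed,
            "best": list(self.best),
            "candidates": [
                {"family": f, "order": o, "rmse": float(r)}
                for (f, o), r in zip(self.candidates, self.rmse)
            ],
            "failed": [list(c) for c in self.failed],
        }


def default_candidates() -> list[tuple[str, int]]:
    """Polynomial degrees 1-5, TPS orders 2-4, ordinary kriging."""
    return [("polynomial", d) for d in range(1, 6)] + [("tps", o) for o in (2, 3, 4)] + [("kriging", 0)]


def crossvalidate_surfaces(
    positions: np.ndarray,
    values: Sequence[float],
    candidates: Sequence[tuple[str, int]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """k-fold cross-validated RMSE per candidate; best = argmin RMSE.

    The fold partition is a seeded random permutation shared by all
    candidates.  A candidate that cannot be fitted on some training fold is
    recorded in ``failed`` (with RMSE NaN), never silently dropped.  Ties in
    RMSE are broken toward the candidate with fewer free parameters.
    """
    xy = np.asarray(positions, float)
    z = np.asarray(values, float).ravel()
    n = len(z)
    if not (2 <= k <= n):
        raise ValueError("need n >= k >= 2")
    if candidates is None:
        candidates = default_candidates()
    candidates = [tuple(c) for c in candidates]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    rmse = np.full(len(candidates), np.nan)
    failed: list[tuple[str, int]] = []
    for ci, (family, order) in enumerate(candidates):
        sq_errors = []
        ok = True
        for test_idx in folds:
            train = np.setdiff1d(perm, test_idx)
            try:
                m = fit_surface(xy[train], z[train], family, order)
                pred = predict_surface(m, xy[test_idx])
            except Exception:
                ok = False
                break
            sq_errors.append((pred - z[test_idx]) ** 2)
        if ok:
            rmse[ci] = float(np.sqrt(np.concatenate(sq_errors).mean()))
        else:
            failed.append((family, order))

    if np.all(np.isnan(rmse)):
        raise ValueError("no candidate could be cross-validated")
    finite = np.where(np.isfinite(rmse))[0]
    best_rmse = rmse[finite].min()
    tied = [i for i in finite if rmse[i] <= best_rmse + 1e-15]
    n_par = [
        SurfaceModel(family=candidates[i][0], order=candidates[i][1]).n_params() for i in tied
    ]
    best = candidates[tied[int(np.argmin(n_par))]]
    return CVReport(candidates=candidates, rmse=rmse, folds=k, seed=seed, best=best, failed=failed)
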