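"""Two-block partial least squares between shape and function, with transfer.

The first pair of PLS axes maximizes the covariance between a shape block
(tangent coordinates) and a function block (two performance metrics, each
standardized to unit variance).  Following the transfer design, the model is
fitted on one clade only (groupA, the placental role); specimens of both
clades are then projected, their score pairs regressed through the major axis
of the training score cloud, and predicted shapes back-transformed.  The
residual distance between observed and predicted shape — Euclidean in
tangent space, which coincides with the Procrustes distance to first order —
measures how well the fitted form-function mapping transfers: if the other
clade (groupB, marsupial role) follows a different mapping, its residuals
should exceed the training clade's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PLSModel", "TransferResult", "fit_pls2b", "pls_scores", "major_axis_predict", "transfer_assessment"]


@dataclass
class PLSModel:
    shape_mean: np.ndarray
    func_mean: np.ndarray
    func_scale: np.ndarray  # per-metric standard deviations
    shape_axis: np.ndarray  # unit vector
    func_axis: np.ndarray  # unit vector
    singular_value: float
    major_axis: np.ndarray | None = None  # unit direction in (s_shape, s_func) space
    major_axis_point: np.ndarray | None = None  # a point on it (the score centroid)


def fit_pls2b(shape_block: np.ndarray, func_block: np.ndarray) -> PLSModel:
    """First singular triplet of the between-block cross-covariance.

    The function block is centered and scaled to unit variance per column;
    the shape block is centered only.  Sign convention: the first loading of
    the function axis is positive (both axes flip together, preserving the
    sign of the association).
    """
    X = np.asarray(shape_block, float)
    Y = np.asarray(func_block, float)
    n = X.shape[0]
    if n != Y.shape[0]:
        raise ValueError("blocks must have the same specimen count")
    if n < 3:
        raise ValueError("need at least 3 specimens")
    shape_mean = X.mean(axis=0)
    func_mean = Y.mean(axis=0)
    func_scale = Y.std(axis=0, ddof=1)
    if np.any(func_scale <= 0):
        raise ValueError("constant functional metric cannot be standardized")
    Xc = X - shape_mean
    Yc = (Y - func_mean) / func_scale
    cross = Xc.T @ Yc / (n - 1)
    u, s, vt = np.linalg.svd(cross, full_matrices=False)
    shape_axis, func_axis, sv = u[:, 0], vt[0], float(s[0])
    if func_axis[0] < 0:
        shape_axis, func_axis = -shape_axis, -func_axis
    model = PLSModel(
        shape_mean=shape_mean, func_mean=func_mean, func_scale=func_scale,
        shape_axis=shape_axis, func_axis=func_axis, singular_value=sv,
    )
    s1, s2 = pls_scores(model, X, Y)
    scores = np.column_stack([s1, s2])
    center = scores.mean(axis=0)
    cov = np.cov(scores.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise ValueError("degenerate score cloud (zero variance)")
    direction = evecs[:, -1]
    if direction[0] < 0:
        direction = -direction
    model.major_axis = direction
    model.major_axis_point = center
    return model


def pls_scores(model: PLSModel, shape_obs: np.ndarray, func_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project observations (original units) on the first axis pair."""
    X = np.atleast_2d(np.asarray(shape_obs, float))
    Y = np.atleast_2d(np.asarray(func_obs, float))
    if X.shape[1] != len(model.shape_mean) or Y.shape[1] != len(model.func_mean):
        raise ValueError("dimension mismatch with the fitted model")
    s_shape = (X - model.shape_mean) @ model.shape_axis
    s_func = ((Y - model.func_mean) / model.func_scale) @ model.func_axis
    return s_shape, s_func


def major_axis_predict(model: PLSModel, shape_obs: np.ndarray, func_obs: np.ndarray) -> np.ndarray:
    """Predicted shapes from the major-axis regression of the score pairs.

    Each observation's (shape score, function score) pair is orthogonally
    projected onto the major axis of the training score cloud; the projected
    shape-score coordinate is back-transformed through the shape axis.
    """
    if model.major_axis is None:
        raise ValueError("model has no major axis (unfitted)")
    s1, s2 = pls_scores(model, shape_obs, func_obs)
    pts = np.column_stack([s1, s2]) - model.major_axis_point
    t = pts @ model.major_axis
    proj = model.major_axis_point + np.outer(t, model.major_axis)
    return model.shape_mean + np.outer(proj[:, 0], model.shape_axis)


def _residual_distances(model: PLSModel, shape_obs: np.ndarray, func_obs: np.ndarray) -> np.ndarray:
    pred = major_axis_predict(model, shape_obs, func_obs)
    return np.linalg.norm(np.atleast_2d(shape_obs) - pred, axis=1)


@dataclass
class TransferResult:
    table: pd.DataFrame  # specimen, group, s_shape, s_func, residual_distance
    median_train: float
    median_transfer: float
    mannwhitney_u: float
    mannwhitney_p: float

    @property
    def median_ratio(self) -> float:
        """Transfer-group over training-group median residual distance."""
        return self.median_transfer / self.median_train


def transfer_assessment(
    model: PLSModel,
    groupA_shapes: np.ndarray,
    groupA_funcs: np.ndarray,
    groupB_shapes: np.ndarray,
    groupB_funcs: np.ndarray,
    groupA_ids: list[str] | None = None,
    groupB_ids: list[str] | None = None,
) -> TransferResult:
    """Residual shape distances for the training and transfer groups.

    ``model`` must have been fitted on groupA only.  Reports per-specimen
    scores and residual distances, per-group medians, and a two-sided
    Mann-Whitney rank comparison of the residual distributions (descriptive,
    not a gate: with a shared mapping the distributions should be similar).
    """
    A_sh, A_fn = np.atleast_2d(groupA_shapes), np.atleast_2d(groupA_funcs)
    B_sh, B_fn = np.atleast_2d(groupB_shapes), np.atleast_2d(groupB_funcs)
    if len(A_sh) == 0 or len(B_sh) == 0:
        raise ValueError("empty group")
    rows = []
    for grp, sh, fn, ids in (("groupA", A_sh, A_fn, groupA_ids), ("groupB", B_sh, B_fn, groupB_ids)):
        s1, s2 = pls_scores(model, sh, fn)
        res = _residual_distances(model, sh, fn)
        names = ids if ids is not None else [f"{grp}_{i}" for i in range(len(sh))]
        for i in range(len(sh)):
            rows.append({"specimen": names[i], "group": grp, "s_shape": s1[i], "s_func": s2[i], "residual_distance": res[i]})
    table = pd.DataFrame(rows)
    res_a = table.loc[table.group == "groupA", "residual_distance"]
    res_b = table.loc[table.group == "groupB", "residual_distance"]
    u = stats.mannwhitneyu(res_a, res_b, alternative="two-sided")
    return TransferResult(
        table=table,
        median_train=float(res_a.median()),
        median_transfer=float(res_b.median()),
        mannwhitney_u=float(u.statistic),
        mannwhitney_p=float(u.pvalue),
    )
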