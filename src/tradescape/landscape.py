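"""Combined functional landscapes and trade-off weight estimation.

Two scaled performance surfaces F1 and F2 (e.g. bite force and bite velocity)
are mixed into a combined landscape W(w) = w*F1 + (1-w)*F2.  For a specimen
at morphospace position z, its log "functional fitness" at a given mixing
weight w is

    ln [ w*F1(z) + (1-w)*F2(z) ] - ln max_grid [ w*F1 + (1-w)*F2 ]

i.e. log height relative to the highest point of the combined landscape at
that w, the maximum being recomputed for every w over a reference grid.  The
trade-off weight of the specimen is the w maximizing this quantity: w near 1
means the shape sits closest to the top of the force-dominated landscape, w
near 0 the velocity-dominated one.  The objective is piecewise-smooth and can
be multi-modal in w (the grid argmax switches cells), so estimation is by
exhaustive grid search over w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surfaces import SurfaceModel, predict_surface

__all__ = [
    "CombinedLandscape",
    "TradeoffEstimate",
    "WSurface",
    "combined_landscape",
    "log_fitness",
    "estimate_w",
    "estimate_w_from_values",
    "w_surface",
    "species_w",
]

_TIE_TOL = 1e-12


@dataclass
class CombinedLandscape:
    """A w-mixture of two performance grids: height = w*f1 + (1-w)*f2."""

    grid: np.ndarray  # (n_cells, 2)
    f1: np.ndarray
    f2: np.ndarray
    w: float
    height: np.ndarray


@dataclass
class TradeoffEstimate:
    """Estimated trade-off weight for one position."""

    w: float
    log_fitness: float
    tied: bool = False
    w_tie_set: tuple[float, float] | None = None  # (lo, hi) when tied


@dataclass
class WSurface:
    """Trade-off weight estimated over a dense morphospace grid."""

    grid: np.ndarray  # (n*n, 2)
    w: np.ndarray
    log_fitness: np.ndarray
    n_per_axis: int


def combined_landscape(f1_grid: np.ndarray, f2_grid: np.ndarray, w: float, grid: np.ndarray | None = None) -> CombinedLandscape:
    """Cell-wise mixture w*F1 + (1-w)*F2 of two congruent grids."""
    f1 = np.asarray(f1_grid, float)
    f2 = np.asarray(f2_grid, float)
    if f1.shape != f2.shape:
        raise ValueError("grid mismatch between F1 and F2")
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must be in [0, 1]")
    if grid is None:
        grid = np.empty((f1.size, 2)) * np.nan
    return CombinedLandscape(grid=grid, f1=f1, f2=f2, w=float(w), height=w * f1 + (1 - w) * f2)


def _objective_curve(
    f1_z: np.ndarray,
    f2_z: np.ndarray,
    f1_ref: np.ndarray,
    f2_ref: np.ndarray,
    w_values: np.ndarray,
    floor: float | None,
) -> np.ndarray:
    """Log-fitness for every (w, position) pair.

    Returns an array of shape (len(w_values), n_positions).  Raises if a
    combined value is non-positive and no floor is given: unclipped surfaces
    can dip below zero off-sample, in which case callers should either
    restrict the evaluation region or pass ``floor=1e-9``.
    """
    W = w_values[:, None]
    num = W * f1_z[None, :] + (1 - W) * f2_z[None, :]  # (k, P)
    den = (W * f1_ref[None, :] + (1 - W) * f2_ref[None, :]).max(axis=1)  # (k,)
    if floor is not None:
        num = np.maximum(num, floor)
        den = np.maximum(den, floor)
    elif np.any(num <= 0) or np.any(den <= 0):
        raise ValueError(
            "non-positive combined performance value; surface predictions are "
            "unclipped — pass floor=1e-9 to floor them, or restrict positions"
        )
    return np.log(num) - np.log(den)[:, None]


def log_fitness(
    position: np.ndarray,
    w: float,
    f1_model: SurfaceModel,
    f2_model: SurfaceModel,
    reference_grid: np.ndarray,
    floor: float | None = None,
) -> float:
    """Log height of ``position`` relative to the combined-landscape maximum at ``w``."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("w must be in [0, 1]")
    ref = np.asarray(reference_grid, float)
    if ref.size == 0:
        raise ValueError("empty reference grid")
    pos = np.atleast_2d(np.asarray(position, float))
    curve = _objective_curve(
        predict_surface(f1_model, pos),
        predict_surface(f2_model, pos),
        predict_surface(f1_model, ref),
        predict_surface(f2_model, ref),
        np.array([w]),
        floor,
    )
    return float(curve[0, 0])


def estimate_w_from_values(
    f1_z: np.ndarray,
    f2_z: np.ndarray,
    f1_ref: np.ndarray,
    f2_ref: np.ndarray,
    resolution: float = 0.001,
    floor: float | None = None,
) -> list[TradeoffEstimate]:
    """Grid-search w for each position given precomputed surface values.

    This is the computational core shared by :func:`estimate_w`,
    :func:`w_surface` and :func:`species_w`; it is fully vectorized over
    positions.  Ties in the maximal log-fitness (within 1e-12) are reported
    with ``tied=True`` and w at the midpoint of the tying set.
    """
    if not (0 < resolution <= 0.1):
        raise ValueError("resolution must be in (0, 0.1]")
    n_steps = int(round(1.0 / resolution))
    w_values = np.linspace(0.0, 1.0, n_steps + 1)
    curves = _objective_curve(
        np.asarray(f1_z, float).ravel(), np.asarray(f2_z, float).ravel(),
        np.asarray(f1_ref, float).ravel(), np.asarray(f2_ref, float).ravel(),
        w_values, floor,
    )
    out = []
    for j in range(curves.shape[1]):
        col = curves[:, j]
        top = col.max()
        tie = np.where(col >= top - _TIE_TOL)[0]
        if len(tie) > 1:
            lo, hi = w_values[tie[0]], w_values[tie[-1]]
            out.append(TradeoffEstimate(w=float(0.5 * (lo + hi)), log_fitness=float(top), tied=True, w_tie_set=(float(lo), float(hi))))
        else:
            out.append(TradeoffEstimate(w=float(w_values[tie[0]]), log_fitness=float(top)))
    return out


def estimate_w(
    position: np.ndarray,
    f1_model: SurfaceModel,
    f2_model: SurfaceModel,
    reference_grid: np.ndarray,
    resolution: float = 0.001,
    floor: float | None = None,
) -> TradeoffEstimate:
    """Trade-off weight of one morphospace position by exhaustive search."""
    pos = np.atleast_2d(np.asarray(position, float))
    ref = np.asarray(reference_grid, float)
    return estimate_w_from_values(
        predict_surface(f1_model, pos), predict_surface(f2_model, pos),
        predict_surface(f1_model, ref), predict_surface(f2_model, ref),
        resolution=resolution, floor=floor,
    )[0]


def _regular_grid(positions: np.ndarray, n: int) -> np.ndarray:
    pos = np.asarray(positions, float)
    ax1 = np.linspace(pos[:, 0].min(), pos[:, 0].max(), n)
    ax2 = np.linspace(pos[:, 1].min(), pos[:, 1].max(), n)
    g2, g1 = np.meshgrid(ax2, ax1, indexing="ij")
    return np.column_stack([g1.ravel(), g2.ravel()])


def w_surface(
    f1_model: SurfaceModel,
    f2_model: SurfaceModel,
    extent: np.ndarray,
    n: int = 40,
    resolution: float = 0.001,
    reference_grid: np.ndarray | None = None,
    floor: float | None = None,
) -> WSurface:
    """Estimate w on an n x n grid spanning the theoretical morphospace extent.

    ``extent`` is any set of positions (typically the theoretical grid) whose
    bounding box defines the surface domain.  ``reference_grid`` defaults to
    the n x n grid itself; pass the 8 x 8 theoretical grid to reproduce the
    species-level convention.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    grid = _regular_grid(np.asarray(extent, float), n)
    ref = grid if reference_grid is None else np.asarray(reference_grid, float)
    estimates = estimate_w_from_values(
        predict_surface(f1_model, grid), predict_surface(f2_model, grid),
        predict_surface(f1_model, ref), predict_surface(f2_model, ref),
        resolution=resolution, floor=floor,
    )
    return WSurface(
        grid=grid,
        w=np.array([e.w for e in estimates]),
        log_fitness=np.array([e.log_fitness for e in estimates]),
        n_per_axis=n,
    )


def species_w(
    species_positions: pd.DataFrame | np.ndarray,
    f1_model: SurfaceModel,
    f2_model: SurfaceModel,
    reference_grid: np.ndarray,
    resolution: float = 0.001,
    floor: float | None = None,
) -> pd.DataFrame:
    """Per-species trade-off weights from surface predictions at their positions.

    ``species_positions`` is either an (n, 2) array or a DataFrame with
    columns ``species``, ``pc1``, ``pc2``.  Returns a DataFrame with columns
    species, pc1, pc2, f1, f2, w, log_fitness, tied.
    """
    if isinstance(species_positions, pd.DataFrame):
        names = species_positions["species"].to_numpy()
        pos = species_positions[["pc1", "pc2"]].to_numpy(float)
    else:
        pos = np.asarray(species_positions, float)
        names = np.array([f"sp{i}" for i in range(len(pos))])
    ref = np.asarray(reference_grid, float)
    f1_z = predict_surface(f1_model, pos)
    f2_z = predict_surface(f2_model, pos)
    estimates = estimate_w_from_values(
        f1_z, f2_z, predict_surface(f1_model, ref), predict_surface(f2_model, ref),
        resolution=resolution, floor=floor,
    )
    return pd.DataFrame(
        {
            "species": names,
            "pc1": pos[:, 0],
            "pc2": pos[:, 1],
            "f1": f1_z,
            "f2": f2_z,
            "w": [e.w for e in estimates],
            "log_fitness": [e.log_fitness for e in estimates],
            "tied": [e.tied for e in estimates],
        }
    )
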