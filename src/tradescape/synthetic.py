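"""Synthetic studies with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-clade carnivore
cranium study: landmark configurations evolved by Brownian motion on a
pure-birth tree, two smooth performance functions over the first two PC axes
(sums of Gaussian peaks — one narrow "force" peak and one broad "velocity"
plateau by default, which yields the skewed, clustered trade-off-weight
distribution of the real system), observed with additive noise and min-max
scaled, and a designated subtree playing the transfer-clade (marsupial)
role.  The true trade-off weight of every species is computed by a
brute-force scan of the noiseless analytic surfaces, providing the oracle
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .shape import LandmarkConfiguration, gpa, pca_morphospace, theoretical_grid
from .surfaces import scale_unit_interval

__all__ = [
    "SurfaceSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "gen_tree",
    "gen_shapes_bm",
    "gen_performance",
    "oracle_w",
    "gen_study",
    "default_surface_spec",
]


@dataclass
class SurfaceSpec:
    """Two analytic performance functions as Gaussian-peak mixtures.

    Centers and widths are expressed in relative coordinates of the
    theoretical-grid bounding box ([0,1] per axis), so the same spec works
    for any morphospace scale; they are converted to PC units when evaluated
    against a concrete grid.
    """

    f1_centers: tuple = ((0.92, 0.88), (0.62, 0.55), (0.35, 0.40))
    f1_widths: tuple = (0.18, 0.18, 0.25)
    f1_heights: tuple = (1.0, 0.55, 0.50)
    f2_centers: tuple = ((0.02, 0.02), (0.15, 0.35), (0.50, 0.05), (0.30, 0.60), (0.62, 0.55))
    f2_widths: tuple = (0.15, 0.50, 0.22, 0.22, 0.20)
    f2_heights: tuple = (1.0, 0.90, 0.55, 0.60, 0.70)

    def _eval(self, positions: np.ndarray, bounds: np.ndarray, centers, widths, heights) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(positions, float))
        lo, span = bounds[0], bounds[1] - bounds[0]
        z = np.zeros(len(pos))
        for (cx, cy), sw, h in zip(centers, widths, heights):
            c = lo + span * np.array([cx, cy])
            s = sw * span.mean()
            d2 = ((pos - c) ** 2).sum(axis=1)
            z += h * np.exp(-d2 / (2.0 * s**2))
        return z

    def f1(self, positions: np.ndarray, bounds: np.ndarray) -> np.ndarray:
        return self._eval(positions, bounds, self.f1_centers, self.f1_widths, self.f1_heights)

    def f2(self, positions: np.ndarray, bounds: np.ndarray) -> np.ndarray:
        return self._eval(positions, bounds, self.f2_centers, self.f2_widths, self.f2_heights)


def default_surface_spec() -> SurfaceSpec:
    """Default performance geometry emulating the force-velocity system.

    Force (F1): a narrow peak just outside the occupied morphospace corner,
    plus two modest "generalist" components.  Velocity (F2): a very local
    specialist spike in the opposite corner over a broad, multi-lobed
    plateau, so most of the map is velocity-leaning.  This plants the
    study-like asymmetry: a small force-dominated basin (few shapes, high
    trade-off weight w) against a wide velocity region (many shapes, low w),
    with trade-off weights clustering at a few interior values.
    """
    return SurfaceSpec()


@dataclass
class SyntheticConfig:
    n_tips: int = 100
    n_landmarks: int = 35
    bm_rate: float = 0.0005
    surface_spec: SurfaceSpec = field(default_factory=default_surface_spec)
    noise_sd: float = 0.01
    clade_split: float = 0.75  # fraction of tips in groupA (model-fitting clade)
    grid_n: int = 8
    grid_extension: float = 0.10
    seed: int = 0


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    tree: dendropy.Tree
    landmarks: list[LandmarkConfiguration]
    alignment: object
    morphospace: object
    grid: np.ndarray  # theoretical grid positions (grid_n^2, 2)
    grid_bounds: np.ndarray  # 2x2: [[lo1, lo2], [hi1, hi2]]
    f1_noiseless: np.ndarray  # analytic values at grid, min-max scaled
    f2_noiseless: np.ndarray
    f1_values: np.ndarray  # noisy observed values at grid, min-max scaled
    f2_values: np.ndarray
    species_positions: pd.DataFrame  # species, pc1, pc2, clade
    true_w: pd.Series


def gen_tree(n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree scaled to unit depth.

    Lineages split at exponential waiting times (rate proportional to the
    number of alive lineages); surviving lineages are extended to the final
    time, and all branch lengths are divided by the tree depth.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    # each node is a dict: leaves have no "children"; internal nodes record
    # the time at which they split
    root = {"birth": 0.0, "split": 0.0}
    first = [{"birth": 0.0, "label": "t1"}, {"birth": 0.0, "label": "t2"}]
    root["children"] = first
    alive = list(first)
    t = 0.0
    next_label = 3
    while len(alive) < n_tips:
        t += rng.exponential(1.0 / len(alive))
        i = int(rng.integers(len(alive)))
        node = alive.pop(i)
        kids = [
            {"birth": t, "label": node.pop("label")},
            {"birth": t, "label": f"t{next_label}"},
        ]
        node["split"] = t
        node["children"] = kids
        next_label += 1
        alive[i:i] = kids
    t_end = t + rng.exponential(1.0 / len(alive))

    def render(node, parent_time: float) -> str:
        if "children" in node:
            inner = ",".join(render(c, node["split"]) for c in node["children"])
            return f"({inner}):{(node['split'] - parent_time) / t_end:.12f}"
        return f"{node['label']}:{(t_end - parent_time) / t_end:.12f}"

    newick = f"({render(first[0], 0.0)},{render(first[1], 0.0)});"
    return dendropy.Tree.get(data=newick, schema="newick")


def _base_configuration(n_landmarks: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0, size=(n_landmarks, 3))


def gen_shapes_bm(
    tree: dendropy.Tree,
    base_config: np.ndarray,
    bm_rate: float,
    seed: int = 0,
) -> list[LandmarkConfiguration]:
    """Evolve each landmark coordinate as independent BM along the tree."""
    if bm_rate < 0:
        raise ValueError("bm_rate must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.asarray(base_config, float)
    flat_dim = base.size
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node._state = base.reshape(-1)
        else:
            bl = float(node.edge.length or 0.0)
            step = rng.normal(0.0, np.sqrt(bm_rate * bl), size=flat_dim) if bm_rate * bl > 0 else 0.0
            node._state = node.parent_node._state + step
        if node.is_leaf():
            out.append(LandmarkConfiguration(node._state.reshape(base.shape), species_id=node.taxon.label))
    return out


def gen_performance(
    grid_positions: np.ndarray,
    surface_spec: SurfaceSpec,
    noise_sd: float,
    seed: int = 0,
    bounds: np.ndarray | None = None,
) -> dict:
    """Noisy, min-max scaled F1/F2 samples at grid positions, plus noiseless.

    Noise is added to the analytic values before scaling, mirroring how
    measured functional metrics carry noise into the scaling step.
    """
    pos = np.asarray(grid_positions, float)
    if len(pos) < 4:
        raise ValueError("need at least 4 positions")
    if bounds is None:
        bounds = np.array([pos.min(axis=0), pos.max(axis=0)])
    rng = np.random.default_rng(seed)
    out = {}
    for name, fn in (("f1", surface_spec.f1), ("f2", surface_spec.f2)):
        raw = fn(pos, bounds)
        noisy = raw + rng.normal(0.0, noise_sd, size=len(pos)) if noise_sd > 0 else raw
        out[name] = scale_unit_interval(noisy)
        out[name + "_noiseless"] = scale_unit_interval(raw)
    out["bounds"] = bounds
    return out


def oracle_w(
    position: np.ndarray,
    surface_spec: SurfaceSpec,
    reference_grid: np.ndarray,
    w_step: float = 1e-4,
    bounds: np.ndarray | None = None,
) -> float:
    """Ground-truth trade-off weight by brute force on the analytic surfaces.

    The analytic F1/F2 are min-max scaled over the reference grid (the same
    convention the pipeline applies to measured values) and the log-fitness
    objective is scanned exhaustively over w.  Exact ties return the
    midpoint of the tying w set.
    """
    ref = np.asarray(reference_grid, float)
    if bounds is None:
        bounds = np.array([ref.min(axis=0), ref.max(axis=0)])
    pos = np.atleast_2d(np.asarray(position, float))

    def scaled(fn, pts):
        raw_ref = fn(ref, bounds)
        lo, hi = raw_ref.min(), raw_ref.max()
        return (fn(pts, bounds) - lo) / (hi - lo), (raw_ref - lo) / (hi - lo)

    f1_z, f1_ref = scaled(surface_spec.f1, pos)
    f2_z, f2_ref = scaled(surface_spec.f2, pos)
    from .landscape import estimate_w_from_values

    est = estimate_w_from_values(f1_z, f2_z, f1_ref, f2_ref, resolution=w_step, floor=1e-9)[0]
    return est.w


def _assign_clades(tree: dendropy.Tree, split: float) -> dict[str, str]:
    """Label the subtree whose tip count is closest to (1-split)*n as groupB."""
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    n = len(labels)
    target = (1.0 - split) * n
    best_node, best_err = None, np.inf
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        size = sum(1 for _ in node.leaf_iter())
        err = abs(size - target)
        if 2 <= size <= n - 3 and err < best_err:
            best_err, best_node = err, node
    groupB = {l.taxon.label for l in best_node.leaf_iter()} if best_node else set()
    return {lab: ("groupB" if lab in groupB else "groupA") for lab in labels}


def gen_study(config: SyntheticConfig) -> SyntheticStudy:
    """Assemble a full synthetic study: tree, shapes, grid, traits, true w.

    Species morphospace positions are the tips' actual PC1/PC2 scores from
    the generated shapes, so morphospace and landscape stay coupled.
    """
    seed = config.seed
    tree = gen_tree(config.n_tips, seed=seed)
    base = _base_configuration(config.n_landmarks, seed=seed + 1)
    landmarks = gen_shapes_bm(tree, base, config.bm_rate, seed=seed + 2)
    clades = _assign_clades(tree, config.clade_split)
    for lm in landmarks:
        lm.clade = clades[lm.species_id]
    alignment = gpa(landmarks)
    morpho = pca_morphospace(alignment)
    grid = theoretical_grid(morpho, n_per_axis=config.grid_n, extension=config.grid_extension)
    bounds = np.array([grid.min(axis=0), grid.max(axis=0)])
    perf = gen_performance(grid, config.surface_spec, config.noise_sd, seed=seed + 3, bounds=bounds)
    positions = pd.DataFrame(
        {
            "species": [c.species_id for c in alignment.aligned],
            "pc1": morpho.scores[:, 0],
            "pc2": morpho.scores[:, 1],
            "clade": [c.clade for c in alignment.aligned],
        }
    )
    true_w = pd.Series(
        [
            oracle_w(row, config.surface_spec, grid, bounds=bounds)
            for row in positions[["pc1", "pc2"]].to_numpy()
        ],
        index=positions["species"].to_list(),
        name="true_w",
    )
    return SyntheticStudy(
        config=config,
        tree=tree,
        landmarks=landmarks,
        alignment=alignment,
        morphospace=morpho,
        grid=grid,
        grid_bounds=bounds,
        f1_noiseless=perf["f1_noiseless"],
        f2_noiseless=perf["f2_noiseless"],
        f1_values=perf["f1"],
        f2_values=perf["f2"],
        species_positions=positions,
        true_w=true_w,
    )
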