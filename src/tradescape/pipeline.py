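"""End-to-end orchestration: landmarks -> morphospace -> surfaces -> w -> windows -> PLS -> comparative.

A single :class:`PipelineConfig` (loadable from YAML/JSON) drives the run.
Every stage writes plain-text artifacts (CSV/JSON) into the output
directory together with a provenance record (config hash, seeds, package
version), and all randomness flows from the config seed.  Inputs can be
files (landmarks, tree, functional-value tables, optional externally
computed rate tables) or, when ``simulate`` is set, a synthetic study
generated in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as tio
from .landscape import species_w, w_surface
from .phylo import fit_trait_model, mantel, pgls_design_comparison, rate_association, tree_tmrca
from .pls import fit_pls2b, transfer_assessment
from .shape import gpa, pca_morphospace, theoretical_grid
from .surfaces import crossvalidate_surfaces, default_candidates, fit_surface
from .synthetic import SyntheticConfig, gen_study
from .windows import association, make_windows, windowed_disparity

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    outdir: str = "tradescape_out"
    landmarks: str | None = None  # .tps or .csv
    tree: str | None = None  # newick
    f1_table: str | None = None  # csv: pc1, pc2, value
    f2_table: str | None = None
    rates_shape: str | None = None  # csv: tip_label, rate
    rates_w: str | None = None
    simulate: dict | None = None  # SyntheticConfig overrides; triggers generation
    grid_n: int = 8
    grid_extension: float = 0.10
    cv_folds: int = 10
    w_resolution: float = 0.001
    wsurface_n: int = 40
    window_step: float = 0.0002
    window_size: float = 0.011
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig(**data)


def _read_table(path: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("pc1", "pc2", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df[["pc1", "pc2"]].to_numpy(float), df["value"].to_numpy(float)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the result bundle (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- stage 0: inputs (files or synthetic study written to files first)
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault("grid_n", config.grid_n)
        sim_kwargs.setdefault("grid_extension", config.grid_extension)
        study = gen_study(SyntheticConfig(**sim_kwargs))
        tio.write_landmarks_csv(study.landmarks, out / "landmarks.csv")
        tio.write_tree(study.tree, out / "tree.nwk")
        for name, vals in (("f1", study.f1_values), ("f2", study.f2_values)):
            pd.DataFrame({"pc1": study.grid[:, 0], "pc2": study.grid[:, 1], "value": vals}).to_csv(
                out / f"{name}_table.csv", index=False
            )
        study.true_w.rename_axis("species").reset_index().to_csv(out / "true_w.csv", index=False)
        config = dataclasses.replace(
            config,
            landmarks=str(out / "landmarks.csv"),
            tree=str(out / "tree.nwk"),
            f1_table=str(out / "f1_table.csv"),
            f2_table=str(out / "f2_table.csv"),
        )

    if config.landmarks is None or config.f1_table is None or config.f2_table is None:
        raise ValueError("pipeline needs landmarks and two functional tables (or simulate)")

    def _stage(name):
        bundle["_last_stage"] = name

    # --- stage 1: superimposition and morphospace
    _stage("gpa")
    reader = tio.read_landmarks_tps if str(config.landmarks).endswith(".tps") else tio.read_landmarks_csv
    landmarks = reader(config.landmarks)
    alignment = gpa(landmarks)
    morpho = pca_morphospace(alignment)
    tio.write_landmarks_csv(alignment.aligned, out / "aligned.csv")
    pd.DataFrame(
        {
            "species": [c.species_id for c in alignment.aligned],
            "clade": [c.clade for c in alignment.aligned],
            "centroid_size": alignment.centroid_sizes,
            "pc1": morpho.scores[:, 0],
            "pc2": morpho.scores[:, 1],
        }
    ).to_csv(out / "morphospace_scores.csv", index=False)
    bundle["morphospace"] = morpho
    bundle["alignment"] = alignment

    # --- stage 2: theoretical grid
    _stage("grid")
    grid = theoretical_grid(morpho, n_per_axis=config.grid_n, extension=config.grid_extension)
    pd.DataFrame(grid, columns=["pc1", "pc2"]).to_csv(out / "theoretical_grid.csv", index=False)
    bundle["grid"] = grid

    # --- stage 3: performance surfaces (CV model selection per trait)
    _stage("surfaces")
    models = {}
    for name, table in (("f1", config.f1_table), ("f2", config.f2_table)):
        pos, vals = _read_table(table)
        report = crossvalidate_surfaces(pos, vals, default_candidates(), k=config.cv_folds, seed=config.seed)
        family, order = report.best
        models[name] = fit_surface(pos, vals, family, order)
        (out / f"{name}_cv.json").write_text(json.dumps(report.as_dict(), indent=1))
        tio.write_surface_model(models[name], out / f"{name}_model.json")
    bundle["surface_models"] = models
    fit_positions, _ = _read_table(config.f1_table)

    # --- stage 4: species trade-off weights (reference grid = fitting grid)
    _stage("tradeoff")
    positions = pd.read_csv(out / "morphospace_scores.csv")[["species", "pc1", "pc2"]]
    sw = species_w(positions, models["f1"], models["f2"], fit_positions,
                   resolution=config.w_resolution, floor=1e-9)
    sw.to_csv(out / "species_w.csv", index=False)
    bundle["species_w"] = sw

    # --- stage 5: dense w-surface
    _stage("w_surface")
    ws = w_surface(models["f1"], models["f2"], extent=grid, n=config.wsurface_n,
                   resolution=config.w_resolution, reference_grid=fit_positions, floor=1e-9)
    pd.DataFrame(
        {"pc1": ws.grid[:, 0], "pc2": ws.grid[:, 1], "w": ws.w, "log_fitness": ws.log_fitness}
    ).to_csv(out / "w_surface.csv", index=False)
    bundle["w_surface"] = ws

    # --- stage 6: sliding-window disparity vs w volume
    _stage("windows")
    wins = make_windows(float(ws.w.min()), float(ws.w.max()), step=config.window_step, size=config.window_size)
    shapes = alignment.flattened()
    wd = windowed_disparity(
        sw["w"].to_numpy(), sw[["pc1", "pc2"]].to_numpy(), shapes, wins, ws.w, seed=config.seed
    )
    wd.to_csv(out / "windows.csv", index=False)
    try:
        assoc = association(wd["volume"], wd["disparity"], seed=config.seed)
    except ValueError as exc:  # too few populated windows / constant profile
        assoc = {"n": int(wd["disparity"].notna().sum()), "error": str(exc)}
    (out / "window_association.json").write_text(json.dumps(assoc, indent=1))
    bundle["windows"] = wd
    bundle["window_association"] = assoc

    # --- stage 7: PLS form-function transfer (groupA -> groupB)
    _stage("pls")
    clades = pd.read_csv(out / "morphospace_scores.csv")["clade"].to_numpy()
    func_block = sw[["f1", "f2"]].to_numpy()
    is_a = clades == "groupA"
    bundle["pls"] = None
    if is_a.sum() >= 3 and (~is_a).sum() >= 1:
        model = fit_pls2b(shapes[is_a], func_block[is_a])
        ids = sw["species"].to_numpy()
        transfer = transfer_assessment(
            model, shapes[is_a], func_block[is_a], shapes[~is_a], func_block[~is_a],
            groupA_ids=list(ids[is_a]), groupB_ids=list(ids[~is_a]),
        )
        transfer.table.to_csv(out / "pls_transfer.csv", index=False)
        (out / "pls_summary.json").write_text(json.dumps({
            "singular_value": model.singular_value,
            "median_train": transfer.median_train,
            "median_transfer": transfer.median_transfer,
            "median_ratio": transfer.median_ratio,
            "mannwhitney_p": transfer.mannwhitney_p,
        }, indent=1))
        bundle["pls"] = transfer

    # --- stage 8: comparative phylogenetics on w
    _stage("comparative")
    comparative: dict = {}
    if config.tree is not None:
        tree = tio.read_tree(config.tree)
        w_series = sw.set_index("species")["w"]
        fits = {m: fit_trait_model(w_series, tree, m) for m in ("BM", "OU", "EB")}
        comparative["trait_models"] = {
            m: {"aicc": f.aicc, "loglik": f.loglik, "params": f.params} for m, f in fits.items()
        }
        scores = pd.read_csv(out / "morphospace_scores.csv").set_index("species")
        labels, _ = tree_tmrca(tree)
        size = np.log(scores.loc[labels, "centroid_size"].to_numpy(float))
        cmp_df = pgls_design_comparison(w_series.loc[labels].to_numpy(), size, tree=tree,
                                        n_perm=199, seed=config.seed)
        comparative["w_vs_size_pgls"] = cmp_df.to_dict(orient="records")
        if config.rates_shape and config.rates_w:
            ra = pd.read_csv(config.rates_shape).set_index("tip_label")["rate"]
            rb = pd.read_csv(config.rates_w).set_index("tip_label")["rate"]
            comparative["rate_association"] = rate_association(ra, rb, tree).to_dict(orient="records")
            shared = ra.index.intersection(rb.index).intersection(labels)
            idx = [labels.index(s) for s in shared]
            _, M = tree_tmrca(tree)
            depths = np.diag(M)
            phylo_d = (depths[:, None] + depths[None, :] - 2 * M)[np.ix_(idx, idx)]
            for name, r in (("shape", ra), ("w", rb)):
                tip = r.loc[shared].to_numpy(float)
                dmat = np.abs(tip[:, None] - tip[None, :])
                comparative[f"mantel_{name}_rates"] = mantel(dmat, phylo_d, n_perm=199, seed=config.seed)
        (out / "comparative.json").write_text(json.dumps(comparative, indent=1, default=float))
    bundle["comparative"] = comparative

    # --- provenance
    prov = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, default=str))
    bundle["provenance"] = prov
    return bundle
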