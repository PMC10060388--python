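"""End-to-end orchestration: read -> GPA + sliding -> relative warps ->
model selection -> per-PC / per-species permutation inference -> output bundle.

The pipeline is a pure function of (input files, config): identical inputs
and seed give byte-identical CSV outputs.  A single global seed expands into
per-stage seeds through a documented spawn-key scheme
(0 = reserved, 1 = classifier folds/tuning, 2 = permutation streams) so any
stage can be re-run in isolation from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import facemorph
from facemorph.classify import model_battery, select_best
from facemorph.inference import per_pc_analysis
from facemorph.procrustes import generalized_procrustes, slide_semilandmarks, tangent_project
from facemorph.relwarps import mean_shape, relative_warps, shape_at_score, variance_table
from facemorph.tps_io import (
    LandmarkDataset,
    assemble_dataset,
    read_metadata,
    read_sliders,
    read_tps,
    write_tps,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis; defaults reproduce the standard
    protocol (PC 1-11 features, fourfold CV, 2^-10..2^10 grid, 1000
    permutations)."""

    tps_path: str | None = None
    sliders_path: str | None = None
    metadata_path: str | None = None
    out_dir: str = "facemorph_out"
    sliding_mode: str = "bending_energy"  # none | bending_energy | procrustes_distance
    alpha: float = 0.0
    n_pcs_for_selection: int = 11
    folds: int = 4
    grid_min_exp: int = -10
    grid_max_exp: int = 10
    B: int = 1000
    seed: int = 0
    fast_perm: bool = False
    standardize: bool = True
    statistic: str = "accuracy"
    flip_y: bool = False
    pcs: tuple[int, ...] = field(default_factory=lambda: tuple(range(1, 12)))


def load_dataset(config: PipelineConfig) -> LandmarkDataset:
    configs = read_tps(config.tps_path, flip_y=config.flip_y)
    sliders = read_sliders(config.sliders_path, k=configs[0].k)
    metadata = read_metadata(config.metadata_path)
    return assemble_dataset(configs, metadata, sliders)


def run_pipeline(config: PipelineConfig, dataset: LandmarkDataset | None = None) -> dict:
    """Run the full analysis and write the output bundle to ``config.out_dir``.

    Returns a dict with the in-memory stage results (fit, model, battery,
    table, manifest).  Any stage failure aborts with the stage name; the
    manifest written so far records which outputs exist.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": facemorph.__version__,
        "stages": [],
    }
    stage = "load"
    try:
        if dataset is None:
            dataset = load_dataset(config)
        manifest["n_specimens"] = dataset.n
        manifest["k_landmarks"] = dataset.k
        manifest["group_sizes"] = {f"{sp}/{age}": n for (sp, age), n in dataset.group_sizes.items()}
        manifest["stages"].append(stage)

        stage = "gpa"
        logger.info("[gpa] superimposing %d specimens (%d landmarks)", dataset.n, dataset.k)
        fit = generalized_procrustes(dataset)
        if config.sliding_mode != "none":
            fit = slide_semilandmarks(fit, dataset.sliders, mode=config.sliding_mode)
        np.savetxt(out / "consensus.csv", fit.consensus, delimiter=",", header="x,y")
        aligned_df = pd.DataFrame(
            fit.aligned.reshape(fit.n, -1),
            index=pd.Index(fit.specimen_ids, name="specimen_id"),
        )
        aligned_df.insert(0, "centroid_size", fit.centroid_sizes)
        aligned_df.to_csv(out / "aligned.csv")
        manifest["sliding_mode"] = config.sliding_mode
        manifest["gpa_converged"] = bool(fit.converged)
        manifest["stages"].append(stage)

        stage = "relwarps"
        rows = tangent_project(fit)
        ages = dataset.age_labels()
        model = relative_warps(rows, alpha=config.alpha, consensus=fit.consensus, age_labels=ages)
        vt = variance_table(model)
        vt.to_csv(out / "variance_table.csv", index=False)
        scores_df = pd.DataFrame(
            model.scores,
            index=pd.Index(fit.specimen_ids, name="specimen_id"),
            columns=[f"PC{j + 1}" for j in range(model.n_components)],
        )
        scores_df.to_csv(out / "scores.csv")
        manifest["n_nontrivial_pcs"] = int(model.n_components)
        n_sel = min(config.n_pcs_for_selection, model.n_components)
        manifest["cumulative_variance_selected_pcs"] = float(
            vt["cumulative_fraction"].iloc[n_sel - 1]
        )
        manifest["stages"].append(stage)
        logger.info(
            "[relwarps] %d non-trivial PCs; PC1-%d cumulative variance %.3f",
            model.n_components, n_sel, manifest["cumulative_variance_selected_pcs"],
        )

        stage = "classify"
        ss = np.random.SeedSequence(config.seed)
        cls_seed = int(ss.spawn(2)[1].generate_state(1)[0] % (2**31))
        features = model.scores[:, :n_sel]
        battery = model_battery(
            features, ages, folds=config.folds, seed=cls_seed,
            grid_min_exp=config.grid_min_exp, grid_max_exp=config.grid_max_exp,
            standardize=config.standardize,
        )
        best = select_best(battery)
        pd.DataFrame(
            [
                {
                    "kind": r.spec.kind,
                    "cost": r.spec.cost,
                    "gamma": r.spec.gamma,
                    "cv_accuracy": r.accuracy,
                    "cv_auc": r.auc,
                    "train_accuracy": r.train_accuracy,
                    "train_auc": r.train_auc,
                    "selected": r.spec == best,
                    "seed": r.seed,
                }
                for r in battery
            ]
        ).to_csv(out / "model_comparison.csv", index=False)
        manifest["selected_model"] = dataclasses.asdict(best)
        manifest["stages"].append(stage)
        logger.info("[classify] selected %s", best)

        stage = "permtest"
        pcs = tuple(pc for pc in config.pcs if pc <= model.n_components)
        perm_seed = int(np.random.SeedSequence(config.seed).spawn(3)[2].generate_state(1)[0] % (2**31))
        table = per_pc_analysis(
            model.scores, dataset.metadata, best, pcs=pcs, B=config.B,
            seed=perm_seed, folds=config.folds, statistic=config.statistic,
            fast_perm=config.fast_perm, standardize=config.standardize,
        )
        table.to_csv(out / "age_class_table.csv")
        manifest["stages"].append(stage)

        stage = "shapes"
        species = dataset.species_labels()
        shapes = []
        for sp in ["all"] + sorted(set(species)):
            sp_mask = np.ones(dataset.n, bool) if sp == "all" else species == sp
            for age in ("adult", "infant"):
                mask = sp_mask & (ages == age)
                if mask.any():
                    shapes.append(mean_shape(fit, mask, name=f"mean_{sp}_{age}"))
        write_tps(shapes, out / "mean_shapes.tps")
        extremes = []
        for pc in pcs:
            sd = float(np.sqrt(model.eigenvalues[pc - 1]))
            extremes.append(shape_at_score(model, pc - 1, 1.5 * sd))
            extremes.append(shape_at_score(model, pc - 1, -1.5 * sd))
        write_tps(extremes, out / "pc_extremes.tps")
        manifest["stages"].append(stage)

        manifest["elapsed_seconds"] = round(time.time() - t0, 3)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return {
            "dataset": dataset,
            "fit": fit,
            "model": model,
            "variance_table": vt,
            "battery": battery,
            "best": best,
            "age_class_table": table,
            "manifest": manifest,
        }
    except Exception as e:
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e
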