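"""End-to-end pipeline: simulate/load -> PCA -> hypervolumes -> compare
-> crosswise projection -> evaluation -> report.

Every stochastic stage draws its seed from the master seed through a
recorded hierarchy (`SeedSequence([master_seed, stage_code, index])`),
so a rerun with the same configuration is byte-identical.  No output
file carries a timestamp for the same reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background import buffer_mask, sample_background
from .compare import (comparison_matrix, centroid_matrix, contribution_table,
                      density_profile)
from .envspace import dedupe_per_cell, extract_env, fit_pca, loadings, pc_scores
from .errors import ConfigurationError, HypernicheError
from .hypervolume import build_bdw, build_mcp, save_hypervolume
from .occurrences import OccurrenceSet
from .project import crosswise_project, evaluate
from .raster import read_raster_stack
from .synthetic import default_world

__all__ = ["RunConfig", "load_config", "run_pipeline", "report"]

TOTAL = "total"
BACKGROUND = "background"

# stage codes of the seed hierarchy (recorded in the manifest)
_STAGE_PCA_SUBSAMPLE = 2
_STAGE_BACKGROUND_SAMPLE = 3
_STAGE_HV_BUILD = 4
_STAGE_BG_HV_SUBSAMPLE = 5


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Either ``synthetic=True`` (the default virtual invasion world is
    generated into the run directory) or ``raster_paths`` +
    ``occurrences_csv`` must be given.
    """

    out_dir: str = "run"
    synthetic: bool = True
    raster_paths: list = field(default_factory=list)
    occurrences_csv: str = None
    groups: list = None              # None = all groups found
    bandwidth: float = 0.5           # bdw kernel half-width, PC units
    radius_km: float = 200.0         # background buffer radius
    n_background: int = 1000         # evaluation pseudo-absences per group
    n_mc: int = None                 # bdw MC draws (None = per-build default)
    n_mc_cap: int = 2_000_000        # ceiling on the per-build default
    target_points: int = 10_000      # uniform cloud size per hypervolume
    pca_cell_cap: int = 50_000       # PCA fit-sample cap (seeded subsample)
    background_hv_cap: int = 10_000  # background cells used for its hypervolume
    exclude_presence_cells: bool = True
    master_seed: int = 20170815

    def validate(self):
        if self.bandwidth <= 0 or self.radius_km <= 0:
            raise ConfigurationError("bandwidth and radius_km must be > 0")
        if not self.synthetic:
            missing = [p for p in list(self.raster_paths) +
                       ([self.occurrences_csv] if self.occurrences_csv else [])
                       if not Path(p).exists()]
            if not self.raster_paths or not self.occurrences_csv:
                raise ConfigurationError(
                    "non-synthetic run needs raster_paths and occurrences_csv")
            if missing:
                raise ConfigurationError(f"missing input paths: {missing}")


def load_config(path=None, **overrides) -> RunConfig:
    """Config from a flat YAML key-value file, overridden by kwargs.

    Precedence: explicit overrides > file > defaults.
    """
    values = {}
    if path is not None:
        with open(path) as fh:
            values.update(yaml.safe_load(fh) or {})
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(values) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)


def _seed(master, stage, index=0) -> int:
    return int(np.random.SeedSequence([master, stage, index])
               .generate_state(1)[0] % (2 ** 31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path, index=True):
    df.to_csv(path, index=index, float_format="%.6g")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Emits, per group plus the pooled total range and the background:
    PCA loadings table, hypervolume files for both methods, comparison
    and centroid-distance matrices, per-axis contribution tables,
    crosswise binary suitability rasters, an evaluation table, PC
    density profiles, and a machine-readable manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": asdict(config),
                "stages": [], "seeds": {}, "inputs": {}, "incomplete": True}
    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------
        stage = "simulate" if config.synthetic else "load"
        if config.synthetic:
            world = default_world(master_seed=config.master_seed)
            world_dir = out / "world"
            layer_paths = world.write(world_dir)
            stack = world.stack
            occ = world.all_occurrences()
            occ_path = world_dir / "occurrences.csv"
        else:
            layer_paths = [Path(p) for p in config.raster_paths]
            stack = read_raster_stack(layer_paths)
            occ_path = Path(config.occurrences_csv)
            occ = OccurrenceSet.read_csv(occ_path)
        manifest["inputs"] = {str(p): _sha256(p)
                              for p in list(layer_paths) + [occ_path]}
        groups = config.groups or occ.groups
        manifest["groups"] = list(groups)
        manifest["stages"].append(stage)

        # ---- thin to one record per cell and group ------------------
        stage = "extract"
        occ = dedupe_per_cell(occ, stack)
        presences = {g: occ.for_group(g) for g in groups}
        presences[TOTAL] = OccurrenceSet.concat([presences[g] for g in groups])
        manifest["stages"].append(stage)

        # ---- buffers + background samples ---------------------------
        stage = "buffer"
        masks_dir = out / "masks"
        masks_dir.mkdir(exist_ok=True)
        buffers, bg_points = {}, {}
        for gi, g in enumerate(list(groups) + [TOTAL]):
            buffers[g] = buffer_mask(stack, presences[g], config.radius_km)
            buffers[g].write(masks_dir / f"{g}_buffer.asc", stack)
            seed = _seed(config.master_seed, _STAGE_BACKGROUND_SAMPLE, gi)
            manifest["seeds"][f"background_sample/{g}"] = seed
            exclude = None
            if config.exclude_presence_cells:
                lon, lat = presences[g].lonlat()
                r, c = stack.cell_index(lon, lat)
                exclude = (r * stack.ncols + c)[r >= 0]
            bg_points[g] = sample_background(
                buffers[g], stack, n=config.n_background, seed=seed,
                exclude_cells=exclude)
            bg_points[g].write_csv(out / "background" / f"{g}_background.csv")
        manifest["stages"].append(stage)

        # ---- PCA on the available climate space ---------------------
        stage = "pca"
        union_mask = np.zeros_like(stack.nodata_mask)
        for g in groups:
            union_mask |= buffers[g].mask
        fit_df, _, _ = stack.cell_matrix(union_mask)
        pca_seed = _seed(config.master_seed, _STAGE_PCA_SUBSAMPLE)
        if len(fit_df) > config.pca_cell_cap:
            rng = np.random.default_rng(pca_seed)
            fit_df = fit_df.iloc[np.sort(
                rng.choice(len(fit_df), config.pca_cell_cap, replace=False))]
        manifest["seeds"]["pca_subsample"] = pca_seed
        pca = fit_pca(fit_df, fit_info={
            "fit_sample": "union of group buffers",
            "cap": config.pca_cell_cap})
        _write_csv(loadings(pca, fit_df), out / "pca_table.csv")
        manifest["pca"] = {"eigenvalues": pca.eigenvalues.tolist(),
                           "k": pca.k, "n_fit": int(len(fit_df))}
        manifest["stages"].append(stage)

        # ---- hypervolumes ------------------------------------------
        stage = "build"
        hv_dir = out / "hypervolumes"
        score_sets = {}
        for g in list(groups) + [TOTAL]:
            matrix, _ = extract_env(stack, presences[g])
            score_sets[g] = pc_scores(pca, matrix)
        bg_df, _, _ = stack.cell_matrix(union_mask)
        bg_seed = _seed(config.master_seed, _STAGE_BG_HV_SUBSAMPLE)
        manifest["seeds"]["background_hv_subsample"] = bg_seed
        if len(bg_df) > config.background_hv_cap:
            rng = np.random.default_rng(bg_seed)
            bg_df = bg_df.iloc[np.sort(
                rng.choice(len(bg_df), config.background_hv_cap, replace=False))]
        score_sets[BACKGROUND] = pc_scores(pca, bg_df)
        hvs = {"bdw": {}, "mcp": {}}
        for gi, (g, scores) in enumerate(score_sets.items()):
            for method in ("bdw", "mcp"):
                seed = _seed(config.master_seed, _STAGE_HV_BUILD,
                             2 * gi + (method == "mcp"))
                manifest["seeds"][f"hypervolume/{g}/{method}"] = seed
                if method == "bdw":
                    n_mc = config.n_mc or min(
                        max(100_000, 1000 * len(scores)), config.n_mc_cap)
                    hv = build_bdw(scores, bandwidth=config.bandwidth,
                                   n_mc=n_mc, seed=seed,
                                   target_points=config.target_points)
                else:
                    hv = build_mcp(scores, seed=seed,
                                   target_points=config.target_points)
                hvs[method][g] = hv
                save_hypervolume(hv, hv_dir / f"{g}_{method}")
        manifest["stages"].append(stage)

        # ---- comparisons -------------------------------------------
        stage = "compare"
        for method in ("bdw", "mcp"):
            _write_csv(comparison_matrix(hvs[method]),
                       out / f"comparison_{method}.csv")
            _write_csv(contribution_table(hvs[method]),
                       out / f"contributions_{method}.csv")
        group_only = [g for g in score_sets if g != BACKGROUND]
        _write_csv(centroid_matrix(
            {g: hvs["mcp"][g] for g in group_only},
            {g: hvs["bdw"][g] for g in group_only}), out / "centroids.csv")
        profiles = []
        for j in range(pca.k):
            prof = density_profile(
                {g: score_sets[g][:, j] for g in score_sets},
                variable=f"PC {j + 1}")
            profiles.append(prof.to_frame())
        _write_csv(pd.concat(profiles, ignore_index=True),
                   out / "profiles.csv", index=False)
        manifest["stages"].append(stage)

        # ---- crosswise projection ----------------------------------
        stage = "project"
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        region_masks = {g: buffers[g].mask for g in list(groups) + [TOTAL]}
        smaps = {}
        for method in ("bdw", "mcp"):
            group_hvs = {g: hvs[method][g] for g in list(groups) + [TOTAL]}
            smaps[method] = crosswise_project(group_hvs, pca, stack,
                                              region_masks)
            for (train, target), smap in smaps[method].items():
                smap.write(maps_dir / f"{method}_{train}_on_{target}.asc",
                           stack)
        manifest["stages"].append(stage)

        # ---- evaluation --------------------------------------------
        stage = "evaluate"
        rows, details = [], {}
        for method in ("bdw", "mcp"):
            for g in list(groups) + [TOTAL]:
                res = evaluate(smaps[method][(g, g)], stack, presences[g],
                               bg_points[g])
                rows.append({"Area": g, "Method": method, "AUC": res.auc,
                             "COR": res.cor, "Kappa": res.kappa})
                details[f"{method}/{g}"] = asdict(res)
        _write_csv(pd.DataFrame(rows), out / "evaluation.csv", index=False)
        with open(out / "evaluation_details.json", "w") as fh:
            json.dump(details, fh, indent=2, sort_keys=True)
        manifest["stages"].append(stage)
        manifest["incomplete"] = False
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        raise HypernicheError(f"stage '{stage}' failed: {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


_REPORT_TABLES = [
    ("PCA loadings, eigenvalues and explained variance", "pca_table.csv"),
    ("Model evaluation (AUC / COR / Kappa)", "evaluation.csv"),
    ("Volumes, intersections (below diagonal) and Soerensen indices "
     "(above diagonal) - bdw", "comparison_bdw.csv"),
    ("Volumes, intersections (below diagonal) and Soerensen indices "
     "(above diagonal) - mcp", "comparison_mcp.csv"),
    ("Centroid distances (mcp below, bdw above the diagonal)",
     "centroids.csv"),
    ("Per-axis contributions - bdw", "contributions_bdw.csv"),
    ("Per-axis contributions - mcp", "contributions_mcp.csv"),
]


def report(run_dir) -> Path:
    """Assemble the human-readable summary of a completed run.

    Reads only the stage CSVs and the manifest (no recomputation) and
    writes ``report.md``.  An incomplete run raises, listing the
    missing pieces.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise HypernicheError("no manifest.json: not a pipeline run directory")
    manifest = json.loads(manifest_path.read_text())
    missing = [fname for _, fname in _REPORT_TABLES
               if not (run_dir / fname).exists()]
    if manifest.get("incomplete") or missing:
        raise HypernicheError(
            f"run incomplete (failed stage: {manifest.get('failed_stage')}; "
            f"missing files: {missing})")
    lines = ["# Niche quantification report", ""]
    lines += [f"- package version: {manifest['version']}",
              f"- master seed: {manifest['config']['master_seed']}",
              f"- groups: {', '.join(manifest['groups'])}",
              f"- bandwidth: {manifest['config']['bandwidth']} PC units; "
              f"buffer radius: {manifest['config']['radius_km']} km; "
              f"background points: {manifest['config']['n_background']}",
              f"- retained PCs: {manifest['pca']['k']}", ""]
    for title, fname in _REPORT_TABLES:
        lines += [f"## {title}", ""]
        table = pd.read_csv(run_dir / fname).to_string(index=False)
        lines += ["```", table, "```", ""]
    lines += ["## Seeds", ""]
    lines += [f"- {k}: {v}" for k, v in sorted(manifest["seeds"].items())]
    out_path = run_dir / "report.md"
    out_path.write_text("\n".join(lines) + "\n")
    return out_path
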