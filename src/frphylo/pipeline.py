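"""Config-driven orchestration: simulate or ingest → correct → fit →
bootstrap bands → comparative models, with a machine-readable run manifest.

Every stochastic stage draws from a named substream of the single global
seed, so a (config, seed) pair fully determines every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, design as design_mod, fixtures
from .design import (
    ExperimentalDesign,
    SpeciesInfo,
    estimate_control_variation,
    records_to_frame,
)
from .frfit import FRCurveBand, bootstrap_group_band, fit_fr_frame, group_mean_params, params_to_frame
from .models import (
    RESPONSES,
    average_over_temperature,
    build_parameter_table,
    fit_splitplot_lmm,
    pgls_by_temperature,
    phylo_covariate,
)
from .phylo import read_newick, study_tree
from .synthetic import NoiseModel, TrueParameterSurface, default_truth, simulate_control, simulate_experiment, substream

logger = logging.getLogger("frphylo")

__all__ = ["load_config", "run_pipeline", "plot_fr_bands", "paper_like_config"]


def paper_like_config() -> dict[str, Any]:
    """Config reproducing the study dimensions in simulate mode."""
    return {
        "mode": "simulate",
        "seed": 0,
        "design": {
            "n_blocks": 3,
            "temperatures_C": [26, 28, 30, 32, 34],
            "biomass_levels_g": [1, 2, 4, 6, 8, 10, 12],
            "duration_hr": 60,
        },
        "noise": {"weighing_sd_g": 0.05},
        "analysis": {
            "n_boot": 2000,
            "grid_points": 50,
            "bands": True,
            "pgls": True,
            "plots": False,
        },
    }


def load_config(path: str | Path) -> dict[str, Any]:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_design(config: dict[str, Any], species: tuple[SpeciesInfo, ...]) -> ExperimentalDesign:
    block = config.get("design", {})
    return ExperimentalDesign(
        n_blocks=int(block.get("n_blocks", 3)),
        temperatures_C=tuple(float(t) for t in block.get("temperatures_C", (26, 28, 30, 32, 34))),
        species=species,
        biomass_levels_g=tuple(float(b) for b in block.get("biomass_levels_g", (1, 2, 4, 6, 8, 10, 12))),
        duration_hr=float(block.get("duration_hr", 60)),
    )


def _load_species(config: dict[str, Any]) -> tuple[SpeciesInfo, ...]:
    path = config.get("paths", {}).get("species")
    if path is None:
        return fixtures.STUDY_SPECIES
    df = pd.read_csv(path)
    return tuple(
        SpeciesInfo(r["species"], r.get("common_name", ""), r["origin_region"], r.get("habitat", ""))
        for _, r in df.iterrows()
    )


def _load_tree(config: dict[str, Any]):
    path = config.get("paths", {}).get("tree")
    if path is None:
        return study_tree()
    tree = read_newick(Path(path))
    drop = config.get("paths", {}).get("drop_taxa", [fixtures.OUTGROUP])
    present = set(tree.taxa)
    to_drop = [t for t in drop if t in present]
    return tree.drop_taxa(to_drop) if to_drop else tree


def _build_truth(config: dict[str, Any], phylo_dist: dict[str, float]) -> TrueParameterSurface:
    truth = default_truth(phylo_distance=phylo_dist)
    overrides = config.get("truth", {})
    for key, value in overrides.items():
        if not hasattr(truth, key):
            raise KeyError(f"unknown truth field: {key!r}")
        setattr(truth, key, value)
    return truth


def run_pipeline(
    config: dict[str, Any] | str | Path,
    seed: int | None = None,
    out: str | Path | None = None,
) -> dict[str, Any]:
    """Run all stages and write CSV outputs plus ``manifest.json``.

    Returns the manifest (stage record counts, config hash, seed, version).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    seed = int(config.get("seed", 0))
    out_dir = Path(out or config.get("output_dir", "results/run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    analysis = config.get("analysis", {})
    manifest: dict[str, Any] = {
        "package": "frphylo",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    species = _load_species(config)
    design = _build_design(config, species)
    mode = config.get("mode", "simulate")
    want_pgls = bool(analysis.get("pgls", True))
    tree = None
    phylo_dist: dict[str, float] = {}
    try:
        tree = _load_tree(config)
        familiar = [s.name for s in species if s.familiarity == "familiar"]
        novel = [s.name for s in species if s.familiarity == "novel"]
        phylo_dist = phylo_covariate(tree, familiar, novel)
    except FileNotFoundError as exc:
        if want_pgls:
            raise RuntimeError(f"stage phylo: missing tree input ({exc})") from exc

    # --- stage 1: data -----------------------------------------------------
    if mode == "simulate":
        truth = _build_truth(config, phylo_dist)
        noise = NoiseModel(
            control=fixtures.STUDY_CONTROL_VARIATION,
            weighing_sd_g=float(config.get("noise", {}).get("weighing_sd_g", 0.05)),
        )
        records = simulate_experiment(design, truth, noise, seed)
        controls = simulate_control(design, design.n_blocks, noise.control, seed)
        control_var = noise.control
    elif mode == "ingest":
        paths = config.get("paths", {})
        for key in ("trials", "control"):
            if key not in paths:
                raise RuntimeError(f"stage ingest: config missing paths.{key}")
        raw = design_mod.read_trials(paths["trials"])
        controls = design_mod.read_controls(paths["control"])
        control_var = estimate_control_variation(controls)
        records = design_mod.apply_correction(raw, control_var)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    trials = records_to_frame(records)
    trials.to_csv(out_dir / "trials.csv", index=False)
    controls.to_csv(out_dir / "controls.csv", index=False)
    manifest["stages"]["data"] = {
        "trial_records": len(trials),
        "control_records": len(controls),
        "clamped_records": int(trials["clamped"].sum()),
    }
    logger.info("data: %d trial, %d control records", len(trials), len(controls))

    # --- stage 2: functional-response fits ---------------------------------
    T = float(analysis.get("T", design.duration_hr))
    params = fit_fr_frame(trials, T)
    params_df = params_to_frame(params)
    params_df.to_csv(out_dir / "params.csv", index=False)
    manifest["stages"]["frfit"] = {
        "fits": len(params_df),
        "converged": int(params_df["converged"].sum()),
    }
    logger.info("frfit: %d fits", len(params_df))

    group_of = {s.name: s.familiarity for s in species}
    means = group_mean_params(params, group_of)
    means.to_csv(out_dir / "group_means.csv", index=False)

    # --- stage 3: bootstrap bands ------------------------------------------
    if analysis.get("bands", True):
        n_boot = int(analysis.get("n_boot", 2000))
        grid = np.linspace(
            min(design.biomass_levels_g), max(design.biomass_levels_g),
            int(analysis.get("grid_points", 50)),
        )
        rng = substream(seed, "bootstrap_bands")
        bands = [
            bootstrap_group_band(
                trials, group, temp, T, n_boot=n_boot, grid=grid,
                seed=rng, group_of=group_of,
            )
            for group in ("familiar", "novel")
            for temp in design.temperatures_C
        ]
        bands_df = pd.concat([b.to_frame() for b in bands], ignore_index=True)
        bands_df.to_csv(out_dir / "bands.csv", index=False)
        manifest["stages"]["bands"] = {"bands": len(bands), "n_boot": n_boot}
        if analysis.get("plots", False):
            files = plot_fr_bands(bands, out_dir / "figures")
            manifest["stages"]["bands"]["figures"] = [f.name for f in files]

    # --- stage 4: comparative models ----------------------------------------
    table = build_parameter_table(params_df, list(species), phylo_dist)
    table.to_csv(out_dir / "parameter_table.csv", index=False)
    manifest["stages"]["models"] = {"parameter_rows": len(table)}

    anova_rows, contrast_rows = [], []
    for fixed in ("temp_origin", "temp_phylo"):
        for response in RESPONSES:
            fit = fit_splitplot_lmm(table, response, fixed=fixed)
            af = fit.anova_frame()
            af.insert(0, "model", fixed)
            anova_rows.append(af)
            cf = fit.contrast_frame()
            cf.insert(0, "model", fixed)
            contrast_rows.append(cf)
    pd.concat(anova_rows, ignore_index=True).to_csv(out_dir / "lmm_anova.csv", index=False)
    pd.concat(contrast_rows, ignore_index=True).to_csv(out_dir / "lmm_contrasts.csv", index=False)

    if want_pgls:
        pgls_rows = []
        for response in RESPONSES:
            for res in pgls_by_temperature(table, tree, response):
                row = res.coef("origin")
                pgls_rows.append(
                    {"response": response, "level": res.level,
                     "estimate": row["estimate"], "t": row["t"], "p": row["p"],
                     "df_resid": res.df_resid, "model": res.covariance_model}
                )
        pd.DataFrame(pgls_rows).to_csv(out_dir / "pgls.csv", index=False)
        manifest["stages"]["pgls"] = {"fits": len(pgls_rows)}

    avg = average_over_temperature(table)
    avg.to_csv(out_dir / "species_means.csv")

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def plot_fr_bands(bands: list[FRCurveBand], output_dir: str | Path) -> list[Path]:
    """One panel per temperature: familiar vs novel mean curves with shaded
    95% bootstrap bands; axes are initial vs consumed biomass (g)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not bands:
        raise ValueError("empty band list")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    styles = {"familiar": ("tab:blue", "-"), "novel": ("tab:red", "--")}
    files = []
    temps = sorted({b.temperature_C for b in bands})
    for temp in temps:
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for band in bands:
            if band.temperature_C != temp:
                continue
            color, ls = styles.get(band.group, ("tab:gray", "-"))
            ax.fill_between(band.grid_N, band.lower, band.upper, color=color, alpha=0.25, lw=0)
            ax.plot(band.grid_N, band.mean, color=color, ls=ls, label=band.group)
        ax.set_xlabel("Initial biomass N (g)")
        ax.set_ylabel("Consumed biomass Ne (g)")
        ax.set_title(f"{temp:g} °C")
        ax.legend(frameon=False)
        fig.tight_layout()
        path = output_dir / f"fr_bands_{temp:g}C.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        files.append(path)
    return files
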