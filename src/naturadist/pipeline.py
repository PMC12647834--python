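"""End-to-end orchestration: world -> distances -> model -> importance -> shapes.

``run_pipeline`` executes the stages in order, writing every product as CSV /
JSON / Newick into a run directory together with a machine-readable manifest.
Re-running with the same config and seed reproduces the outputs byte for
byte. ``mode="simulate"`` generates a synthetic world; ``mode="ingest"``
reads user-supplied tables in the same documented layout (regions.csv,
cells.csv, flora.csv, phylogeny.nwk, optional outcomes.csv and taxonomy.csv
with genus/family columns for grafting species missing from the tree).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .synthetic_world import (
    BIDIRECTIONAL,
    DISTANCE_NAMES,
    Phylogeny,
    TrueParams,
    WorldConfig,
    generate_outcomes,
    simulate_world,
)
from .climate_pca import fit_pca, transform_scores, region_pc_means
from .phylo import TreeIndex
from .flora_diversity import (
    area_correction,
    donor_union_metrics,
    graft_missing,
    region_diversity,
)
from .distance_engine import build_distance_table
from .model import apply_subset, build_design, fit_model, partial_effect_curve, peak_location, wald_tests
from .importance import bootstrap_importance
from .scenarios import classify_model

import dendropy

__all__ = ["PipelineConfig", "run_pipeline", "report", "PRODUCT_FILES"]

logger = logging.getLogger(__name__)

PRODUCT_FILES = [
    "regions.csv",
    "cells.csv",
    "flora.csv",
    "outcomes.csv",
    "phylogeny.nwk",
    "world_config.yaml",
    "pca_model.json",
    "region_climate.csv",
    "diversity.csv",
    "area_correction.json",
    "distances.csv",
    "model_coefficients.csv",
    "variance_components.csv",
    "partial_effects.csv",
    "peaks.csv",
    "importance_replicates.csv",
    "importance_summary.csv",
    "scenarios.csv",
    "manifest.json",
]

CELL_PUBLIC_COLUMNS = ["cell_id", "region_id"] + [f"bioclim_{i}" for i in range(1, 20)] + ["hmi"]

DIRECTION_TYPES = {
    name: ("bidirectional" if name in BIDIRECTIONAL else "unidirectional")
    for name in DISTANCE_NAMES
}


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    mode: str = "simulate"  # simulate | ingest
    seed: int = 0
    input_dir: str | None = None  # ingest mode
    world: WorldConfig = field(default_factory=WorldConfig)
    diversity_flavor: str = "phylogenetic"  # flora-diversity distance metric
    dissimilarity_flavor: str = "phylogenetic"
    flora_distance_mode: str = "union"
    random_effects: bool = True
    laplace_refine: bool = True
    bootstrap_reps: int = 99
    bootstrap_size: int = 5000
    subset_rule: str | None = None
    subset_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest" and not self.input_dir:
            raise ValueError("ingest mode requires input_dir")
        for name in ("diversity_flavor", "dissimilarity_flavor"):
            if getattr(self, name) not in ("phylogenetic", "taxonomic"):
                raise ValueError(f"{name} must be phylogenetic or taxonomic")
        if self.mode == "simulate":
            self.world.seed = self.seed
            self.world.validate()

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        world = d.pop("world", None) or {}
        tp = world.pop("true_params", None) or {}
        cfg = cls(**d)
        cfg.world = WorldConfig(**world, true_params=TrueParams(**tp))
        return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _load_world(config: PipelineConfig, out: Path):
    """Simulate or ingest, returning (phylogeny, regions, cells, flora, outcomes)."""
    if config.mode == "simulate":
        world = simulate_world(config.world)
        return world.phylogeny, world.regions, world.cells, world.flora, None
    src = Path(config.input_dir)
    regions = pd.read_csv(src / "regions.csv")
    cells = pd.read_csv(src / "cells.csv")
    flora = pd.read_csv(src / "flora.csv")
    tree = dendropy.Tree.get(path=str(src / "phylogeny.nwk"), schema="newick")
    genus_map: dict = {}
    family_map: dict = {}
    tax_path = src / "taxonomy.csv"
    if tax_path.exists():
        tax = pd.read_csv(tax_path)
        genus_map = dict(zip(tax["species_id"], tax["genus"]))
        family_map = dict(zip(tax["species_id"], tax["family"]))
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(flora["species_id"]) - tips)
    if missing:
        tree = graft_missing(tree, missing, genus_map, family_map)
        logger.info("grafted %d species missing from the tree", len(missing))
    phy = Phylogeny(tree=tree, genus=genus_map, family=family_map)
    outcomes = None
    out_path = src / "outcomes.csv"
    if out_path.exists():
        outcomes = pd.read_csv(out_path)
    else:
        nat = flora[flora["status"] == "naturalized"]
        if len(nat):
            outcomes = pd.DataFrame(
                {
                    "species_id": nat["species_id"].to_numpy(),
                    "recipient_region_id": nat["region_id"].to_numpy(),
                    "outcome": 1,
                }
            )
    return phy, regions, cells, flora, outcomes


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage and write all products into ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "mode": config.mode,
        "stages": {},
        "warnings": [],
    }

    stage = "world"
    try:
        phy, regions, cells, flora, outcomes = _load_world(config, out)
        tree_index = TreeIndex(phy.tree)
        manifest["stages"][stage] = {
            "n_regions": len(regions),
            "n_cells": len(cells),
            "n_species": tree_index.n_tips,
            "n_flora_rows": len(flora),
        }

        stage = "climate_pca"
        pca_model = fit_pca(cells)
        scores = transform_scores(pca_model, cells)
        region_climate = region_pc_means(scores, regions["region_id"])
        manifest["stages"][stage] = {
            "explained_pc1": float(pca_model.explained_variance_fraction[0]),
            "explained_pc2": float(pca_model.explained_variance_fraction[1]),
            "dropped": pca_model.dropped,
        }

        stage = "flora_diversity"
        metric = "faith_pd" if config.diversity_flavor == "phylogenetic" else "richness"
        reg_div = region_diversity(flora, regions, tree_index)
        union_div = donor_union_metrics(flora, regions, tree_index)
        records = pd.concat([reg_div, union_div], ignore_index=True)
        fits = {}
        for m in ("faith_pd", "richness"):
            fit_m, resid_m = area_correction(records, metric=m, scope="pooled")
            records[f"area_corrected_{'pd' if m == 'faith_pd' else 'richness'}"] = resid_m
            fits[m] = fit_m
        manifest["stages"][stage] = {"n_units": len(records)}

        stage = "distance_engine"
        resid_col = "area_corrected_pd" if metric == "faith_pd" else "area_corrected_richness"
        reg_rec = records[records["unit_type"] == "region"].set_index("unit_id")
        uni_rec = records[records["unit_type"] == "donor_union"].set_index("unit_id")
        region_resid = reg_rec[resid_col].to_dict()
        union_resid = uni_rec[resid_col].to_dict()
        region_hmi = cells.groupby("region_id")["hmi"].mean().to_dict()
        distances = build_distance_table(
            regions,
            flora,
            region_climate,
            region_hmi,
            region_resid,
            union_resid,
            tree_index,
            outcomes=outcomes,
            dissim_flavor=config.dissimilarity_flavor,
            flora_distance_mode=config.flora_distance_mode,
        )
        if config.mode == "simulate":
            outcomes = generate_outcomes(distances, config.world.true_params, config.seed)
            distances["outcome"] = outcomes["outcome"].to_numpy()
            nat = outcomes[outcomes["outcome"] == 1]
            flora = pd.concat(
                [
                    flora,
                    pd.DataFrame(
                        {
                            "region_id": nat["recipient_region_id"].to_numpy(),
                            "species_id": nat["species_id"].to_numpy(),
                            "status": "naturalized",
                        }
                    ),
                ],
                ignore_index=True,
            )
        if config.subset_rule:
            distances = apply_subset(distances, config.subset_rule, **config.subset_params)
        manifest["stages"][stage] = {
            "n_rows": len(distances),
            "prevalence": float(distances["outcome"].mean()),
        }

        stage = "naturalization_model"
        design = build_design(distances, random_effects=config.random_effects)
        model = fit_model(design, laplace_refine=config.laplace_refine)
        tests = wald_tests(model)
        peaks = []
        curves = []
        for name in DISTANCE_NAMES:
            t = tests.set_index("term")
            pk = peak_location(
                beta1=float(t.loc[f"{name}_linear", "estimate"]),
                beta2=float(t.loc[f"{name}_quadratic", "estimate"]),
                scaling_factor=model.spec.scaling[name],
                p_quadratic=float(t.loc[f"{name}_quadratic", "p"]),
                predictor=name,
            )
            peaks.append(dataclasses.asdict(pk))
            curves.append(partial_effect_curve(model, name))
        manifest["stages"][stage] = {
            "converged": model.converged,
            "sigma2_species": model.sigma2_species,
            "sigma2_region": model.sigma2_region,
        }

        stage = "importance_partitioning"
        imp = bootstrap_importance(
            distances,
            n_reps=config.bootstrap_reps,
            sample_size=min(config.bootstrap_size, len(distances)),
            seed=config.seed,
        )
        manifest["stages"][stage] = {
            "n_reps": config.bootstrap_reps,
            "n_discarded": imp.n_discarded,
        }

        stage = "scenario_classifier"
        scen = classify_model(tests, DIRECTION_TYPES)
        manifest["stages"][stage] = {"n_predictors": len(scen)}
    except Exception as err:
        partial = [p.name for p in out.iterdir()] if out.exists() else []
        raise RuntimeError(
            f"pipeline stage {stage!r} failed: {err}; partial outputs in {out}: {partial}"
        ) from err

    # ----- write products -----
    _write_csv(regions, out / "regions.csv")
    _write_csv(cells[[c for c in CELL_PUBLIC_COLUMNS if c in cells.columns]], out / "cells.csv")
    _write_csv(flora, out / "flora.csv")
    _write_csv(outcomes if outcomes is not None else pd.DataFrame(columns=["species_id", "recipient_region_id", "outcome"]), out / "outcomes.csv")
    (out / "phylogeny.nwk").write_text(phy.newick() + "\n")
    config.to_yaml(out / "world_config.yaml")
    (out / "pca_model.json").write_text(pca_model.to_json())
    _write_csv(region_climate, out / "region_climate.csv")
    _write_csv(records, out / "diversity.csv")
    (out / "area_correction.json").write_text(
        json.dumps(
            {
                m: {"slope": f.slope, "intercept": f.intercept, "scope": f.scope}
                for m, f in fits.items()
            },
            indent=2,
        )
    )
    _write_csv(distances, out / "distances.csv")
    _write_csv(tests, out / "model_coefficients.csv")
    _write_csv(
        pd.DataFrame(
            {
                "component": ["species", "region"],
                "variance": [model.sigma2_species, model.sigma2_region],
            }
        ),
        out / "variance_components.csv",
    )
    _write_csv(pd.concat(curves, ignore_index=True), out / "partial_effects.csv")
    _write_csv(pd.DataFrame(peaks), out / "peaks.csv")
    _write_csv(imp.replicates, out / "importance_replicates.csv")
    _write_csv(imp.summary, out / "importance_summary.csv")
    _write_csv(scen, out / "scenarios.csv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def report(run_directory) -> Path:
    """Render a single human-readable summary of a completed run."""
    run = Path(run_directory)
    required = [
        "model_coefficients.csv",
        "importance_summary.csv",
        "partial_effects.csv",
        "peaks.csv",
        "scenarios.csv",
        "manifest.json",
    ]
    missing = [f for f in required if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run}: missing products {missing}")
    coefs = pd.read_csv(run / "model_coefficients.csv")
    imp = pd.read_csv(run / "importance_summary.csv")
    peaks = pd.read_csv(run / "peaks.csv")
    scen = pd.read_csv(run / "scenarios.csv", keep_default_na=False)
    manifest = json.loads((run / "manifest.json").read_text())

    lines = ["# naturadist run report", ""]
    lines.append(f"seed: {manifest['seed']}  mode: {manifest['mode']}  version: {manifest['version']}")
    lines.append("")
    lines.append("## Standardized coefficients (cloglog scale)")
    lines.append(coefs.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    lines.append("")
    lines.append("## Relative importance (% of fixed-effect R2m)")
    lines.append(imp.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    lines.append("")
    lines.append("## Peak locations")
    lines.append(peaks.to_string(index=False))
    lines.append("")
    lines.append("## Shape scenarios")
    lines.append(scen.to_string(index=False))
    lines.append("")
    path = run / "report.md"
    path.write_text("\n".join(lines))
    return path
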