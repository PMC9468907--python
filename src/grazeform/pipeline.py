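"""End-to-end orchestration of the survey analysis.

Stages run in the field-analysis order: trait indices -> growth-form
classification -> fourth-corner trait-environment model -> environmental
ordination with cover surfaces -> bare-ground regressions.  Each stage is
file-based (reads the previous stage's outputs from the output directory),
so running the stages one by one produces exactly the files a single
:func:`run_pipeline` call does.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .bareground import BareGroundAnalysis, analyze_bare_ground, site_summaries
from .fourthcorner import anova_resampling, build_triplet, select_env_subset
from .growthform import assign_growth_forms
from .ordination import (
    growthform_site_cover,
    interpolate_cover_surface,
    site_environment_pca,
)
from .survey import FLOAT_FORMAT, Survey, load_overrides, load_survey
from .traits import build_trait_table


@dataclass
class PipelineConfig:
    """Inputs, outputs and tunables of a full pipeline run."""

    quadrats_path: str
    meta_path: str
    sites_path: str
    out_dir: str
    overrides_path: str | None = None
    k: int = 4
    n_iterations: int = 999
    seed: int = 0
    grid_n: int = 100
    unit_variance_pca: bool = True

    def validate(self) -> "PipelineConfig":
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_iterations < 99:
            raise ValueError("n_iterations must be >= 99")
        return self


def _load(config: PipelineConfig) -> Survey:
    return load_survey(config.quadrats_path, config.meta_path, config.sites_path)


def stage_indices(config: PipelineConfig, survey: Survey | None = None) -> pd.DataFrame:
    """Compute and write the species trait table (``trait_table.csv``)."""
    survey = survey or _load(config)
    table = build_trait_table(survey)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "trait_table.csv", float_format=FLOAT_FORMAT)
    return table


def _read_trait_table(out_dir) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "trait_table.csv", index_col="species")


def stage_classify(config: PipelineConfig, survey: Survey | None = None):
    """Growth-form classification from the written trait table."""
    table = _read_trait_table(config.out_dir)
    overrides = load_overrides(config.overrides_path) if config.overrides_path else None
    model = assign_growth_forms(
        table, k=config.k, overrides=overrides, unit_variance=config.unit_variance_pca
    )
    model.to_files(config.out_dir)
    return model

def stage_fourthcorner(config: PipelineConfig, survey: Survey | None = None):
    """Fourth-corner GLM: AICc subset selection plus the permutation ANOVA."""
    survey = survey or _load(config)
    table = _read_trait_table(config.out_dir)
    triplet = build_triplet(survey, table)
    selection = select_env_subset(triplet)
    selection.to_files(config.out_dir)
    test = anova_resampling(
        triplet,
        env_subset=selection.best.env_subset,
        n_iterations=config.n_iterations,
        seed=config.seed,
    )
    test.to_files(config.out_dir)
    return selection, test


def stage_ordination(config: PipelineConfig, survey: Survey | None = None):
    """Site environment PCA and growth-form cover surfaces."""
    survey = survey or _load(config)
    assignments = pd.read_csv(Path(config.out_dir) / "assignments.csv", index_col="species")
    ordn = site_environment_pca(survey.sites)
    ordn.to_files(config.out_dir)
    cover = growthform_site_cover(survey, assignments)
    cover.to_csv(Path(config.out_dir) / "site_cover.csv", float_format=FLOAT_FORMAT)
    surfaces = interpolate_cover_surface(ordn, cover, grid_n=config.grid_n)
    for surface in surfaces.values():
        surface.to_files(config.out_dir)
    return ordn, cover, surfaces


def stage_bareground(config: PipelineConfig, survey: Survey | None = None) -> BareGroundAnalysis:
    """Dominance split, group comparison and bare-ground AICc regressions."""
    survey = survey or _load(config)
    cover = pd.read_csv(Path(config.out_dir) / "site_cover.csv", index_col="site_id")
    result = analyze_bare_ground(site_summaries(survey, cover))
    result.to_files(config.out_dir)
    return result


STAGES = {
    "indices": stage_indices,
    "classify": stage_classify,
    "fourthcorner": stage_fourthcorner,
    "ordination": stage_ordination,
    "bareground": stage_bareground,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write ``manifest.json``.

    A stage failure aborts the downstream stages; the manifest records the
    error and which stages completed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    survey = _load(config)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": {},
        "complete": False,
    }
    try:
        for name, fn in STAGES.items():
            t0 = time.perf_counter()
            fn(config, survey)
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        manifest["complete"] = True
    except Exception as e:
        manifest["stages"][name] = {"status": "failed", "error": str(e)}
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
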