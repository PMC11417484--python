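"""End-to-end orchestration: simulate -> quantify -> cohort -> cox -> scan ->
clump -> prs, under one validated config with per-stage seeds and a manifest.

Every stage output is a pure function of (config, seed): per-stage seeds are
derived from the global seed by stable hashing, tables are written with a
fixed float format, so identical reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import association, cohort as cohort_mod, genetics, regional_mass
from .errors import ConfigurationError
from .simulate import (
    CategoryEffects,
    GenoSimSpec,
    LDBlock,
    SimCohortSpec,
    attach_outcome_dates,
    generate_cohort,
    generate_genotypes,
    generate_phantom_stack,
    random_phantom_specs,
    simulate_category_survival,
    simulate_quantitative_phenotype,
)

FLOAT_FORMAT = "%.10g"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomStageConfig(_Strict):
    n_phantoms: int = 200
    grid_shape: tuple[int, int] = (128, 128)
    pixel_spacing: float = 1.0
    n_slices: int = 10
    n_apical: int = 4


class CohortStageConfig(_Strict):
    n_subjects: int = 5000
    percentile: float = 90.0
    outcome: str = "cardiomyopathy"
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.01
    max_follow_up_years: float = 10.0
    prevalent_fraction: float = 0.02


class GeneticsStageConfig(_Strict):
    n_variants: int = 500
    n_causal: int = 5
    causal_beta: float = 0.35
    noise_sd: float = 1.0
    ld_block_size: int = 5
    ld_r: float = 0.8
    p_thresh: float = genetics.GENOME_WIDE_P
    r2_thresh: float = genetics.CLUMP_R2
    window_kb: float = genetics.CLUMP_WINDOW_KB
    prs_quantiles: tuple[float, ...] = (90.0, 95.0)


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "cardiomass_run"
    phantoms: PhantomStageConfig = Field(default_factory=PhantomStageConfig)
    cohort: CohortStageConfig = Field(default_factory=CohortStageConfig)
    genetics: GeneticsStageConfig = Field(default_factory=GeneticsStageConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except Exception as exc:  # pydantic error -> package error
            raise ConfigurationError(f"invalid run config {path}: {exc}") from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to the out dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tool": "cardiomass", "seed": config.seed, "stages": {}}
    t0 = time.time()

    # --- stage 1+2: phantoms and quantification -------------------------
    pc = config.phantoms
    specs = random_phantom_specs(
        pc.n_phantoms,
        seed=stage_seed(config.seed, "phantoms"),
        grid_shape=pc.grid_shape,
        pixel_spacing=pc.pixel_spacing,
        n_slices=pc.n_slices,
    )
    rows = []
    for i, spec in enumerate(specs):
        stack, truth = generate_phantom_stack(spec, subject_id=f"P{i:05d}")
        rec = regional_mass.quantify_subject(stack, n_apical=pc.n_apical)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "total_mass_g": rec.total_mass_g,
                "apical_mass_g": rec.apical_mass_g,
                "septal_mass_g": rec.septal_mass_g,
                "truth_total_g": truth.total_mass_g,
                "truth_apical_g": truth.apical_mass_g,
                "truth_septal_g": truth.septal_mass_g,
                "qc_passed": int(rec.qc_passed),
            }
        )
    masses = pd.DataFrame(rows)
    h = _write(masses, out / "masses.tsv")
    rel = (masses["total_mass_g"] - masses["truth_total_g"]).abs() / masses["truth_total_g"]
    manifest["stages"]["quantify"] = {
        "n_phantoms": len(masses),
        "max_rel_error_total": float(rel.max()),
        "sha256": h,
    }

    # --- stage 3: cohort -------------------------------------------------
    cc = config.cohort
    sim_spec = SimCohortSpec(n_subjects=cc.n_subjects, seed=stage_seed(config.seed, "cohort"))
    table = cohort_mod.add_hypertrophy_flags(generate_cohort(sim_spec), percentile=cc.percentile)[0]
    table = cohort_mod.assign_categories(table)
    effects = CategoryEffects()
    table = simulate_category_survival(
        table,
        "model_group",
        effects,
        baseline_hazard=cc.baseline_hazard,
        censoring_rate=cc.censoring_rate,
        max_follow_up_years=cc.max_follow_up_years,
        seed=stage_seed(config.seed, "survival"),
        outcome=cc.outcome,
    )
    table = attach_outcome_dates(
        table,
        cc.outcome,
        prevalent_fraction=cc.prevalent_fraction,
        seed=stage_seed(config.seed, "prevalent"),
    )
    incident, prevalent_ids = cohort_mod.remove_prevalent(table, cc.outcome)
    corr = cohort_mod.phenotype_correlations(incident)
    h = _write(incident, out / "cohort.tsv")
    _write(corr.reset_index().rename(columns={"index": "phenotype"}), out / "correlations.tsv")
    manifest["stages"]["cohort"] = {
        "n_subjects": len(table),
        "n_incident": len(incident),
        "n_prevalent_removed": len(prevalent_ids),
        "n_events": int(incident[f"{cc.outcome}_event"].sum()),
        "sha256": h,
    }

    # --- stage 4: survival models ---------------------------------------
    hr_cat = association.hypertrophy_hazard_table(incident, cc.outcome)
    hr_sd = pd.concat(
        [
            association.per_sd_mass_model(incident, cc.outcome, col)
            for col in ("total_mass_g", "apical_mass_g", "septal_mass_g")
        ],
        ignore_index=True,
    )
    m_apical, m_septal = association.joint_mass_models(incident, cc.outcome)
    h = _write(hr_cat, out / "hr_categorical.tsv")
    _write(hr_sd, out / "hr_per_sd.tsv")
    _write(m_apical, out / "hr_joint_apical.tsv")
    _write(m_septal, out / "hr_joint_septal.tsv")
    manifest["stages"]["cox"] = {"n_fits": 6, "sha256": h}

    # --- stage 5: genetics -----------------------------------------------
    gc = config.genetics
    rng = np.random.default_rng(stage_seed(config.seed, "genetics"))
    causal = {
        int(i): gc.causal_beta
        for i in rng.choice(gc.n_variants, size=gc.n_causal, replace=False)
    }
    blocks = []
    next_free = 0
    for i in sorted(causal):
        if i >= next_free and i + gc.ld_block_size <= gc.n_variants:
            blocks.append(LDBlock(start=int(i), size=gc.ld_block_size, r=gc.ld_r))
            next_free = i + gc.ld_block_size
    blocks = tuple(blocks)
    geno_spec = GenoSimSpec(
        n_subjects=cc.n_subjects,
        n_variants=gc.n_variants,
        ld_blocks=blocks,
        causal_betas=causal,
        seed=stage_seed(config.seed, "genotypes"),
    )
    panel = generate_genotypes(geno_spec)
    panel_f = genetics.filter_variants(panel)
    pheno = simulate_quantitative_phenotype(
        panel, noise_sd=gc.noise_sd, seed=stage_seed(config.seed, "phenotype")
    )
    covs = table[["age"]].copy()
    covs["sex_male"] = (table["sex"] == "male").astype(float)
    stats_table = genetics.linear_scan(panel_f, pheno, covs.to_numpy(dtype=float))
    h = _write(stats_table, out / "sumstats.tsv")
    leads = genetics.clump(
        stats_table,
        genetics.ld_lookup_from_panel(panel_f),
        p_thresh=gc.p_thresh,
        r2_thresh=gc.r2_thresh,
        window_kb=gc.window_kb,
    )
    (out / "leads.txt").write_text("".join(f"{v}\n" for v in leads))
    manifest["stages"]["scan"] = {
        "n_variants_scanned": panel_f.n_variants,
        "n_significant": int((stats_table["p_value"] < gc.p_thresh).sum()),
        "n_leads": len(leads),
        "lambda_gc": genetics.genomic_control_lambda(stats_table["p_value"].to_numpy()),
        "sha256": h,
    }

    # --- stage 6: PRS ----------------------------------------------------
    weights = pd.DataFrame(
        {
            "variant_id": [panel.variants["variant_id"].iloc[i] for i in sorted(causal)],
            "effect_allele": [panel.variants["alt"].iloc[i] for i in sorted(causal)],
            "weight": [causal[i] for i in sorted(causal)],
        }
    )
    scores = genetics.prs_score(panel, weights)
    scores_inc = scores.loc[incident.index].reset_index(drop=True)
    prs_table = genetics.prs_outcome_association(
        scores_inc, incident.reset_index(drop=True), cc.outcome, quantiles=gc.prs_quantiles
    )
    h = _write(prs_table, out / "prs_associations.tsv")
    manifest["stages"]["prs"] = {
        "n_weights": len(weights),
        "n_scored": len(scores),
        "sha256": h,
    }

    manifest["wall_seconds"] = round(time.time() - t0, 3)
    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
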