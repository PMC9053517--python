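"""Configuration-driven end-to-end orchestration.

The pipeline runs simulate (or load) → harmonize → slopes → scores → GWAS
(→ optional signal dissection and sensitivity analyses), writing every
intermediate table under the output directory and emitting a run report with
the headline numbers: subject counts at each stage, PCA variance explained,
genomic lambda per GWAS, and the top association per domain.  Identical
configuration and seed reproduce the report byte for byte.
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

from . import associations, gwas, harmonize, io, scores, signals, slopes
from ._util import PipelineError
from .scales import DEFAULT_SCALES, load_scales
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs.  Exactly one of ``simulation`` (generator
    parameters) or ``inputs`` (paths to visit/subject/genotype files) must be
    given; a seed is mandatory when simulating."""

    output_dir: str = "pdprog_run"
    simulation: dict | None = None
    inputs: dict | None = None           # keys: visits, subjects, vcf | (dosage_matrix, variant_table)
    scales_file: str | None = None
    seed: int | None = None
    cap_months: float = 72.0
    percent: bool = True
    flip_direction: bool = False
    n_genetic_pcs: int = 5
    maf_min: float = 0.01
    sig_threshold: float = 5e-8
    use_t: bool = True
    sex_stratified: bool = False
    stepwise: bool = False
    gene_regions: str | None = None
    gene_n_null: int = 100_000
    certainty_threshold: float | None = None
    trim_fraction: float | None = None
    ledd_attenuation: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Schema and cross-field checks; returns the accumulated error list."""
    errors: list[str] = []
    if (config.simulation is None) == (config.inputs is None):
        errors.append("exactly one of 'simulation' and 'inputs' must be set")
    if config.simulation is not None and config.seed is None and "seed" not in config.simulation:
        errors.append("seed is mandatory when simulating")
    if config.inputs is not None:
        have_vcf = "vcf" in config.inputs
        have_matrix = "dosage_matrix" in config.inputs and "variant_table" in config.inputs
        for key in ("visits", "subjects"):
            if key not in config.inputs:
                errors.append(f"inputs missing required path {key!r}")
        if not (have_vcf or have_matrix):
            errors.append("inputs need either 'vcf' or 'dosage_matrix'+'variant_table'")
    if not 0 <= config.maf_min < 0.5:
        errors.append("maf_min must lie in [0, 0.5)")
    if not 0 < config.sig_threshold < 1:
        errors.append("sig_threshold must lie in (0, 1)")
    if config.n_genetic_pcs < 0:
        errors.append("n_genetic_pcs must be >= 0")
    if config.trim_fraction is not None and not 0 <= config.trim_fraction < 0.5:
        errors.append("trim_fraction must lie in [0, 0.5)")
    if config.certainty_threshold is not None and not 0 <= config.certainty_threshold <= 100:
        errors.append("certainty_threshold must lie in [0, 100]")
    return errors


def _load_stage(config: PipelineConfig, outdir: Path):
    scale_defs = load_scales(config.scales_file) if config.scales_file else DEFAULT_SCALES
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        if config.seed is not None:
            sim_kwargs.setdefault("seed", config.seed)
        if "causal_effects" in sim_kwargs:
            sim_kwargs["causal_effects"] = tuple(
                (int(i), str(d), float(e)) for i, d, e in sim_kwargs["causal_effects"]
            )
        sim = SimulationConfig(**sim_kwargs)
        cohort = simulate_cohort(sim)
        io.write_table(cohort.subjects, outdir / "subjects.tsv")
        io.write_table(cohort.visits, outdir / "visits.tsv")
        io.write_table(cohort.truth, outdir / "truth.tsv")
        io.write_dosage_matrix(cohort.genotypes, outdir / "dosages.tsv", outdir / "variants.tsv")
        return cohort.subjects, cohort.visits, cohort.genotypes, scale_defs
    paths = config.inputs
    subjects = io.read_table(paths["subjects"])
    visits = io.read_table(paths["visits"])
    if "vcf" in paths:
        genotypes = io.read_vcf(paths["vcf"])
    else:
        genotypes = io.read_dosage_matrix(paths["dosage_matrix"], paths["variant_table"])
    return subjects, visits, genotypes, scale_defs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; return (and persist) the run report."""
    errs = validate_config(config)
    if errs:
        raise PipelineError("invalid configuration: " + "; ".join(errs))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    stage = "load"
    try:
        subjects, visits, genotypes, scale_defs = _load_stage(config, outdir)
        report["stages"]["load"] = {
            "n_subjects": int(subjects["subject_id"].nunique()),
            "n_visit_rows": int(len(visits)),
            "n_variants": int(genotypes.n_variants),
        }

        stage = "sensitivity-precheck"
        if config.certainty_threshold is not None:
            subjects = associations.filter_by_certainty(subjects, config.certainty_threshold)
            keep = set(subjects["subject_id"])
            visits = visits.loc[visits["subject_id"].isin(keep)].reset_index(drop=True)
            report["stages"]["certainty_filter"] = {"n_subjects": len(subjects)}
        if config.ledd_attenuation is not None:
            visits = associations.ledd_adjust(visits, config.ledd_attenuation, scales=scale_defs)
            report["stages"]["ledd_adjust"] = {"attenuation": config.ledd_attenuation}

        stage = "harmonize"
        std = harmonize.harmonize(
            visits, scale_defs, cap_months=config.cap_months,
            percent=config.percent, flip=config.flip_direction,
        )
        io.write_table(std, outdir / "harmonized.tsv")
        report["stages"]["harmonize"] = {"n_rows": int(len(std))}

        stage = "slopes"
        slope_matrix, fits = slopes.fit_all_scales(std, subjects, scale_defs)
        io.write_table(slope_matrix.reset_index(), outdir / "slope_matrix.tsv")
        diag = pd.DataFrame(
            [
                {
                    "scale_id": f.scale_id, "converged": f.converged, "method": f.method,
                    "var_intercept": f.var_intercept, "var_slope": f.var_slope,
                    "cov_int_slope": f.cov_int_slope, "resid_var": f.resid_var,
                    "n_subjects": f.n_subjects, "n_obs": f.n_obs,
                    "n_dropped_covariates": f.n_dropped_covariates, "loglike": f.loglike,
                }
                for f in fits.values()
            ]
        )
        io.write_table(diag, outdir / "slope_diagnostics.tsv")
        report["stages"]["slopes"] = {
            "n_converged": int(diag["converged"].sum()), "n_models": len(diag),
        }

        stage = "scores"
        score_table, pca_results = scores.compute_progression_scores(
            slope_matrix, scale_defs, direction_flipped=config.flip_direction
        )
        io.write_table(score_table.reset_index(), outdir / "progression_scores.tsv")
        pca_report = {
            d: {
                "variance_explained": r.variance_explained,
                "n_subjects": r.n_subjects,
                "loadings": {k: float(v) for k, v in r.loadings.items()},
            }
            for d, r in pca_results.items()
        }
        r_mc, p_mc = scores.correlate_domains(score_table["motor"], score_table["cognitive"])
        report["stages"]["scores"] = {
            "pca": pca_report, "motor_cognitive_r": r_mc, "motor_cognitive_p": p_mc,
        }

        stage = "gwas"
        if config.trim_fraction is not None:
            report["stages"]["trim"] = {}
        pcs, pc_evr = (None, None)
        cov = gwas.CovariateSet(cohort=subjects.set_index("subject_id")["cohort"])
        if config.n_genetic_pcs > 0:
            pcs, pc_evr = gwas.compute_genetic_pcs(genotypes, k=config.n_genetic_pcs)
            io.write_table(pcs.reset_index(), outdir / "genetic_pcs.tsv")
            cov = gwas.CovariateSet(
                cohort=subjects.set_index("subject_id")["cohort"], genetic_pcs=pcs
            )
        gwas_summary = {}
        for domain in score_table.columns:
            dom_scores = score_table[domain]
            if config.trim_fraction is not None:
                dom_scores = associations.trim_extremes(dom_scores, config.trim_fraction)
                report["stages"]["trim"][domain] = {"n_after": int(dom_scores.notna().sum())}
            stats_df = gwas.run_gwas(
                dom_scores, genotypes, cov, maf_min=config.maf_min, use_t=config.use_t
            )
            io.write_table(stats_df, outdir / f"gwas_{domain}.tsv")
            lam = gwas.genomic_lambda(stats_df)
            top = stats_df.loc[stats_df["P"].idxmin()]
            n_sig = int((stats_df["P"] < config.sig_threshold).sum())
            gwas_summary[domain] = {
                "n": int(stats_df["N"].iloc[0]) if len(stats_df) else 0,
                "n_variants": int(len(stats_df)),
                "lambda": lam,
                "n_genome_wide_significant": n_sig,
                "top_variant": str(top["variant_id"]),
                "top_beta": float(top["BETA"]),
                "top_p": float(top["P"]),
            }
            if config.sex_stratified:
                strata = gwas.sex_stratified_gwas(
                    dom_scores, genotypes, cov, subjects.set_index("subject_id")["sex"],
                    maf_min=config.maf_min,
                )
                for label, tab in strata.items():
                    io.write_table(tab, outdir / f"gwas_{domain}_{label}.tsv")
            if config.stepwise:
                sel, joint = signals.stepwise_select(
                    dom_scores, genotypes, cov, p_threshold=config.sig_threshold
                )
                io.write_table(joint, outdir / f"signals_{domain}.tsv")
                gwas_summary[domain]["independent_signals"] = sel
            if config.gene_regions:
                regions = signals.read_regions_table(config.gene_regions)
                gene_tab = signals.gene_based_test(
                    dom_scores, genotypes, cov, regions,
                    n_null=config.gene_n_null, seed=config.seed or 0, maf_min=config.maf_min,
                    summary=stats_df,
                )
                io.write_table(gene_tab, outdir / f"genes_{domain}.tsv")
                gwas_summary[domain]["gene_bonferroni_threshold"] = gene_tab.attrs[
                    "bonferroni_threshold"
                ]
        report["stages"]["gwas"] = gwas_summary
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
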