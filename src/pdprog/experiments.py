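"""Reference experiments on synthetic cohorts with known ground truth.

Each function builds a study condition the pipeline is expected to handle —
a fully null cohort for calibration, a single causal variant for parameter
recovery, an LD block with two causal variants for signal dissection, a
medication-masked motor exam for the LEDD sensitivity check — runs the full
relevant slice of the pipeline, and returns the measured quantities together
with the ground truth they should match.  The analysis drivers and the
acceptance checks are thin wrappers around these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gwas, harmonize, scores, signals, slopes
from ._util import rng_stream
from .associations import ledd_adjust
from .scales import MOTOR_EXAM_SCALE, scales_by_id
from .simulate import (
    GenotypeMatrix,
    SimulationConfig,
    latent_rho_for_dosage_r,
    simulate_cohort,
    simulate_genotype_block,
    simulate_genotypes,
)
from .slopes import MixedModelSpec, fit_random_slopes


def _pipeline_scores(cohort, n_pcs=5):
    """harmonize -> slopes -> PCA scores + covariates for the cohort."""
    std = harmonize.harmonize(cohort.visits)
    slope_matrix, fits = slopes.fit_all_scales(std, cohort.subjects)
    table, pca = scores.compute_progression_scores(slope_matrix)
    cov = gwas.CovariateSet(cohort=cohort.subjects.set_index("subject_id")["cohort"])
    if n_pcs > 0:
        pcs, _ = gwas.compute_genetic_pcs(cohort.genotypes, k=n_pcs)
        cov = gwas.CovariateSet(
            cohort=cohort.subjects.set_index("subject_id")["cohort"], genetic_pcs=pcs
        )
    return table, pca, cov, fits


def null_gwas_calibration(
    seed: int,
    n_subjects_per_cohort: int = 667,
    n_variants: int = 5000,
    n_pcs: int = 5,
) -> dict:
    """Genomic lambda of the composite-score GWAS on a fully null cohort.

    Three cohorts (~2,000 subjects total), independent variants with allele
    frequencies uniform on (0.05, 0.5), six scales with random intercepts and
    slopes but no genetic effects anywhere; progression scores are built
    through the full harmonize -> mixed-model -> PCA path and tested against
    every variant with cohort + genetic-PC adjustment.
    """
    cfg = SimulationConfig(
        n_subjects=n_subjects_per_cohort, n_cohorts=3, n_variants=n_variants,
        maf_range=(0.05, 0.5), ld_rho=0.0, seed=seed,
    )
    cohort = simulate_cohort(cfg)
    table, pca, cov, _ = _pipeline_scores(cohort, n_pcs=n_pcs)
    out = {"pca_variance_explained": {d: r.variance_explained for d, r in pca.items()}}
    out["motor_cognitive_r"] = scores.correlate_domains(table["motor"], table["cognitive"])[0]
    out["summary"] = {}
    for domain in ("composite", "motor", "cognitive"):
        stats_df = gwas.run_gwas(table[domain], cohort.genotypes, cov, maf_min=0.01)
        out["summary"][domain] = stats_df
        out[f"lambda_{domain}"] = gwas.genomic_lambda(stats_df)
        out[f"n_significant_{domain}"] = int((stats_df["P"] < 5e-8).sum())
    out["n_subjects"] = int(table["composite"].notna().sum())
    out["n_variants"] = int(len(out["summary"]["composite"]))
    return out


def causal_recovery_trial(
    seed: int,
    effect_slope_sd: float = 0.3,
    causal_maf: float = 0.3,
    n_subjects_per_cohort: int = 1000,
    n_variants: int = 120,
) -> dict:
    """One replicate of the cognitive-variant recovery experiment.

    A single variant (fixed MAF) shifts the latent cognitive slope by
    ``effect_slope_sd`` random-slope SDs per alt allele.  The full pipeline is
    run and the variant's association with the cognitive and motor scores is
    measured.  The induced score-scale effect is computed from ground truth:
    the score regressed on the true latent cognitive slope (the only channel
    the variant can act through), times the realized dosage effect on that
    slope.
    """
    cfg = SimulationConfig(
        n_subjects=n_subjects_per_cohort, n_cohorts=2, n_variants=n_variants,
        maf_range=(causal_maf, causal_maf),
        visit_times=(0.0, 1.5, 3.0, 4.5, 6.0),
        causal_effects=((0, "cognitive", effect_slope_sd),),
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    table, _, cov, _ = _pipeline_scores(cohort)
    res = {}
    for domain in ("cognitive", "motor"):
        stats_df = gwas.run_gwas(table[domain], cohort.genotypes, cov, maf_min=0.01)
        row = stats_df.set_index("variant_id").loc["snp_00000"]
        res[f"beta_{domain}"] = float(row["BETA"])
        res[f"p_{domain}"] = float(row["P"])
    # ground-truth induced effect on the cognitive score scale
    truth = cohort.truth.set_index("subject_id")
    y = table["cognitive"].dropna()
    s = truth.loc[y.index, "slope_cognitive"].to_numpy()
    d = cohort.genotypes.dosage[
        pd.Index(cohort.genotypes.subject_ids).get_indexer(y.index), 0
    ]
    slope_y_on_s = np.polyfit(s, y.to_numpy(), 1)[0]
    slope_s_on_d = np.polyfit(d, s, 1)[0]
    res["induced_beta_cognitive"] = float(slope_y_on_s * slope_s_on_d)
    return res


def make_signal_block(
    rng: np.random.Generator,
    n_subjects: int,
    maf: float = 0.3,
    r2_between_causals: float = 0.5,
    r2_proxy: float = 0.9,
    n_null_variants: int = 20,
) -> GenotypeMatrix:
    """Genotypes with one LD block [causal A, causal B, proxy of A] + null SNPs.

    Pairwise dosage correlations are set by inverting the genotype copula;
    the proxy is conditionally independent of causal B given causal A.
    """
    r_ab = latent_rho_for_dosage_r(maf, maf, np.sqrt(r2_between_causals))
    r_ap = latent_rho_for_dosage_r(maf, maf, np.sqrt(r2_proxy))
    latent = np.array(
        [[1.0, r_ab, r_ap], [r_ab, 1.0, r_ab * r_ap], [r_ap, r_ab * r_ap, 1.0]]
    )
    block = simulate_genotype_block(rng, n_subjects, [maf] * 3, latent)
    nulls = rng.binomial(2, maf, size=(n_subjects, n_null_variants)).astype(float)
    dosage = np.hstack([block, nulls])
    m = dosage.shape[1]
    variants = pd.DataFrame(
        {
            "variant_id": [f"snp_{j:05d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 10_000,
            "ref": "A",
            "alt": "G",
            "freq": dosage.mean(axis=0) / 2.0,
        }
    )
    return GenotypeMatrix(dosage=dosage, variants=variants,
                          subject_ids=[f"S{idx:05d}" for idx in range(n_subjects)])


def signal_dissection_trial(
    seed: int, n_subjects: int = 2000, beta_primary: float = 0.5, beta_secondary: float = 0.4
) -> dict:
    """One replicate of stepwise independent-signal selection.

    Two causal variants in LD (r^2 = 0.5) plus a pure r^2 = 0.9 proxy of the
    first; correct behaviour is selecting exactly the two causal variants.
    The effects are deliberately unequal (a strong primary signal and a
    weaker secondary one, the pattern seen in real multi-signal loci):
    with exactly equal effects the proxy of the primary becomes statistically
    interchangeable with it whenever the secondary is selected first, and no
    selection procedure can distinguish them.
    """
    rng = rng_stream(seed, "signal-dissection")
    g = make_signal_block(rng, n_subjects)
    y = pd.Series(
        beta_primary * g.dosage[:, 0]
        + beta_secondary * g.dosage[:, 1]
        + rng.standard_normal(n_subjects),
        index=g.subject_ids,
    )
    selected, joint = signals.stepwise_select(y, g, None)
    return {
        "selected": selected,
        "correct": set(selected) == {"snp_00000", "snp_00001"},
        "joint": joint,
    }


def gene_test_null_calibration(
    seed: int,
    n_subjects: int = 1000,
    n_genes: int = 200,
    variants_per_gene: int = 10,
    ld_rho: float = 0.8,
    n_null: int = 4000,
) -> pd.DataFrame:
    """Gene-based test p-values on a null phenotype with strong intra-gene LD."""
    cfg = SimulationConfig(
        n_subjects=n_subjects, n_cohorts=1, n_variants=n_genes * variants_per_gene,
        ld_block_size=variants_per_gene, ld_rho=ld_rho, maf_range=(0.1, 0.5), seed=seed,
    )
    g = simulate_genotypes(cfg)
    rng = rng_stream(seed, "gene-null-phenotype")
    y = pd.Series(rng.standard_normal(n_subjects), index=g.subject_ids)
    regions = [
        signals.GeneRegion(
            f"G{k}", "1", int(g.variants["pos"].iloc[k * variants_per_gene]),
            int(g.variants["pos"].iloc[(k + 1) * variants_per_gene - 1]),
        )
        for k in range(n_genes)
    ]
    return signals.gene_based_test(y, g, None, regions, n_null=n_null, seed=seed, maf_min=0.0)


def ledd_sensitivity_trial(
    seed: int,
    attenuation: float = 0.05,
    n_subjects_per_cohort: int = 500,
) -> dict:
    """Medication-masking experiment for the motor examination.

    Three scenarios share one seed: untreated (no masking), treated but
    unadjusted, and treated with the dose-reconstruction adjustment using the
    generator's true attenuation.  Reported quantity: correlation between the
    extracted motor-exam random slope and the true underlying slope.
    """
    base = dict(
        n_subjects=n_subjects_per_cohort, n_cohorts=2, n_variants=4, seed=seed,
        scale_slope_sd=0.0, ledd_coef=150.0,
    )
    untreated = simulate_cohort(SimulationConfig(**base))
    treated = simulate_cohort(SimulationConfig(**base, ledd_attenuation=attenuation))
    scale = scales_by_id()[MOTOR_EXAM_SCALE]
    spec = MixedModelSpec(MOTOR_EXAM_SCALE)

    def slope_truth_corr(cohort, visits):
        std = harmonize.harmonize(visits)
        fit = fit_random_slopes(std, cohort.subjects, spec)
        truth = cohort.truth.set_index("subject_id")
        common = fit.slopes.index
        return float(
            np.corrcoef(fit.slopes.to_numpy(), truth.loc[common, "slope_motor"])[0, 1]
        )

    adjusted_visits = ledd_adjust(treated.visits, attenuation, scale=scale)
    return {
        "corr_untreated": slope_truth_corr(untreated, untreated.visits),
        "corr_masked": slope_truth_corr(treated, treated.visits),
        "corr_adjusted": slope_truth_corr(treated, adjusted_visits),
    }


def carrier_trim_trial(seed: int, effect_slope_sd: float = 0.8,
                       n_subjects_per_cohort: int = 500) -> dict:
    """Carrier effect on cognitive progression, with and without 5% trimming."""
    from .associations import score_association, trim_extremes

    cfg = SimulationConfig(
        n_subjects=n_subjects_per_cohort, n_cohorts=2, n_variants=4, seed=seed,
        carrier_rate=0.15, carrier_effects=(0.0, effect_slope_sd),
    )
    cohort = simulate_cohort(cfg)
    table, _, cov, _ = _pipeline_scores(cohort, n_pcs=0)
    carrier = cohort.subjects.set_index("subject_id")["carrier_status"]
    full = score_association(carrier, table["cognitive"], cov, name="carrier")
    trimmed_scores = trim_extremes(table["cognitive"], 0.05)
    trimmed = score_association(carrier.loc[trimmed_scores.index], trimmed_scores,
                                cov, name="carrier")
    return {"full": full, "trimmed": trimmed}
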