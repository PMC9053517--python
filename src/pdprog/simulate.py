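"""Synthetic longitudinal PD cohorts with known ground truth.

Generates the three ingredients the progression-GWAS pipeline consumes —
genotype dosages, subject covariates, and longitudinal clinical visits —
with the statistical structure the downstream analysis assumes:

* genotypes in Hardy–Weinberg proportions, with linkage disequilibrium
  produced by a Gaussian copula (AR(1) latent correlation within fixed-size
  blocks, independence across blocks);
* per-subject latent disease severity per domain (motor, cognitive), linear
  in years from symptom onset, with correlated random intercepts and slopes,
  covariate effects, and optional genetic effects on the domain slopes;
* six bounded clinical scales observed as affine maps of the latent severity
  plus residual noise, with within-cohort measurement offsets, visit-level
  missingness and monotone dropout;
* a levodopa-equivalent daily dose (LEDD) trajectory coupled to motor
  severity, and an optional treatment attenuation of the motor examination
  score so medication-adjustment procedures can be validated against truth.

Every quantity that downstream recovery tests need (true intercepts, true
slopes, entry delays) is returned alongside the observable tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._util import ConfigurationError, rng_stream
from .scales import DEFAULT_SCALES, MOTOR_EXAM_SCALE, ScaleDefinition

DOMAINS = ("motor", "cognitive")

#: Affine map from latent severity (unit-SD scale) to each raw instrument:
#: raw = anchor + direction * amplitude * severity (+ noise), truncated to the
#: scale range.  Anchors/amplitudes mirror typical early-PD cohort baselines
#: (e.g. MDS-UPDRS III ~24 +/- 12, MoCA ~25 +/- 3.5).
SCALE_MAPS: dict[str, tuple[float, float]] = {
    "updrs3": (24.0, 12.0),
    "updrs2": (9.0, 6.0),
    "hoehn_yahr": (1.8, 0.55),
    "moca": (25.0, 3.0),
    "fluency": (25.0, 8.0),
    "updrs1_1": (0.5, 0.6),
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Effect sizes in ``causal_effects`` are expressed in units of the random
    slope SD (``sqrt(var_slope)``) per alt-allele dosage, on the latent
    severity scale.
    """

    n_subjects: int = 1000          # per cohort
    n_cohorts: int = 3
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)  # years from entry
    followup_sd: float = 0.1        # per-visit jitter, years (baseline not jittered)
    causal_effects: tuple[tuple[int, str, float], ...] = ()
    var_intercept: float = 1.0
    var_slope: float = 0.04         # (0.2 / yr)^2 latent slope heterogeneity
    cov_int_slope: float = 0.02
    cross_domain_corr: float = 0.3  # correlation of motor and cognitive random slopes
    resid_sd: float = 0.35          # per-measurement noise, latent-SD units
    scale_slope_sd: float = 0.12    # scale-specific progression component, latent SD / yr
    scale_intercept_sd: float = 0.5  # scale-specific severity offset, latent-SD units
    dropout_rate: float = 0.06      # per-visit hazard of leaving the study
    missing_rate: float = 0.05      # per-measurement missingness
    informative_dropout: float = 0.0  # extra dropout log-odds per severity SD
    # subject covariates
    male_fraction: float = 0.65
    onset_age_mean: float = 64.0
    onset_age_sd: float = 10.0
    education_mean: float = 11.0
    education_sd: float = 2.5
    higher_education_fraction: float = 0.35
    entry_delay_mean: float = 2.9   # disease duration at study entry, years
    entry_delay_sd: float = 2.6
    carrier_rate: float = 0.096
    carrier_effects: tuple[float, float] = (0.0, 0.0)  # (motor, cognitive) slope-SD units
    # covariate effects on latent trajectories (latent-SD units)
    age_slope_beta: float = 0.03    # per onset-age SD, per year
    sex_slope_beta: float = 0.02
    education_slope_beta: float = -0.02  # cognitive domain only, per education SD
    age_intercept_beta: float = 0.10
    mean_slope: float = 0.18        # population mean progression, latent SD / yr
    cohort_offset_sd: float = 0.25  # per cohort x scale measurement offset, latent-SD units
    # medication model
    ledd_base: float = 300.0        # mg/day
    ledd_coef: float = 100.0        # mg/day per latent motor severity SD
    ledd_sd: float = 50.0
    ledd_attenuation: float = 0.0   # motor-exam points masked per mg/day
    # population structure (for genetic-PC tests only)
    ancestry_fraction: float = 0.0  # fraction of subjects in a second ancestry group
    ancestry_maf_shift: float = 0.0
    seed: int = 0
    scales: tuple[ScaleDefinition, ...] = field(default=DEFAULT_SCALES)

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError(f"maf_range must lie within (0,1), got {self.maf_range}")
        if not 0 <= self.ld_rho < 1:
            raise ConfigurationError(f"ld_rho must lie in [0,1), got {self.ld_rho}")
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        g = np.array(
            [[self.var_intercept, self.cov_int_slope], [self.cov_int_slope, self.var_slope]]
        )
        if np.any(np.linalg.eigvalsh(g) < 0) or (
            self.var_slope > 0 and np.linalg.det(g) < -1e-12
        ):
            raise ConfigurationError("random-effect covariance is not positive semi-definite")
        times = np.asarray(self.visit_times, float)
        if times.size == 0 or times.min() < 0 or times.max() > 6.0:
            raise ConfigurationError("visit_times must be within [0, 6] years (72-month design)")
        if not 0 <= self.cross_domain_corr <= 1:
            raise ConfigurationError("cross_domain_corr must lie in [0,1]")
        for idx, domain, _ in self.causal_effects:
            if not 0 <= idx < self.n_variants:
                raise ConfigurationError(f"causal variant index {idx} out of range")
            if domain not in DOMAINS and domain != "both":
                raise ConfigurationError(f"unknown causal-effect domain {domain!r}")

    @property
    def n_total(self) -> int:
        return self.n_subjects * self.n_cohorts

    @property
    def cohort_labels(self) -> list[str]:
        return [f"cohort_{chr(ord('A') + i)}" for i in range(self.n_cohorts)]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (subjects x variants) plus per-variant metadata.

    ``variants`` columns: ``variant_id, chrom, pos, ref, alt, freq`` where
    ``freq`` is the alt-allele frequency (column mean / 2).
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        assert self.dosage.shape == (len(self.subject_ids), len(self.variants))

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]


class SimulatedTrajectories(NamedTuple):
    visits: pd.DataFrame
    truth: pd.DataFrame


class SimulatedCohort(NamedTuple):
    subjects: pd.DataFrame
    genotypes: GenotypeMatrix
    visits: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genotypes


def _simulate_haplotype_block(rng, n_hap: int, thresholds: np.ndarray, rho: float) -> np.ndarray:
    """Latent AR(1) Gaussians thresholded to alleles, one row per haplotype."""
    m = thresholds.size
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return (z < thresholds).astype(np.float64)


def simulate_genotype_block(
    rng: np.random.Generator, n_subjects: int, mafs: Sequence[float], latent_corr: np.ndarray
) -> np.ndarray:
    """Dosages for one LD block with an arbitrary latent correlation matrix.

    Two haplotypes per subject are drawn from a zero-mean Gaussian with the
    given correlation and thresholded at the normal quantile of each allele
    frequency, giving Hardy–Weinberg marginals with controllable LD.
    """
    mafs = np.asarray(mafs, float)
    thresholds = stats.norm.ppf(mafs)
    chol = np.linalg.cholesky(latent_corr + 1e-12 * np.eye(len(mafs)))
    z = rng.standard_normal((2 * n_subjects, len(mafs))) @ chol.T
    alleles = (z < thresholds).astype(np.float64)
    return alleles[:n_subjects] + alleles[n_subjects:]


def expected_dosage_correlation(maf1: float, maf2: float, latent_rho: float) -> float:
    """Dosage correlation implied by the copula for one latent correlation.

    Haplotypes are independent, so the dosage correlation equals the
    single-haplotype allele correlation, computed from the bivariate normal
    orthant probability.
    """
    t1, t2 = stats.norm.ppf([maf1, maf2])
    p11 = stats.multivariate_normal.cdf(
        [t1, t2], mean=[0.0, 0.0], cov=[[1.0, latent_rho], [latent_rho, 1.0]]
    )
    return (p11 - maf1 * maf2) / np.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))


def latent_rho_for_dosage_r(maf1: float, maf2: float, target_r: float) -> float:
    """Invert the copula: latent correlation giving a target dosage correlation."""
    if not -1 < target_r < 1:
        raise ConfigurationError("target dosage correlation must lie in (-1, 1)")
    f = lambda rho: expected_dosage_correlation(maf1, maf2, rho) - target_r
    return optimize.brentq(f, -0.999, 0.999, xtol=1e-10)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw the cohort genotype matrix.

    Variants come in consecutive blocks of ``ld_block_size`` with AR(1)
    latent correlation ``ld_rho``; blocks are mutually independent.  With an
    ``ancestry_fraction`` > 0, a second subject group uses allele frequencies
    shifted by ``ancestry_maf_shift`` (for genetic-PC validation only).
    """
    rng = rng_stream(config.seed, "genotypes")
    n, m = config.n_total, config.n_variants
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, m)

    n2 = int(round(config.ancestry_fraction * n))
    groups = [(n - n2, mafs)]
    if n2 > 0:
        shifted = np.clip(
            mafs + rng.choice([-1.0, 1.0], m) * config.ancestry_maf_shift, 0.01, 0.99
        )
        groups.append((n2, shifted))

    dosage = np.empty((n, m))
    row0 = 0
    for n_grp, grp_mafs in groups:
        col0 = 0
        while col0 < m:
            width = min(config.ld_block_size, m - col0)
            thr = stats.norm.ppf(grp_mafs[col0 : col0 + width])
            h1 = _simulate_haplotype_block(rng, n_grp, thr, config.ld_rho)
            h2 = _simulate_haplotype_block(rng, n_grp, thr, config.ld_rho)
            dosage[row0 : row0 + n_grp, col0 : col0 + width] = h1 + h2
            col0 += width
        row0 += n_grp

    variants = pd.DataFrame(
        {
            "variant_id": [f"snp_{j:05d}" for j in range(m)],
            "chrom": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * 10_000,
            "ref": "A",
            "alt": "G",
            "freq": dosage.mean(axis=0) / 2.0,
        }
    )
    subject_ids = [f"S{idx:05d}" for idx in range(n)]
    return GenotypeMatrix(dosage=dosage, variants=variants, subject_ids=subject_ids)


# ---------------------------------------------------------------------------
# subjects


def simulate_subjects(config: SimulationConfig) -> pd.DataFrame:
    """Draw the per-subject covariate table.

    Columns: ``subject_id, cohort, sex, age_at_onset, education_years,
    higher_education, diagnostic_certainty, carrier_status``.  The last cohort
    plays the role of a study without clinician certainty ratings (certainty
    is NaN there).
    """
    rng = rng_stream(config.seed, "subjects")
    n = config.n_total
    cohorts = np.repeat(config.cohort_labels, config.n_subjects)
    sex = (rng.random(n) < config.male_fraction).astype(int)
    onset = np.clip(
        rng.normal(config.onset_age_mean, config.onset_age_sd, n), 25.0, 95.0
    )
    edu = np.clip(rng.normal(config.education_mean, config.education_sd, n), 5.0, 16.0)
    higher = (rng.random(n) < config.higher_education_fraction).astype(int)
    certainty = np.clip(5 * np.round((100 - rng.exponential(4.0, n)) / 5), 50, 100)
    if config.n_cohorts > 1:
        certainty[cohorts == config.cohort_labels[-1]] = np.nan
    carrier = (rng.random(n) < config.carrier_rate).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"S{idx:05d}" for idx in range(n)],
            "cohort": cohorts,
            "sex": sex,
            "age_at_onset": onset,
            "education_years": edu,
            "higher_education": higher,
            "diagnostic_certainty": certainty,
            "carrier_status": carrier,
        }
    )


# ---------------------------------------------------------------------------
# trajectories


def _latent_effects(config: SimulationConfig, subjects: pd.DataFrame,
                    genotypes: GenotypeMatrix | None, rng) -> pd.DataFrame:
    """True per-subject latent intercepts and slopes for both domains."""
    n = len(subjects)
    # correlated random effects: (int_m, slope_m, int_c, slope_c)
    g = np.array(
        [[config.var_intercept, config.cov_int_slope], [config.cov_int_slope, config.var_slope]]
    )
    cov = np.zeros((4, 4))
    cov[:2, :2] = g
    cov[2:, 2:] = g
    cov[1, 3] = cov[3, 1] = config.cross_domain_corr * config.var_slope
    # keep PSD if cross-domain correlation pushes the 4x4 past the boundary
    w, v = np.linalg.eigh(cov)
    cov = (v * np.clip(w, 0, None)) @ v.T
    re = rng.multivariate_normal(np.zeros(4), cov, size=n)

    age_z = (subjects["age_at_onset"].to_numpy() - config.onset_age_mean) / config.onset_age_sd
    edu_z = (subjects["education_years"].to_numpy() - config.education_mean) / config.education_sd
    sex = subjects["sex"].to_numpy()
    carrier = subjects["carrier_status"].to_numpy()
    slope_sd = np.sqrt(config.var_slope) if config.var_slope > 0 else 1.0

    out = {}
    for d_idx, domain in enumerate(DOMAINS):
        intercept = re[:, 2 * d_idx] + config.age_intercept_beta * age_z
        slope = (
            config.mean_slope
            + re[:, 2 * d_idx + 1]
            + config.age_slope_beta * age_z
            + config.sex_slope_beta * sex
            + config.carrier_effects[d_idx] * slope_sd * carrier
        )
        if domain == "cognitive":
            slope = slope + config.education_slope_beta * edu_z
        if genotypes is not None:
            for vidx, eff_domain, eff in config.causal_effects:
                if eff_domain in (domain, "both"):
                    slope = slope + eff * slope_sd * genotypes.dosage[:, vidx]
        out[f"intercept_{domain}"] = intercept
        out[f"slope_{domain}"] = slope
    out["subject_id"] = subjects["subject_id"].to_numpy()
    return pd.DataFrame(out)


def simulate_trajectories(
    subjects: pd.DataFrame,
    genotypes: GenotypeMatrix | None,
    config: SimulationConfig,
) -> SimulatedTrajectories:
    """Generate the long-format visit table and the ground-truth table.

    Visit rows carry ``subject_id, cohort, scale_id, time_from_onset,
    time_from_entry, raw_value, ledd``.  The truth table has one row per
    subject with the latent intercepts/slopes and the entry delay.
    """
    if genotypes is not None and list(subjects["subject_id"]) != genotypes.subject_ids:
        raise ConfigurationError("subjects and genotype rows are not aligned by subject_id")
    rng = rng_stream(config.seed, "trajectories")
    n = len(subjects)
    truth = _latent_effects(config, subjects, genotypes, rng)

    # disease duration at study entry (years from self-reported onset)
    a, b = (0.1 - config.entry_delay_mean) / config.entry_delay_sd, np.inf
    delay = stats.truncnorm.rvs(
        a, b, loc=config.entry_delay_mean, scale=config.entry_delay_sd, size=n, random_state=rng
    )
    truth["entry_delay"] = delay

    # per cohort x scale measurement offsets (latent-SD units)
    offs_rng = rng_stream(config.seed, "cohort_offsets")
    offsets = {
        (c, s.scale_id): config.cohort_offset_sd * offs_rng.standard_normal()
        for c in config.cohort_labels
        for s in config.scales
    }

    times = np.asarray(config.visit_times, float)
    n_vis = times.size
    jitter = rng.normal(0.0, config.followup_sd, (n, n_vis))
    jitter[:, 0] = 0.0  # baseline anchored at study entry
    t_entry = np.clip(times[None, :] + jitter, 0.0, None)

    # monotone dropout: subject attends visits 0..K
    motor_sev = truth["intercept_motor"].to_numpy()
    drop_p = config.dropout_rate * np.ones((n, n_vis))
    if config.informative_dropout:
        drop_p = drop_p * np.exp(config.informative_dropout * motor_sev[:, None])
        drop_p = np.clip(drop_p, 0, 1)
    drops = rng.random((n, n_vis)) < drop_p
    drops[:, 0] = False
    attended = np.cumsum(drops, axis=1) == 0

    cohort = subjects["cohort"].to_numpy()
    im = truth["intercept_motor"].to_numpy()
    sm = truth["slope_motor"].to_numpy()
    ic = truth["intercept_cognitive"].to_numpy()
    sc = truth["slope_cognitive"].to_numpy()

    t_onset = delay[:, None] + t_entry  # (n, n_vis)
    sev = {
        "motor": im[:, None] + sm[:, None] * t_onset,
        "cognitive": ic[:, None] + sc[:, None] * t_onset,
    }
    ledd = np.clip(
        config.ledd_base
        + config.ledd_coef * sev["motor"]
        + rng.normal(0.0, config.ledd_sd, (n, n_vis)),
        0.0,
        None,
    )

    frames = []
    subj_ids = subjects["subject_id"].to_numpy()
    for sdef in config.scales:
        anchor, amp = SCALE_MAPS[sdef.scale_id]
        direction = 1.0 if sdef.higher_is_worse else -1.0
        noise = rng.normal(0.0, config.resid_sd, (n, n_vis)) if config.resid_sd > 0 else 0.0
        # scale-specific progression not shared with the rest of the domain
        sc_int = (
            rng.normal(0.0, config.scale_intercept_sd, n)
            if config.scale_intercept_sd > 0
            else np.zeros(n)
        )
        sc_slope = (
            rng.normal(0.0, config.scale_slope_sd, n)
            if config.scale_slope_sd > 0
            else np.zeros(n)
        )
        sev_scale = sev[sdef.domain] + sc_int[:, None] + sc_slope[:, None] * t_onset
        truth[f"slope_scale_{sdef.scale_id}"] = (
            truth[f"slope_{sdef.domain}"].to_numpy() + sc_slope
        )
        off = np.array([offsets[(c, sdef.scale_id)] for c in cohort])
        raw = anchor + amp * (direction * sev_scale + off[:, None] + noise)
        if sdef.scale_id == MOTOR_EXAM_SCALE and config.ledd_attenuation > 0:
            raw = raw - config.ledd_attenuation * ledd
        raw = np.clip(raw, sdef.min, sdef.max if sdef.max is not None else np.inf)
        missing = rng.random((n, n_vis)) < config.missing_rate
        keep = attended & ~missing
        ii, jj = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subj_ids[ii],
                    "cohort": cohort[ii],
                    "scale_id": sdef.scale_id,
                    "time_from_onset": t_onset[ii, jj],
                    "time_from_entry": t_entry[ii, jj],
                    "raw_value": raw[ii, jj],
                    "ledd": ledd[ii, jj],
                }
            )
        )
    visits = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["subject_id", "scale_id", "time_from_onset"], kind="stable")
        .reset_index(drop=True)
    )
    return SimulatedTrajectories(visits=visits, truth=truth)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full synthetic study: genotypes, subjects, visits, and truth."""
    genotypes = simulate_genotypes(config)
    subjects = simulate_subjects(config)
    visits, truth = simulate_trajectories(subjects, genotypes, config)
    return SimulatedCohort(subjects, genotypes, visits, truth, config)
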