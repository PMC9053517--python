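"""Targeted analyses and sensitivity procedures.

Covers the genetic risk score built from external case-control weights,
linear-regression tests of arbitrary subject-level predictors (carrier
status, risk scores, single candidate variants) against the progression
scores, the two misdiagnosis filters (clinician diagnostic certainty,
extreme-progressor trimming), and the medication sensitivity adjustment that
reconstructs untreated motor-exam severity from the levodopa-equivalent
daily dose before harmonization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import PipelineError
from .gwas import CovariateSet, _wald_scan
from .scales import MOTOR_EXAM_SCALE, ScaleDefinition, scales_by_id
from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


@dataclass
class AssociationResult:
    """One predictor's linear-regression association with one score."""

    predictor: str
    beta: float
    se: float
    p: float
    n: int


def genetic_risk_score(
    genotypes: GenotypeMatrix,
    weights: pd.DataFrame,
    standardize: bool = False,
) -> pd.Series:
    """Weighted effect-allele dosage sum per subject.

    ``weights`` columns: ``variant_id, effect_allele, weight`` (log odds-ratio
    scale).  When the effect allele is the ref allele the dosage is flipped to
    2 - d; rows whose effect allele matches neither allele are reported and
    skipped.  Strand-ambiguous A/T and C/G variants are flagged but included.
    """
    meta = genotypes.variants.set_index("variant_id")
    score = np.zeros(genotypes.n_subjects)
    matched = 0
    unmatched: list[str] = []
    for row in weights.itertuples():
        vid = row.variant_id
        if vid not in meta.index:
            unmatched.append(vid)
            continue
        ref, alt = meta.loc[vid, "ref"], meta.loc[vid, "alt"]
        if frozenset((ref, alt)) in _AMBIGUOUS:
            logger.warning("genetic_risk_score: %s is strand-ambiguous (%s/%s); included", vid, ref, alt)
        col = genotypes.variants.index[genotypes.variants["variant_id"] == vid][0]
        d = genotypes.dosage[:, col]
        if row.effect_allele == alt:
            eff = d
        elif row.effect_allele == ref:
            eff = 2.0 - d
        else:
            unmatched.append(vid)
            continue
        score = score + row.weight * eff
        matched += 1
    if unmatched:
        logger.warning("genetic_risk_score: %d weight rows unmatched: %s", len(unmatched), unmatched)
    if matched == 0:
        raise PipelineError("no weight row matched the genotype data")
    out = pd.Series(score, index=pd.Index(genotypes.subject_ids, name="subject_id"), name="grs")
    if standardize:
        out = (out - out.mean()) / out.std(ddof=1)
    return out


def score_association(
    predictor: pd.Series,
    scores: pd.Series,
    covariates: CovariateSet | None = None,
    name: str | None = None,
) -> AssociationResult:
    """OLS of a progression score on one predictor plus covariates.

    The same Wald machinery as the GWAS is used, so feeding a single dosage
    column reproduces that variant's GWAS row exactly.
    """
    common = predictor.dropna().index.intersection(scores.dropna().index)
    if len(common) == 0:
        raise PipelineError("no overlapping subjects")
    x = predictor.loc[common].to_numpy(float)
    if np.ptp(x) == 0:
        raise PipelineError(f"predictor {name or predictor.name!r} is constant")
    y = scores.loc[common].to_numpy(float)
    cov = covariates or CovariateSet()
    c = cov.matrix(common).to_numpy(float)
    beta, se, tstat, p, n_used = _wald_scan(y, x[:, None], c)
    return AssociationResult(
        predictor=name or str(predictor.name), beta=float(beta[0]), se=float(se[0]),
        p=float(p[0]), n=int(n_used[0]),
    )


def filter_by_certainty(subjects: pd.DataFrame, threshold_percent: float = 90.0) -> pd.DataFrame:
    """Drop subjects whose recorded diagnostic certainty is below the threshold.

    Subjects with no recorded certainty (e.g. a cohort that never collected
    it) are retained, with a warning when none at all carry a rating.
    """
    if not 0 <= threshold_percent <= 100:
        raise PipelineError("threshold must lie in [0, 100]")
    cert = subjects["diagnostic_certainty"]
    if cert.isna().all():
        logger.warning("filter_by_certainty: no certainty ratings recorded; nothing filtered")
        return subjects.reset_index(drop=True)
    keep = cert.isna() | (cert >= threshold_percent)
    n_removed = int((~keep).sum())
    logger.info("filter_by_certainty: removed %d subjects below %.0f%%", n_removed, threshold_percent)
    return subjects.loc[keep].reset_index(drop=True)


def trim_extremes(scores: pd.Series, fraction_per_tail: float = 0.05) -> pd.Series:
    """Remove the ceil(fraction*n) fastest and slowest progressors per tail.

    Operates on one named score at a time (each GWAS trims on its own score's
    distribution).  Ties at the cut are broken by subject order, which is
    deterministic for a fixed input.
    """
    if not 0 <= fraction_per_tail < 0.5:
        raise PipelineError("fraction_per_tail must lie in [0, 0.5)")
    s = scores.dropna()
    k = math.ceil(fraction_per_tail * len(s))
    if k == 0:
        return s
    order = np.argsort(s.to_numpy(), kind="stable")
    keep = order[k : len(s) - k]
    return s.iloc[np.sort(keep)]


def ledd_adjust(
    visits: pd.DataFrame,
    attenuation: float,
    scale: ScaleDefinition | None = None,
    scales=None,
) -> pd.DataFrame:
    """Reconstruct untreated motor-exam severity before harmonization.

    Medication lowers the observed motor examination score, and dose tracks
    the underlying severity, so entering dose as a covariate would adjust
    away part of the outcome itself; instead the observed value is corrected
    to ``observed + attenuation * LEDD`` on the motor-exam scale only.
    Visits with no recorded LEDD pass through unchanged with an
    ``ledd_adjusted`` flag of False; values pushed outside the scale range
    are clipped with a logged count.
    """
    if attenuation < 0:
        raise PipelineError("attenuation must be >= 0")
    if scale is None:
        scale = scales_by_id(scales)[MOTOR_EXAM_SCALE] if scales else scales_by_id()[MOTOR_EXAM_SCALE]
    df = visits.copy()
    mask = (df["scale_id"] == scale.scale_id) & df["ledd"].notna()
    df["ledd_adjusted"] = False
    df.loc[mask, "ledd_adjusted"] = True
    n_missing = int(((df["scale_id"] == scale.scale_id) & df["ledd"].isna()).sum())
    if n_missing:
        logger.warning("ledd_adjust: %d motor-exam visits lack LEDD; passed through", n_missing)
    adj = df.loc[mask, "raw_value"] + attenuation * df.loc[mask, "ledd"]
    lo, hi = scale.min, np.inf if scale.max is None else scale.max
    n_clip = int(((adj < lo) | (adj > hi)).sum())
    if n_clip:
        logger.info("ledd_adjust: clipped %d adjusted values into [%s, %s]", n_clip, lo, scale.max)
    df.loc[mask, "raw_value"] = np.clip(adj, lo, hi)
    return df
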