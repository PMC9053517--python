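"""Composite, motor, and cognitive progression scores from slope PCA.

Subject random slopes for the clinical variables are zero-centered, scaled to
unit variance (i.e. a correlation-matrix PCA), and the first principal
component is taken as the progression score for the domain: motor PCA over
the three motor scales, cognitive PCA over the three cognitive measures, and
a composite PCA pooling all six.  Because a principal component's sign is
arbitrary, an explicit orientation convention is applied afterwards via an
anchor variable whose loading sign is fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.decomposition import PCA

from ._util import PipelineError
from .scales import DEFAULT_SCALES

logger = logging.getLogger(__name__)

#: default orientation anchors: (anchor variable, required loading sign).
#: With unflipped harmonized scales, worse motor function loads positively on
#: the motor exam and worse cognition loads negatively on MoCA.
DEFAULT_ANCHORS = {
    "motor": ("updrs3", +1),
    "cognitive": ("moca", -1),
    "composite": ("updrs3", +1),
}


class OrientationError(PipelineError):
    """The anchor variable has a (numerically) zero PC1 loading."""


@dataclass
class ProgressionScore:
    """PC1 scores for one domain, with loadings and variance explained."""

    domain: str
    scores: pd.Series              # indexed by subject_id, mean 0
    loadings: pd.Series            # unit-norm PC1 loadings, indexed by variable
    variance_explained: float      # fraction carried by PC1
    all_variance_explained: np.ndarray
    n_subjects: int


def compute_domain_pca(slope_matrix: pd.DataFrame, variables, domain: str = "domain") -> ProgressionScore:
    """Correlation-matrix PCA of the listed slope columns, complete cases only.

    Raises on fewer than 2 variables, fewer than 2 complete-case subjects, or
    a constant column (named in the error).
    """
    variables = list(variables)
    if len(variables) < 2:
        raise PipelineError(f"{domain}: PCA needs >=2 variables, got {len(variables)}")
    missing_cols = [v for v in variables if v not in slope_matrix.columns]
    if missing_cols:
        raise PipelineError(f"{domain}: variables absent from slope matrix: {missing_cols}")
    mat = slope_matrix[variables].dropna()
    if len(mat) < 2:
        raise PipelineError(f"{domain}: fewer than 2 complete-case subjects")
    sds = mat.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise PipelineError(f"{domain}: constant slope column(s): {constant}")
    x = (mat - mat.mean()) / sds
    pca = PCA(svd_solver="full").fit(x.to_numpy())
    evr = pca.explained_variance_ratio_
    if len(evr) > 1 and abs(pca.explained_variance_[0] - pca.explained_variance_[1]) < 1e-8:
        logger.warning("%s: near-degenerate leading eigenvalues; PC1 direction is fragile", domain)
    loadings = pd.Series(pca.components_[0], index=variables)
    scores = pd.Series(x.to_numpy() @ loadings.to_numpy(), index=mat.index, name=domain)
    return ProgressionScore(
        domain=domain,
        scores=scores - scores.mean(),
        loadings=loadings,
        variance_explained=float(evr[0]),
        all_variance_explained=evr,
        n_subjects=len(mat),
    )


def orient_score(score: ProgressionScore, anchor_variable: str, anchor_sign: int) -> ProgressionScore:
    """Fix the arbitrary PC1 sign so the anchor loading has the requested sign."""
    if anchor_variable not in score.loadings.index:
        raise OrientationError(f"anchor {anchor_variable!r} not among PCA variables")
    loading = score.loadings[anchor_variable]
    if abs(loading) < 1e-12:
        raise OrientationError(f"anchor {anchor_variable!r} has zero loading; cannot orient")
    if np.sign(loading) == np.sign(anchor_sign):
        return score
    return replace(score, scores=-score.scores, loadings=-score.loadings)


def correlate_domains(motor_scores: pd.Series, cognitive_scores: pd.Series):
    """Pearson correlation of two domain scores over the subject intersection."""
    common = motor_scores.dropna().index.intersection(cognitive_scores.dropna().index)
    if len(common) < 3:
        raise PipelineError(f"only {len(common)} overlapping subjects; need >=3")
    r, p = sp_stats.pearsonr(motor_scores.loc[common], cognitive_scores.loc[common])
    return float(r), float(p)


def compute_progression_scores(
    slope_matrix: pd.DataFrame,
    scales=DEFAULT_SCALES,
    anchors: dict | None = None,
    direction_flipped: bool = False,
) -> tuple[pd.DataFrame, dict[str, ProgressionScore]]:
    """Motor, cognitive, and composite PC1 scores from the slope matrix.

    The composite PCA pools all motor and cognitive slope columns jointly
    (complete cases across the six).  When the harmonization stage flipped
    scale directions, cognitive anchors flip sign accordingly.

    Returns a (subjects x {motor, cognitive, composite}) table — NaN where a
    subject lacks complete data for a domain — and the per-domain PCA details.
    """
    if anchors is None:
        anchors = dict(DEFAULT_ANCHORS)
        if direction_flipped:
            anchors = {
                d: (var, abs(sign)) for d, (var, sign) in anchors.items()
            }  # all-worse-positive data: anchor loadings positive
    groups = {
        "motor": [s.scale_id for s in scales if s.domain == "motor"],
        "cognitive": [s.scale_id for s in scales if s.domain == "cognitive"],
    }
    groups["composite"] = groups["motor"] + groups["cognitive"]
    results: dict[str, ProgressionScore] = {}
    for domain, variables in groups.items():
        variables = [v for v in variables if v in slope_matrix.columns]
        res = compute_domain_pca(slope_matrix, variables, domain=domain)
        var, sign = anchors[domain]
        results[domain] = orient_score(res, var, sign)
        logger.info(
            "%s PCA: PC1 explains %.1f%% over %d subjects (anchor %s %s)",
            domain, 100 * res.variance_explained, res.n_subjects, var, "+" if sign > 0 else "-",
        )
    table = pd.DataFrame({d: r.scores for d, r in results.items()})
    table.index.name = "subject_id"
    return table, results
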