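"""Per-scale linear mixed models and extraction of subject random slopes.

Each harmonized scale is regressed on age at onset, sex, cohort, and their
interactions with time from symptom onset (education terms are added for
cognitive scales), with correlated subject-level random intercepts and random
slopes on time.  The model is estimated by REML; the posterior-mean (BLUP)
random slope per subject is the measure of residual progression — the rate of
change not predicted by the fixed covariates — and is what downstream PCA
consumes.

Noise-free degenerate inputs (observations lying exactly on subject-specific
lines) are detected up front: the REML objective is unbounded there, while
the BLUP limit is exactly the per-subject least-squares deviation from the
fixed-effect slope, which is returned directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._util import PipelineError
from .scales import DEFAULT_SCALES, ScaleDefinition

logger = logging.getLogger(__name__)

#: pooled within-subject OLS residual SD below this fraction of the response SD
#: triggers the noise-free limit path.
_NOISE_FREE_TOL = 1e-8


@dataclass
class MixedModelSpec:
    """Model structure for one scale's mixed-effects fit.

    Time enters as a fixed main effect, interacted with every fixed covariate,
    and as a correlated subject-level random slope; the random part always
    also carries a subject intercept.
    """

    response: str
    covariates: tuple[str, ...] = ("age_c", "sex", "cohort")
    education_covariates: bool = False       # add edu_c and higher_education
    education_interactions: bool = True      # ... also interacted with time
    time_variable: str = "time_from_onset"
    diagonal_covariance: bool = False        # force independent intercept/slope

    def fixed_terms(self) -> list[str]:
        cov = ["C(cohort)" if c == "cohort" else c for c in self.covariates]
        if self.education_covariates:
            cov = cov + ["edu_c", "higher_education"]
        terms = ["time"]
        for i, c in enumerate(cov):
            interact = True
            if c in ("edu_c", "higher_education") and not self.education_interactions:
                interact = False
            terms.append(c)
            if interact:
                terms.append(f"time:{c}")
        return terms

    def formula(self) -> str:
        return "z_value ~ " + " + ".join(self.fixed_terms())


@dataclass
class SlopeFit:
    """One column of the slope matrix plus model diagnostics."""

    scale_id: str
    slopes: pd.Series                 # BLUP random slopes, indexed by subject_id
    converged: bool
    method: str                       # "reml" | "reml-diagonal" | "noise-free-limit"
    var_intercept: float
    var_slope: float
    cov_int_slope: float
    resid_var: float
    n_subjects: int
    n_obs: int
    n_dropped_covariates: int
    loglike: float = np.nan
    fixed_effects: pd.Series | None = field(default=None, repr=False)


def spec_for_scale(scale: ScaleDefinition) -> MixedModelSpec:
    return MixedModelSpec(response=scale.scale_id, education_covariates=scale.cognitive_covariates_required)


def _prepare_frame(std_visits: pd.DataFrame, subjects: pd.DataFrame, spec: MixedModelSpec):
    df = std_visits.loc[std_visits["scale_id"] == spec.response].copy()
    keep_cols = [c for c in subjects.columns if c not in df.columns or c == "subject_id"]
    df = df.merge(subjects[keep_cols], on="subject_id", how="left")
    df["time"] = df[spec.time_variable]
    needed = ["z_value", "time"]
    if "age_c" in spec.covariates:
        df["age_c"] = df["age_at_onset"] - df["age_at_onset"].mean()
    if spec.education_covariates:
        df["edu_c"] = df["education_years"] - df["education_years"].mean()
        needed += ["edu_c", "higher_education"]
    needed += [c for c in spec.covariates]
    complete = df[needed].notna().all(axis=1)
    n_dropped = int(df.loc[~complete, "subject_id"].nunique())
    if n_dropped:
        logger.info("%s: dropping %d subjects with incomplete covariates", spec.response, n_dropped)
    df = df.loc[complete].reset_index(drop=True)
    # largest cohort as reference level
    if "cohort" in spec.covariates and df["cohort"].nunique() > 1:
        ref = df.groupby("cohort")["subject_id"].nunique().idxmax()
        levels = [ref] + sorted(set(df["cohort"]) - {ref})
        df["cohort"] = pd.Categorical(df["cohort"], categories=levels)
    return df, n_dropped


def _noise_free_slopes(df: pd.DataFrame, spec: MixedModelSpec):
    """Exact limit when observations sit on per-subject lines.

    Per-subject OLS lines are fit, then the subject slopes are regressed on
    the subject-level interaction covariates; the residuals are the random
    slopes (the REML/BLUP limit as the residual variance tends to zero in a
    balanced design).
    Returns None when the data are not noise-free.
    """
    g = df.groupby("subject_id")
    stats_rows = {}
    sse = 0.0
    for sid, sub in g:
        t, z = sub["time"].to_numpy(), sub["z_value"].to_numpy()
        if len(sub) >= 2 and np.ptp(t) > 0:
            a = np.column_stack([np.ones_like(t), t])
            coef, res, *_ = np.linalg.lstsq(a, z, rcond=None)
            sse += float(res[0]) if len(res) else float(((z - a @ coef) ** 2).sum())
            stats_rows[sid] = coef[1]
    if not stats_rows:
        return None
    z_sd = df["z_value"].std()
    if z_sd == 0 or np.sqrt(sse / len(df)) > _NOISE_FREE_TOL * max(z_sd, 1.0):
        return None
    per_subj = pd.Series(stats_rows)
    subj_df = df.drop_duplicates("subject_id").set_index("subject_id").loc[per_subj.index]
    x_cols = [np.ones(len(per_subj))]
    for c in spec.covariates:
        if c == "cohort":
            if subj_df["cohort"].nunique() > 1:
                dummies = pd.get_dummies(subj_df["cohort"], drop_first=True)
                for dc in dummies.columns:
                    x_cols.append(dummies[dc].to_numpy(float))
        else:
            x_cols.append(subj_df[c].to_numpy(float))
    if spec.education_covariates and spec.education_interactions:
        x_cols.append(subj_df["edu_c"].to_numpy(float))
        x_cols.append(subj_df["higher_education"].to_numpy(float))
    x = np.column_stack(x_cols)
    coef, *_ = np.linalg.lstsq(x, per_subj.to_numpy(), rcond=None)
    resid = per_subj.to_numpy() - x @ coef
    return pd.Series(resid, index=per_subj.index, name="slope"), float(np.var(resid, ddof=1))


def fit_random_slopes(
    std_visits: pd.DataFrame,
    subjects: pd.DataFrame,
    spec: MixedModelSpec,
) -> SlopeFit:
    """Fit one scale's mixed model and return the BLUP random slopes.

    Non-convergence is reported in the ``converged`` flag and diagnostics,
    never by silently dropping the column; a singular 2x2 random-effect
    covariance triggers a refit with independent intercept and slope.
    """
    df, n_dropped = _prepare_frame(std_visits, subjects, spec)
    if df.empty:
        raise PipelineError(f"{spec.response}: no usable observations")

    nf = _noise_free_slopes(df, spec)
    if nf is not None:
        slopes, var_slope = nf
        return SlopeFit(
            scale_id=spec.response, slopes=slopes, converged=True, method="noise-free-limit",
            var_intercept=np.nan, var_slope=var_slope, cov_int_slope=np.nan, resid_var=0.0,
            n_subjects=df["subject_id"].nunique(), n_obs=len(df), n_dropped_covariates=n_dropped,
        )

    formula = spec.formula()
    model = smf.mixedlm(formula, df, groups=df["subject_id"], re_formula="~time")
    method, singular = "reml", False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        if spec.diagonal_covariance:
            free = MixedLMParams.from_components(
                fe_params=np.ones(len(model.exog_names)), cov_re=np.eye(2)
            )
            result = model.fit(reml=True, method="lbfgs", free=free)
            cov_re = result.cov_re.to_numpy()
            method = "reml-diagonal"
            eig = np.array([1.0])  # skip the singular-refit branch below
        else:
            result = model.fit(reml=True, method="lbfgs")
            cov_re = result.cov_re.to_numpy()
            eig = np.linalg.eigvalsh(cov_re)
        if eig.min() < 1e-8 * max(eig.max(), 1e-12):
            # boundary fit: drop the intercept-slope correlation and refit
            free = MixedLMParams.from_components(
                fe_params=np.ones(len(result.fe_params)), cov_re=np.eye(2)
            )
            result = model.fit(reml=True, method="lbfgs", free=free)
            cov_re = result.cov_re.to_numpy()
            method, singular = "reml-diagonal", True

    re = result.random_effects
    slopes = pd.Series({sid: eff.iloc[1] for sid, eff in re.items()}, name="slope")
    return SlopeFit(
        scale_id=spec.response,
        slopes=slopes,
        converged=bool(result.converged),
        method=method,
        var_intercept=float(cov_re[0, 0]),
        var_slope=float(cov_re[1, 1]),
        cov_int_slope=float(cov_re[0, 1]),
        resid_var=float(result.scale),
        n_subjects=df["subject_id"].nunique(),
        n_obs=len(df),
        n_dropped_covariates=n_dropped,
        loglike=float(result.llf),
        fixed_effects=result.fe_params,
    )


def export_slope_matrix(fits: dict[str, SlopeFit]) -> pd.DataFrame:
    """Align converged slope columns into a subjects x scales matrix.

    Subjects missing from a column get NaN there but keep their row; columns
    whose model did not converge are excluded.  Raises PipelineError when no
    column converged.
    """
    good = {sid: f for sid, f in fits.items() if f.converged}
    bad = sorted(set(fits) - set(good))
    if bad:
        logger.warning("slope matrix: dropping non-converged columns %s", bad)
    if not good:
        raise PipelineError("no converged slope columns")
    mat = pd.DataFrame({sid: f.slopes for sid, f in good.items()})
    mat.index.name = "subject_id"
    return mat


def fit_all_scales(
    std_visits: pd.DataFrame,
    subjects: pd.DataFrame,
    scales=DEFAULT_SCALES,
) -> tuple[pd.DataFrame, dict[str, SlopeFit]]:
    """Fit every scale present in the data; return (slope matrix, diagnostics)."""
    fits: dict[str, SlopeFit] = {}
    present = set(std_visits["scale_id"])
    for sdef in scales:
        if sdef.scale_id not in present:
            logger.warning("scale %s absent from visits; skipped", sdef.scale_id)
            continue
        fits[sdef.scale_id] = fit_random_slopes(std_visits, subjects, spec_for_scale(sdef))
    return export_slope_matrix(fits), fits
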