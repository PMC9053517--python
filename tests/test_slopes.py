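"""Random-slope extraction: exact limits, shrinkage, and the Henderson oracle."""

import numpy as np
import pandas as pd
import pytest

from pdprog._util import PipelineError
from pdprog.harmonize import harmonize
from pdprog.simulate import SimulationConfig, simulate_cohort
from pdprog.slopes import MixedModelSpec, SlopeFit, export_slope_matrix, fit_random_slopes


def long_frame(times, intercepts, slopes, noise_sd=0.0, rng=None):
    """Balanced per-subject lines, one synthetic 'updrs3' column."""
    rows = []
    for i, (b0, b1) in enumerate(zip(intercepts, slopes)):
        for t in times:
            eps = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
            rows.append((f"s{i:03d}", "A", "updrs3", t, t, b0 + b1 * t + eps))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "cohort", "scale_id", "time_from_onset", "time_from_entry", "z_value"],
    )


def subjects_frame(n):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "cohort": "A",
            "sex": 0,
            "age_at_onset": 64.0,
            "education_years": 11.0,
            "higher_education": 0,
        }
    )


def henderson_blups(df, var_int, var_slope, cov_is, resid_var):
    """Hand-coded mixed-model-equations solver for z ~ time with per-subject
    random intercept+slope of known covariance; returns BLUP slopes."""
    subjects = sorted(df["subject_id"].unique())
    n_sub = len(subjects)
    t = df["time_from_onset"].to_numpy()
    y = df["z_value"].to_numpy()
    x = np.column_stack([np.ones(len(df)), t])
    z = np.zeros((len(df), 2 * n_sub))
    for k, sid in enumerate(subjects):
        mask = (df["subject_id"] == sid).to_numpy()
        z[mask, 2 * k] = 1.0
        z[mask, 2 * k + 1] = t[mask]
    g = np.kron(np.eye(n_sub), np.array([[var_int, cov_is], [cov_is, var_slope]]))
    g_inv = np.linalg.inv(g)
    top = np.hstack([x.T @ x, x.T @ z])
    bottom = np.hstack([z.T @ x, z.T @ z + resid_var * g_inv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([x.T @ y, z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    b = sol[2:].reshape(n_sub, 2)
    return pd.Series(b[:, 1], index=subjects)


class TestNoiseFreeLimit:
    def test_exact_ols_slopes_recovered(self):
        rng = np.random.default_rng(0)
        n = 50
        slopes_true = rng.normal(0.2, 0.1, n)
        df = long_frame(np.arange(5.0), rng.normal(0, 1, n), slopes_true)
        fit = fit_random_slopes(df, subjects_frame(n), MixedModelSpec("updrs3", covariates=()))
        assert fit.method == "noise-free-limit"
        expected = slopes_true - slopes_true.mean()  # OLS slope minus fixed prediction
        np.testing.assert_allclose(fit.slopes.sort_index().to_numpy(), expected, atol=1e-6)

    def test_covariate_prediction_subtracted(self):
        rng = np.random.default_rng(1)
        n = 60
        subj = subjects_frame(n)
        subj["age_at_onset"] = rng.normal(64, 10, n)
        subj["sex"] = rng.integers(0, 2, n)
        dev = rng.normal(0, 0.1, n)
        slopes_true = 0.2 + 0.02 * (subj["age_at_onset"] - subj["age_at_onset"].mean()) + 0.05 * subj["sex"] + dev
        df = long_frame(np.arange(4.0), rng.normal(0, 1, n), slopes_true.to_numpy())
        fit = fit_random_slopes(df, subj, MixedModelSpec("updrs3", covariates=("age_c", "sex")))
        # independent check: OLS of per-subject slopes on the covariates
        x = np.column_stack([
            np.ones(n),
            (subj["age_at_onset"] - subj["age_at_onset"].mean()).to_numpy(),
            subj["sex"].to_numpy(float),
        ])
        coef, *_ = np.linalg.lstsq(x, slopes_true.to_numpy(), rcond=None)
        expected = pd.Series(slopes_true.to_numpy() - x @ coef, index=subj["subject_id"])
        np.testing.assert_allclose(
            fit.slopes.sort_index().to_numpy(), expected.sort_index().to_numpy(), atol=1e-6
        )


@pytest.fixture(scope="module")
def noisy_fit():
    rng = np.random.default_rng(2)
    n, times = 80, np.arange(5.0)
    b0 = rng.normal(0, 1, n)
    b1 = rng.normal(0.2, 0.15, n)
    df = long_frame(times, b0, b1, noise_sd=0.25, rng=rng)
    fit = fit_random_slopes(df, subjects_frame(n), MixedModelSpec("updrs3", covariates=()))
    return df, fit, b1


class TestReml:
    def test_blups_match_henderson_oracle(self, noisy_fit):
        df, fit, _ = noisy_fit
        assert fit.converged and fit.method == "reml"
        oracle = henderson_blups(df, fit.var_intercept, fit.var_slope, fit.cov_int_slope, fit.resid_var)
        np.testing.assert_allclose(fit.slopes.sort_index().to_numpy(), oracle.to_numpy(), atol=1e-6)

    def test_aggregate_shrinkage_below_ols_dispersion(self, noisy_fit):
        df, fit, _ = noisy_fit
        ols = df.groupby("subject_id").apply(
            lambda s: np.polyfit(s["time_from_onset"], s["z_value"], 1)[0], include_groups=False
        )
        dev = ols - fit.fixed_effects["time"]
        assert fit.slopes.var() < dev.var()

    def test_componentwise_shrinkage_bound_with_diagonal_covariance(self):
        # centered balanced times + independent intercept/slope decouple the
        # mixed-model equations, so each predicted slope is a pure contraction
        # of the per-subject OLS slope deviation
        rng = np.random.default_rng(21)
        n, times = 60, np.arange(5.0) - 2.0
        df = long_frame(times, rng.normal(0, 1, n), rng.normal(0.2, 0.15, n),
                        noise_sd=0.3, rng=rng)
        fit = fit_random_slopes(
            df, subjects_frame(n),
            MixedModelSpec("updrs3", covariates=(), diagonal_covariance=True),
        )
        assert fit.method == "reml-diagonal"
        ols = df.groupby("subject_id").apply(
            lambda s: np.polyfit(s["time_from_onset"], s["z_value"], 1)[0], include_groups=False
        )
        dev = (ols - fit.fixed_effects["time"]).reindex(fit.slopes.index)
        assert (fit.slopes.abs() <= dev.abs() + 1e-8).all()

    def test_constant_shift_changes_intercepts_not_slopes(self, noisy_fit):
        df, fit, _ = noisy_fit
        shifted = df.assign(z_value=df["z_value"] + 5.0)
        fit2 = fit_random_slopes(shifted, subjects_frame(80), MixedModelSpec("updrs3", covariates=()))
        np.testing.assert_allclose(
            fit2.slopes.sort_index(), fit.slopes.sort_index(), atol=1e-5
        )
        assert fit2.fixed_effects["Intercept"] == pytest.approx(fit.fixed_effects["Intercept"] + 5, abs=1e-4)

    def test_true_slopes_recovered_with_noise(self, noisy_fit):
        _, fit, b1 = noisy_fit
        extracted = fit.slopes.sort_index().to_numpy()
        assert np.corrcoef(extracted, b1 - b1.mean())[0, 1] > 0.75


def test_zero_slope_variance_shrinks_towards_zero():
    rng = np.random.default_rng(3)
    n, times = 150, np.arange(5.0)
    df = long_frame(times, rng.normal(0, 1, n), np.zeros(n), noise_sd=0.8, rng=rng)
    fit = fit_random_slopes(df, subjects_frame(n), MixedModelSpec("updrs3", covariates=()))
    ols = df.groupby("subject_id").apply(
        lambda s: np.polyfit(s["time_from_onset"], s["z_value"], 1)[0], include_groups=False
    )
    assert fit.slopes.var() < 0.10 * ols.var()


def test_covariate_orthogonality_on_simulated_cohort():
    cfg = SimulationConfig(n_subjects=250, n_cohorts=2, n_variants=4, seed=12,
                           age_slope_beta=0.05, sex_slope_beta=0.05)
    coh = simulate_cohort(cfg)
    std = harmonize(coh.visits)
    fit = fit_random_slopes(std, coh.subjects, MixedModelSpec("updrs3"))
    subj = coh.subjects.set_index("subject_id").loc[fit.slopes.index]
    for col in ("age_at_onset", "sex"):
        r = np.corrcoef(fit.slopes.to_numpy(), subj[col].to_numpy(float))[0, 1]
        assert abs(r) < 0.08


def test_single_visit_subjects_are_retained():
    rng = np.random.default_rng(4)
    n = 40
    df = long_frame(np.arange(4.0), rng.normal(0, 1, n), rng.normal(0.2, 0.1, n),
                    noise_sd=0.3, rng=rng)
    solo = pd.DataFrame(
        [["solo", "A", "updrs3", 1.0, 1.0, 0.5]], columns=df.columns
    )
    subj = pd.concat([subjects_frame(n), subjects_frame(1).assign(subject_id="solo")])
    fit = fit_random_slopes(pd.concat([df, solo]), subj, MixedModelSpec("updrs3", covariates=()))
    assert "solo" in fit.slopes.index
    assert np.isfinite(fit.slopes["solo"])


class TestExportMatrix:
    def _fit(self, scale_id, subjects, converged=True):
        return SlopeFit(
            scale_id=scale_id, slopes=pd.Series(1.0, index=subjects), converged=converged,
            method="reml", var_intercept=1, var_slope=0.04, cov_int_slope=0, resid_var=0.1,
            n_subjects=len(subjects), n_obs=4 * len(subjects), n_dropped_covariates=0,
        )

    def test_single_column(self):
        mat = export_slope_matrix({"updrs3": self._fit("updrs3", ["a", "b"])})
        assert mat.shape == (2, 1)

    def test_partial_overlap_keeps_rows_with_mask(self):
        mat = export_slope_matrix(
            {"updrs3": self._fit("updrs3", ["a", "b"]), "moca": self._fit("moca", ["b", "c"])}
        )
        assert mat.shape == (3, 2)
        assert np.isnan(mat.loc["a", "moca"]) and np.isnan(mat.loc["c", "updrs3"])
        assert mat.notna().sum().sum() == 4

    def test_nonconverged_columns_excluded(self):
        mat = export_slope_matrix(
            {"updrs3": self._fit("updrs3", ["a"]), "moca": self._fit("moca", ["a"], converged=False)}
        )
        assert list(mat.columns) == ["updrs3"]

    def test_no_converged_columns_raises(self):
        with pytest.raises(PipelineError):
            export_slope_matrix({"moca": self._fit("moca", ["a"], converged=False)})
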