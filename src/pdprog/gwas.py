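"""Covariate-adjusted single-variant association of progression scores.

Each variant's dosage is tested in an ordinary least-squares regression of the
progression score on dosage + intercept + covariates (cohort indicators and
the leading genetic principal components by default), with a two-sided Wald
test.  The scan is vectorized via Frisch–Waugh–Lovell residualization, which
is algebraically identical to the per-variant joint regression; variants with
missing dosages fall back to an explicit per-variant complete-case fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from ._util import CollinearityError, PipelineError
from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = 0.4549364231195724

GENOME_WIDE_P = 5e-8


@dataclass
class CovariateSet:
    """Design-matrix builder: cohort indicators, genetic PCs, extras.

    The assembled matrix always carries an intercept; rank deficiency raises
    :class:`CollinearityError` naming the collinear columns.
    """

    cohort: pd.Series | None = None          # categorical, indexed by subject
    genetic_pcs: pd.DataFrame | None = None  # PC columns, indexed by subject
    extra: pd.DataFrame | None = None

    def matrix(self, index) -> pd.DataFrame:
        cols = {"intercept": pd.Series(1.0, index=index)}
        if self.cohort is not None:
            dummies = pd.get_dummies(self.cohort.loc[index], drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[f"cohort_{c}"] = dummies[c]
        if self.genetic_pcs is not None:
            for c in self.genetic_pcs.columns:
                cols[str(c)] = self.genetic_pcs.loc[index, c].astype(float)
        if self.extra is not None:
            for c in self.extra.columns:
                cols[str(c)] = self.extra.loc[index, c].astype(float)
        mat = pd.DataFrame(cols, index=index)
        rank = np.linalg.matrix_rank(mat.to_numpy())
        if rank < mat.shape[1]:
            # identify offending columns by greedy QR
            keep, bad = [], []
            arr = mat.to_numpy()
            for j, name in enumerate(mat.columns):
                trial = arr[:, keep + [j]]
                if np.linalg.matrix_rank(trial) == len(keep) + 1:
                    keep.append(j)
                else:
                    bad.append(name)
            raise CollinearityError(f"covariate matrix rank deficient; collinear columns: {bad}")
        return mat


def compute_genetic_pcs(genotypes: GenotypeMatrix, k: int = 5):
    """Principal components of the column-standardized dosage matrix.

    Constant variant columns are dropped (logged).  Returns (PC table indexed
    by subject_id, variance-explained array).  PCs are deterministic up to
    sign for a given input.
    """
    d = genotypes.dosage
    if not k < min(d.shape):
        raise PipelineError(f"k={k} must be < min(n_subjects, n_variants)={min(d.shape)}")
    sd = d.std(axis=0)
    keep = sd > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.info("compute_genetic_pcs: dropped %d constant variant columns", n_const)
    x = (d[:, keep] - d[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=k, svd_solver="randomized", random_state=0).fit(x)
    pcs = pca.transform(x)
    table = pd.DataFrame(
        pcs, index=pd.Index(genotypes.subject_ids, name="subject_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return table, pca.explained_variance_ratio_


def _wald_scan(y: np.ndarray, g: np.ndarray, c: np.ndarray, use_t: bool = True):
    """Vectorized per-column OLS of y on [column, c]; returns beta, se, t, p, n.

    Columns containing NaN are refit per-variant on their complete cases.
    """
    n, m = g.shape
    q, _ = np.linalg.qr(c)

    def scan_block(yb, gb, qb, n_obs):
        y_r = yb - qb @ (qb.T @ yb)
        g_r = gb - qb @ (qb.T @ gb)
        gtg = np.einsum("ij,ij->j", g_r, g_r)
        gtg = np.where(gtg <= 0, np.nan, gtg)
        beta = (g_r * y_r[:, None]).sum(axis=0) / gtg
        df = n_obs - qb.shape[1] - 1
        rss = np.maximum(y_r @ y_r - beta**2 * gtg, 0.0)
        se = np.sqrt(rss / df / gtg)
        tstat = beta / se
        if use_t:
            p = 2 * stats.t.sf(np.abs(tstat), df)
        else:
            p = 2 * stats.norm.sf(np.abs(tstat))
        return beta, se, tstat, p

    has_nan = np.isnan(g).any(axis=0)
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    p = np.full(m, np.nan)
    n_used = np.full(m, n)
    if (~has_nan).any():
        b, s, t_, p_ = scan_block(y, g[:, ~has_nan], q, n)
        beta[~has_nan], se[~has_nan], tstat[~has_nan], p[~has_nan] = b, s, t_, p_
    for j in np.nonzero(has_nan)[0]:
        ok = ~np.isnan(g[:, j])
        n_used[j] = int(ok.sum())
        qj, _ = np.linalg.qr(c[ok])
        b, s, t_, p_ = scan_block(y[ok], g[ok, j : j + 1], qj, n_used[j])
        beta[j], se[j], tstat[j], p[j] = b[0], s[0], t_[0], p_[0]
    return beta, se, tstat, p, n_used


def run_gwas(
    scores: pd.Series,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | None = None,
    maf_min: float = 0.01,
    use_t: bool = True,
) -> pd.DataFrame:
    """Single-variant Wald-test GWAS of a progression score.

    Subjects are the intersection of the score index and the genotype rows.
    Variants with minor allele frequency below ``maf_min`` are excluded (and
    counted in the log).  Returns per-variant summary statistics with columns
    ``variant_id, CHR, POS, REF, ALT, FREQ, N, BETA, SE, WALD, P`` where FREQ
    is the alt-allele frequency in the analyzed subjects, BETA is in score
    units per alt dosage, and WALD is the signed BETA/SE statistic.
    """
    scores = scores.dropna()
    geno_index = pd.Index(genotypes.subject_ids)
    common = scores.index.intersection(geno_index)
    if len(common) == 0:
        raise PipelineError("no overlapping subjects between scores and genotypes")
    y = scores.loc[common].to_numpy(float)
    rows = geno_index.get_indexer(common)
    g = genotypes.dosage[rows]

    cov = covariates or CovariateSet()
    c = cov.matrix(common).to_numpy(float)

    freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    n_excl = int((~keep).sum())
    if n_excl:
        logger.info("run_gwas: excluded %d variants with MAF < %g", n_excl, maf_min)

    beta, se, tstat, p, n_used = _wald_scan(y, g[:, keep], c, use_t=use_t)
    meta = genotypes.variants.loc[keep].reset_index(drop=True)
    return pd.DataFrame(
        {
            "variant_id": meta["variant_id"],
            "CHR": meta["chrom"],
            "POS": meta["pos"],
            "REF": meta["ref"],
            "ALT": meta["alt"],
            "FREQ": freq[keep],
            "N": n_used,
            "BETA": beta,
            "SE": se,
            "WALD": tstat,
            "P": p,
        }
    )


def genomic_lambda(summary: pd.DataFrame) -> float:
    """Genomic-control inflation factor: median Wald chi-square over the
    null chi-square(1) median, 0.4549."""
    if len(summary) < 100:
        logger.warning("genomic_lambda: only %d variants; estimate is unstable", len(summary))
    chi2 = (summary["WALD"].to_numpy() ** 2)
    return float(np.median(chi2[~np.isnan(chi2)]) / CHI2_1_MEDIAN)


def sex_stratified_gwas(
    scores: pd.Series,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet,
    sex: pd.Series,
    maf_min: float = 0.01,
    min_stratum_n: int = 50,
) -> dict[str, pd.DataFrame]:
    """Run the GWAS separately in males (sex==1) and females (sex==0).

    Sex must not be among the covariates (it is constant within a stratum).
    Strata below ``min_stratum_n`` subjects return an empty, flagged table.
    """
    out: dict[str, pd.DataFrame] = {}
    for label, code in (("male", 1), ("female", 0)):
        ids = sex.index[sex == code]
        sub = scores.loc[scores.index.intersection(ids)]
        if len(sub) < min_stratum_n:
            logger.warning("sex_stratified_gwas: %s stratum has n=%d < %d; skipped",
                           label, len(sub), min_stratum_n)
            out[label] = pd.DataFrame(
                columns=["variant_id", "CHR", "POS", "REF", "ALT", "FREQ", "N", "BETA", "SE", "WALD", "P"]
            )
            out[label].attrs["flag"] = f"stratum below minimum n ({len(sub)} < {min_stratum_n})"
            continue
        out[label] = run_gwas(sub, genotypes, covariates, maf_min=maf_min)
    return out
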