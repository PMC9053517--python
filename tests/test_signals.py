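"""Conditional analysis, stepwise signal selection, and the gene-based test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_genotypes, ols_oracle
from pdprog._util import CollinearityError, PipelineError, rng_stream
from pdprog.gwas import run_gwas
from pdprog.signals import (
    GeneRegion,
    conditional_scan,
    gene_based_test,
    read_regions_bed,
    stepwise_select,
)
from pdprog.simulate import latent_rho_for_dosage_r, simulate_genotype_block


def ld_genotypes(rng, n, mafs, dosage_r):
    """Block with target pairwise dosage correlations given as a matrix."""
    m = len(mafs)
    latent = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            if dosage_r[i][j] != 0:
                latent[i, j] = latent[j, i] = latent_rho_for_dosage_r(mafs[i], mafs[j], dosage_r[i][j])
    d = simulate_genotype_block(rng, n, mafs, latent)
    return make_genotypes(d)


def series_for(g, values):
    return pd.Series(np.asarray(values, float), index=g.subject_ids)


class TestConditionalScan:
    def test_zero_ld_conditioning_equals_marginal(self):
        rng = np.random.default_rng(0)
        n = 800
        g = make_genotypes(rng.binomial(2, 0.3, size=(n, 4)).astype(float))
        y = series_for(g, rng.normal(size=n) + 0.3 * g.dosage[:, 2])
        marginal = run_gwas(y, g, maf_min=0.0)
        cond = conditional_scan(y, g, None, ["snp_00000"])
        # conditioning variant is near-orthogonal; betas shift only by its
        # sampling correlation with the test dosages
        merged = cond.merge(marginal, on="variant_id", suffixes=("_c", "_m"))
        np.testing.assert_allclose(merged["BETA_c"], merged["BETA_m"], atol=0.05)

    def test_conditioning_on_exactly_orthogonal_variant_is_identical(self):
        rng = np.random.default_rng(1)
        n = 300
        d = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        # force exact orthogonality of column 0 to the others and the phenotype
        y_raw = rng.normal(size=n)
        basis = np.column_stack([np.ones(n), d[:, 1:], y_raw])
        d0 = d[:, 0] - basis @ np.linalg.lstsq(basis, d[:, 0], rcond=None)[0]
        d[:, 0] = d0
        g = make_genotypes(d)
        y = series_for(g, y_raw)
        marginal = run_gwas(y, g, maf_min=-np.inf)
        cond = conditional_scan(y, g, None, ["snp_00000"])
        merged = cond.merge(marginal, on="variant_id", suffixes=("_c", "_m"))
        np.testing.assert_allclose(merged["BETA_c"], merged["BETA_m"], atol=1e-8)

    def test_conditioning_on_causal_removes_proxy_signal(self):
        rng = rng_stream(2, "ld-sim")
        n = 1500
        g = ld_genotypes(rng, n, [0.3, 0.3], [[0, np.sqrt(0.8)], [np.sqrt(0.8), 0]])
        y = series_for(g, 0.3 * g.dosage[:, 0] + rng.standard_normal(n))
        marginal = run_gwas(y, g, maf_min=0.0)
        assert marginal.loc[1, "P"] < 5e-8  # proxy genome-wide significant
        cond = conditional_scan(y, g, None, ["snp_00000"])
        assert cond.set_index("variant_id").loc["snp_00001", "P"] > 0.05

    def test_conditional_equals_joint_regression_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(40, 100))
            d = rng.binomial(2, rng.uniform(0.2, 0.5), size=(n, 3)).astype(float)
            g = make_genotypes(d)
            y = series_for(g, rng.normal(size=n) + 0.2 * d[:, 0])
            cond = conditional_scan(y, g, None, ["snp_00002"]).set_index("variant_id")
            for j, vid in ((0, "snp_00000"), (1, "snp_00001")):
                beta, se, _ = ols_oracle(y.to_numpy(), [d[:, j], np.ones(n), d[:, 2]])
                assert cond.loc[vid, "BETA"] == pytest.approx(beta[0], rel=1e-8, abs=1e-12)
                assert cond.loc[vid, "SE"] == pytest.approx(se[0], rel=1e-8)

    def test_collinear_conditioned_pair_raises(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.4, size=(200, 3)).astype(float)
        d[:, 1] = d[:, 0]
        g = make_genotypes(d)
        with pytest.raises(CollinearityError, match="snp_00000.*snp_00001"):
            conditional_scan(series_for(g, rng.normal(size=200)), g, None,
                             ["snp_00000", "snp_00001"])


class TestStepwise:
    def test_no_signal_returns_empty_selection(self):
        rng = np.random.default_rng(5)
        g = make_genotypes(rng.binomial(2, 0.3, size=(300, 10)).astype(float))
        sel, joint = stepwise_select(series_for(g, rng.normal(size=300)), g, None)
        assert sel == [] and joint.empty

    def test_two_independent_causals_both_selected(self):
        rng = np.random.default_rng(6)
        n = 2000
        g = make_genotypes(rng.binomial(2, 0.3, size=(n, 8)).astype(float))
        b = {2: 0.3, 5: -0.35}
        y = rng.normal(size=n)
        for j, beta in b.items():
            y = y + beta * g.dosage[:, j]
        sel, joint = stepwise_select(series_for(g, y), g, None)
        assert set(sel) == {"snp_00002", "snp_00005"}
        joint = joint.set_index("variant_id")
        assert joint.loc["snp_00002", "BETA"] == pytest.approx(0.3, rel=0.15)
        assert joint.loc["snp_00005", "BETA"] == pytest.approx(-0.35, rel=0.15)

    def test_causal_with_tight_proxy_selects_single_signal(self):
        rng = rng_stream(7, "ld-sim")
        n = 2000
        r = np.sqrt(0.9)
        g = ld_genotypes(rng, n, [0.3, 0.3], [[0, r], [r, 0]])
        y = series_for(g, 0.35 * g.dosage[:, 0] + rng.standard_normal(n))
        sel, _ = stepwise_select(y, g, None)
        assert len(sel) == 1


class TestGeneBased:
    def test_single_variant_gene_matches_variant_p(self):
        rng = np.random.default_rng(8)
        n = 500
        g = make_genotypes(rng.binomial(2, 0.4, size=(n, 1)).astype(float))
        y = series_for(g, rng.normal(size=n) + 0.08 * g.dosage[:, 0])
        single = run_gwas(y, g, maf_min=0.0, use_t=False)
        region = [GeneRegion("GENE1", "1", 1, 20_000)]
        out = gene_based_test(y, g, None, region, n_null=400_000, seed=0, maf_min=0.0)
        assert out.loc[0, "P"] == pytest.approx(single.loc[0, "P"], abs=0.01)

    def test_statistic_is_hand_summed_chi2(self):
        rng = np.random.default_rng(9)
        n = 300
        g = make_genotypes(rng.binomial(2, 0.4, size=(n, 3)).astype(float))
        y = series_for(g, rng.normal(size=n))
        summary = run_gwas(y, g, maf_min=0.0)
        out = gene_based_test(y, g, None, [GeneRegion("G", "1", 1, 40_000)],
                              n_null=5000, seed=1, maf_min=0.0)
        assert out.loc[0, "stat"] == pytest.approx(float((summary["WALD"] ** 2).sum()), abs=1e-9)

    def test_gene_p_monotone_in_effect_size(self):
        rng = rng_stream(10, "ld-sim")
        n = 500
        r = 0.5
        mat = [[0, r, r], [r, 0, r], [r, r, 0]]
        g = ld_genotypes(rng, n, [0.3, 0.3, 0.3], mat)
        noises = [rng.standard_normal(n) for _ in range(8)]
        mean_ps = []
        for eff in (0.0, 0.25, 0.6):
            ps = []
            for noise in noises:
                y = series_for(g, noise + eff * g.dosage[:, 0])
                out = gene_based_test(y, g, None, [GeneRegion("G", "1", 1, 40_000)],
                                      n_null=20_000, seed=2, maf_min=0.0)
                ps.append(out.loc[0, "P"])
            mean_ps.append(np.mean(ps))
        assert mean_ps[0] > mean_ps[1] > mean_ps[2]

    def test_null_gene_pvalues_uniform_with_ld(self):
        rng = rng_stream(11, "ld-sim")
        n, n_genes, m_per = 400, 60, 5
        blocks, regions = [], []
        for k in range(n_genes):
            latent = 0.8 ** np.abs(np.subtract.outer(np.arange(m_per), np.arange(m_per)))
            blocks.append(simulate_genotype_block(rng, n, [0.3] * m_per, latent))
            lo = k * m_per
            regions.append(GeneRegion(f"G{k}", "1", (lo + 1) * 10_000, (lo + m_per) * 10_000))
        g = make_genotypes(np.hstack(blocks))
        y = series_for(g, rng.standard_normal(n))
        out = gene_based_test(y, g, None, regions, n_null=3000, seed=3, maf_min=0.0)
        assert len(out) == n_genes
        assert stats.kstest(out["P"], "uniform").pvalue > 0.01

    def test_empty_region_omitted(self):
        rng = np.random.default_rng(12)
        g = make_genotypes(rng.binomial(2, 0.4, size=(100, 2)).astype(float))
        y = series_for(g, rng.normal(size=100))
        out = gene_based_test(
            y, g, None,
            [GeneRegion("HAS", "1", 1, 30_000), GeneRegion("EMPTY", "2", 1, 10)],
            n_null=2000, seed=4, maf_min=0.0,
        )
        assert list(out["gene_id"]) == ["HAS"]

    def test_all_regions_empty_raises(self):
        rng = np.random.default_rng(13)
        g = make_genotypes(rng.binomial(2, 0.4, size=(50, 2)).astype(float))
        with pytest.raises(PipelineError):
            gene_based_test(series_for(g, rng.normal(size=50)), g, None,
                            [GeneRegion("EMPTY", "9", 1, 10)], n_null=100)


def test_bed_regions_converted_to_one_based_inclusive(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("track name=test\n1\t999\t2000\tGENE1\n2\t0\t100\n")
    regions = read_regions_bed(bed)
    assert regions[0] == GeneRegion("GENE1", "1", 1000, 2000)
    assert regions[1].start == 1 and regions[1].end == 100


def test_gene_region_validation():
    with pytest.raises(PipelineError):
        GeneRegion("bad", "1", 10, 5)
    with pytest.raises(PipelineError):
        GeneRegion("bad", "1", 1, 5, flank=-1)
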