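import numpy as np
import pandas as pd
import pytest

from pdprog.simulate import GenotypeMatrix, SimulationConfig, simulate_cohort


def make_genotypes(dosage: np.ndarray, mafs=None) -> GenotypeMatrix:
    """Wrap a plain dosage array in genotype metadata for unit tests."""
    n, m = dosage.shape
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
    return GenotypeMatrix(
        dosage=dosage.astype(float),
        variants=variants,
        subject_ids=[f"S{idx:05d}" for idx in range(n)],
    )


def ols_oracle(y, x_cols):
    """Brute-force normal-equations OLS: returns (beta, se, t) for every column.

    Deliberately naive (explicit X'X inverse) so it shares no code path with
    the package's residualization-based scan.
    """
    x = np.column_stack(x_cols)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = resid @ resid / (len(y) - x.shape[1])
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return beta, se, beta / se


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_subjects=150, n_cohorts=3, n_variants=60, seed=7)
    return simulate_cohort(cfg)
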