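import numpy as np
import pytest

from sparsemr.data import OutcomeStats, SnpExposureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_exposures(rng):
    """10 SNPs x 3 exposures with mild correlation and honest SEs."""
    p, K = 10, 3
    base = rng.normal(0.3, 0.05, size=p)
    gamma = np.column_stack([base + rng.normal(0, 0.05, p) for _ in range(K)])
    se = rng.uniform(0.02, 0.08, size=(p, K))
    return SnpExposureMatrix(
        [f"rs{i}" for i in range(p)], [f"X{k + 1}" for k in range(K)], gamma, se
    )


@pytest.fixture
def small_outcome(small_exposures, rng):
    p = small_exposures.n_snps
    Gamma = small_exposures.gamma @ np.array([0.4, 0.0, 0.0]) + rng.normal(0, 0.02, p)
    se = rng.uniform(0.01, 0.05, size=p)
    return OutcomeStats(list(small_exposures.snp_ids), Gamma, se)


@pytest.fixture
def two_block_exposures(rng):
    """12 SNPs x 6 exposures; SNP block b drives exposure block b only."""
    p, K = 12, 6
    gamma = rng.normal(0, 0.02, size=(p, K))
    gamma[:6, :3] += np.abs(rng.normal(0.5, 0.1, size=(6, 3)))
    gamma[6:, 3:] += np.abs(rng.normal(0.5, 0.1, size=(6, 3)))
    se = np.full((p, K), 0.05)
    return SnpExposureMatrix(
        [f"rs{i}" for i in range(p)], [f"X{k + 1}" for k in range(K)], gamma, se
    )
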