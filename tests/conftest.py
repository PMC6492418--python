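import numpy as np
import pytest

from sparseherit import SimulationScenario, simulate_dataset
from sparseherit.io import GenotypeData


@pytest.fixture
def small_panel() -> GenotypeData:
    """A tiny handwritten genotype panel (3 samples x 2 SNPs, one missing)."""
    from sparseherit.io import MISSING

    Z = np.array([[0, 2], [1, MISSING], [2, 1]], dtype=np.int8)
    return GenotypeData(
        Z=Z,
        snp_ids=np.array(["rs1", "rs2"]),
        chrom=np.array(["1", "1"]),
        pos=np.array([100, 200]),
        a1=np.array(["A", "C"]),
        a2=np.array(["G", "T"]),
        sample_ids=np.array(["s1", "s2", "s3"]),
    )


@pytest.fixture(scope="session")
def sparse_cohort():
    """A seeded cohort with 10 strong causal SNPs (session-wide reuse)."""
    scenario = SimulationScenario(m=400, n=600, s=10, sigma_e2=0.25, seed=11)
    return simulate_dataset(scenario)
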