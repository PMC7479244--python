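import numpy as np
import pandas as pd
import pytest

from rrbsdiff.core import CountMatrix, SampleRecord
from rrbsdiff.pipeline import small_simulation_config
from rrbsdiff.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """One reduced-scale simulated cohort shared across tests (seed fixed)."""
    cfg = small_simulation_config(seed=11)
    bundle, fragments, cohort = simulate_cohort(cfg)
    return bundle, fragments, cohort


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    _, _, cohort = small_sim
    return cohort.count_matrix(merge_strands=True).filter_cpg10(10)


@pytest.fixture
def toy_matrix():
    """Tiny hand-built count matrix: 3 sites x 4 samples, 2 groups."""
    sites = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"], "pos": [99, 199, 49]})
    samples = [
        SampleRecord("A1", "bullA1", "HM", 15),
        SampleRecord("A2", "bullA2", "HM", 15),
        SampleRecord("B1", "bullB1", "MM", 15),
        SampleRecord("B2", "bullB2", "MM", 15),
    ]
    meth = np.array([[9, 8, 1, 0], [12, 11, 12, 11], [0, 0, 0, 0]])
    total = np.array([[12, 10, 10, 11], [12, 12, 12, 12], [9, 10, 0, 15]])
    return CountMatrix(sites, samples, meth, total)
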