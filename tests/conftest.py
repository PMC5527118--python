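import numpy as np
import pandas as pd
import pytest

from onsetmod import syndata
from onsetmod.gio import GenotypeMatrix


def make_matrix(dosage, samples=None, chrom=None, pos=None):
    """Small GenotypeMatrix straight from a dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    samples = samples or [f"s{i}" for i in range(n)]
    chrom = chrom or ["1"] * m
    pos = pos or [1000 * (j + 1) for j in range(m)]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "allele_minor": "A", "allele_major": "G"},
        index=pd.Index([f"m{j}" for j in range(m)], name="marker"))
    return GenotypeMatrix(samples, markers, dosage)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = syndata.SimulationConfig(n_families=60, markers=120, seed=7,
                                   missing_rate=0.01)
    return syndata.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def selected_cohort():
    """200-family cohort with 95+95 extreme probands selected."""
    cfg = syndata.SimulationConfig(n_families=200, markers=2000, seed=3)
    co = syndata.simulate_cohort(cfg)
    co.pedigree = syndata.rank_and_select_extremes(co, 95, 0)
    return co
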