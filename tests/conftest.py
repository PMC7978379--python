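import numpy as np
import pandas as pd
import pytest

from alleleburst.synthetic import PopulationSpec, generate_population, sample_kinetics_cloud


@pytest.fixture(scope="session")
def small_homogeneous():
    """120 genes x 400 cells, identical allelic kinetics, no missing data."""
    spec = PopulationSpec(n_genes=120, n_cells=400, seed=11)
    m_cast, m_c57, truth = generate_population(spec)
    return m_cast, m_c57, truth


@pytest.fixture(scope="session")
def kinetics_long(small_homogeneous):
    """Generating kinetics of the homogeneous fixture in the long table schema."""
    _, _, truth = small_homogeneous
    kin = truth["kinetics"]
    return kin.loc[kin["subpopulation"] == 0, ["gene_id", "allele", "k_on", "k_off", "k_syn"]]


@pytest.fixture(scope="session")
def kinetics_cloud():
    return sample_kinetics_cloud(50, seed=7)
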