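import numpy as np
import pandas as pd
import pytest

from peagain.simdata import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """3 connected populations x 40 lines, 300 markers, moderate GEI."""
    cfg = SimConfig(
        seed=11,
        n_markers=300,
        lines_per_pop=40,
        n_qtl=40,
        gei_sd_ratio=0.5,
        h2_per_env={"env1": 0.6, "env2": 0.6, "env3": 0.6},
    )
    genotypes, phenotypes, traits = simulate_study(cfg)
    return cfg, genotypes, phenotypes, traits


@pytest.fixture(scope="session")
def small_geno(small_study):
    return small_study[1]


@pytest.fixture(scope="session")
def small_pheno(small_study):
    return small_study[2]


@pytest.fixture(scope="session")
def line_means(small_study):
    return small_study[2].line_means("trait")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
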