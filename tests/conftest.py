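import warnings

import pytest

from regprof.alignment import blosum62_scheme, simple_dna_scheme
from regprof.regulon import load_regulon_table, packaged_table1_path
from regprof.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def scheme():
    return blosum62_scheme()


@pytest.fixture(scope="session")
def dna_scheme():
    return simple_dna_scheme()


@pytest.fixture(scope="session")
def table1_network():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the known duplicated locus tag
        return load_regulon_table(packaged_table1_path())


@pytest.fixture(scope="session")
def panel_identical():
    """Scaled panel, 50% retention, zero divergence (orthologs verbatim)."""
    cfg = SimConfig.scaled_default(retention=0.5, divergence=0.0, n_families=10, seed=42)
    return cfg, *simulate(cfg)


@pytest.fixture(scope="session")
def panel_diverged():
    """Scaled panel, 50% retention, 0.05 substitutions/site per branch."""
    cfg = SimConfig.scaled_default(retention=0.5, divergence=0.05, n_families=10, seed=42)
    return cfg, *simulate(cfg)
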