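import warnings

import pytest

from syncom_metatx.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small but fully featured community: duplicates, paralogs, host genes."""
    return SimConfig(
        n_strains=4,
        genes_per_strain=30,
        n_orthogroups=20,
        frac_interstrain_duplicate=0.1,
        frac_within_strain_paralog=0.1,
        gene_length_range=(150, 250),
        reads_per_sample=20_000,
        n_host_genes=5,
        de_fraction=0.1,
        amplicon_dropout=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_all(tiny_config)
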