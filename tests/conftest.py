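import pytest

from ighvkit.simulate import (
    SimParams,
    load_toy_db,
    load_toy_jdb,
    simulate_subject,
)


@pytest.fixture(scope="session")
def toy_db():
    return load_toy_db()


@pytest.fixture(scope="session")
def toy_jdb():
    return load_toy_jdb()


@pytest.fixture(scope="session")
def small_truth(toy_db):
    """A 30-allele subject with 20% novel alleles, fixed seed."""
    params = SimParams(n_alleles=30, novel_fraction=0.2, n_repertoire_reads=0)
    return simulate_subject(toy_db, params, seed=101, subject_id="TS1")
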