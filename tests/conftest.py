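import pytest

import netfrail as nf
from netfrail.cohort import PathwayNetwork, sample_frailness


@pytest.fixture(scope="session")
def path3():
    """Path graph 1 - 2 - 3."""
    return nf.Network.from_edges([("1", "2"), ("2", "3")])


@pytest.fixture(scope="session")
def ts_path3(path3):
    return nf.build_transition_system(path3)


@pytest.fixture(scope="session")
def k20():
    return nf.make_complete_network(20)


@pytest.fixture(scope="session")
def ts_k20(k20):
    return nf.build_transition_system(k20)


@pytest.fixture(scope="session")
def er8():
    """Small dense connected fixture used for exhaustive sweeps."""
    return nf.make_random_network("erdos_renyi", 8, seed=3, p=0.45)


@pytest.fixture(scope="session")
def ts_er8(er8):
    return nf.build_transition_system(er8)


@pytest.fixture(scope="session")
def er15():
    return nf.make_random_network("erdos_renyi", 15, seed=11, p=0.3)


@pytest.fixture(scope="session")
def ts_er15(er15):
    return nf.build_transition_system(er15)


@pytest.fixture(scope="session")
def ppi_like():
    """Scale-free core plus 8 marginal (degree-1) genes."""
    return nf.make_ppi_like_network(n_core=24, n_leaves=8, seed=5)


@pytest.fixture(scope="session")
def pathway(ppi_like):
    return PathwayNetwork("W", frozenset(ppi_like.labels), ppi_like)


@pytest.fixture(scope="session")
def ts_ppi(pathway):
    return pathway.transition_system()


@pytest.fixture(scope="session")
def trend_cohort(pathway, ts_ppi):
    """Cohort sized to populate the co-mutation bins m* = 1..5.

    400 samples with a 6% mean background rate give tens of samples per bin;
    returns (muts, sample_rho).
    """
    spec = nf.CohortSpec(n_genes=pathway.size, n_samples=400, seed=7,
                         tail_mean=0.06)
    muts = nf.make_mutation_cohort(spec, pathway.network)
    sr = sample_frailness(pathway, muts, ts=ts_ppi)
    return muts, sr


@pytest.fixture(scope="session")
def planted_cohort(pathway, ts_ppi):
    """Cohort with the driver + marginal-gene co-mutation signal planted."""
    spec = nf.CohortSpec(n_genes=pathway.size, n_samples=150, seed=1,
                         tail_mean=0.03, planted_effect=True)
    muts = nf.make_mutation_cohort(spec, pathway.network)
    sr = sample_frailness(pathway, muts, ts=ts_ppi)
    return muts, sr

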