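from __future__ import annotations

import numpy as np
import pytest

import ssnmap as m

# Study conditions reused across tests: the five-subgroup superfamily at
# the default divergences, and the two-subgroup family with a planted
# four-step linker chain.

CHAIN_CONFIG = dict(
    n_subgroups=2,
    subgroup_sizes=(15, 15),
    fused=(True, True),
    within_divergence=0.1,
    between_divergence=1.2,
    linker_chain_length=4,
    linker_subgroups=(0, 1),
    non_pro1_fraction=0.0,
)

#: E-value threshold for the linker-chain study networks (chain edges are
#: designed to be orders of magnitude more significant, two-hop shortcuts
#: orders of magnitude less).
CHAIN_THRESHOLD = 1e-9


@pytest.fixture(scope="session")
def family():
    return m.generate_superfamily(m.GeneratorConfig(rng_seed=42))


@pytest.fixture(scope="session")
def family_edges(family):
    return m.all_by_all(family.records)


@pytest.fixture(scope="session")
def family_network(family, family_edges):
    return m.build_representative_network(family.records, family_edges, 0.5)


@pytest.fixture(scope="session")
def chain_family():
    return m.generate_superfamily(m.GeneratorConfig(rng_seed=0, **CHAIN_CONFIG))


@pytest.fixture(scope="session")
def chain_network(chain_family):
    edges = m.all_by_all(chain_family.records)
    net = m.build_representative_network(chain_family.records, edges, 0.5)
    return m.apply_threshold(net, CHAIN_THRESHOLD)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
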