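import numpy as np
import pytest

from protofibril.builder import (build_extended_glucan, build_topology,
                                 build_tower)
from protofibril.forcefield import load_tables


@pytest.fixture(scope="session")
def tables():
    return load_tables()


@pytest.fixture(scope="session")
def cellobiose():
    """Two-residue chain (45 atoms) with its topology."""
    chain = build_extended_glucan(2)
    topo = build_topology(chain.system, chain.bonds)
    return chain.system, topo


@pytest.fixture(scope="session")
def hexamer_tower():
    """Six 6-mer chains on the 4 nm anchor circle (774 atoms)."""
    chains = [build_extended_glucan(6, chain_index=i) for i in range(6)]
    return build_tower(chains)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
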