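import numpy as np
import pytest

import latticegel as lg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_pair():
    """One S and one P monomer on L = 2: the enumeration oracle's system."""
    return lg.generate_fixture("tiny-enumerable", 0)


@pytest.fixture
def bound_chain():
    """Ten divalent molecules with one bound chain of three (phi_c = 0.3)."""
    return lg.generate_fixture("bound-chain", 0)


@pytest.fixture
def dense_ball():
    """900/1000 single-bead molecules in a radius-10 ball inside L = 100."""
    return lg.generate_fixture("dense-ball", 0)


@pytest.fixture
def frc_chain_system():
    """A divalent implicit-linker chain plus one P monomer on L = 3."""
    s_chain = lg.MoleculeTopology.uniform("S2", "S", 2, linker_n=1)
    p_mono = lg.MoleculeTopology.uniform("P1", "P", 1)
    return lg.build_system(lg.LatticeConfig(3), [(s_chain, 1), (p_mono, 1)], seed=5)


@pytest.fixture
def explicit_chain_system():
    """A divalent one-explicit-bead chain plus one P monomer on L = 3."""
    s_exp = lg.MoleculeTopology.uniform("SX", "S", 2, linker_n=1, linker_e=1)
    p_mono = lg.MoleculeTopology.uniform("P1", "P", 1)
    return lg.build_system(lg.LatticeConfig(3), [(s_exp, 1), (p_mono, 1)], seed=6)
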