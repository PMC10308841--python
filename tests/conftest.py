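import numpy as np
import pytest

import pathmorph as pm
from pathmorph import fixtures as fx


@pytest.fixture(scope="session")
def polyala_helix():
    return fx.make_polyalanine(10, *fx.HELIX)


@pytest.fixture(scope="session")
def polyala_extended():
    return fx.make_polyalanine(10, *fx.EXTENDED)


@pytest.fixture(scope="session")
def helix_extended_pair(polyala_helix, polyala_extended):
    """Extended conformer superposed onto the helix on Cα, ready to morph."""
    sup = pm.superpose(polyala_extended, polyala_helix, "name CA")
    return polyala_helix, pm.apply_transform(polyala_extended,
                                            sup.rotation, sup.translation)


@pytest.fixture(scope="session")
def bead_morph():
    return fx.make_bead_morph(8)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_frame(rng, n_atoms=20):
    atoms = [pm.AtomRecord(i + 1, "CA", "C", "BEA", i + 1, "A")
             for i in range(n_atoms)]
    return pm.StructureFrame(atoms, rng.normal(scale=5.0, size=(n_atoms, 3)))
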