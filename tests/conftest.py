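import numpy as np
import pytest

from trsfx.synthetic import (apply_perturbation, asn_chi2_perturbation,
                             make_toy_crystal)
from trsfx.xtal_core import AtomModel, UnitCell


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_crystal(seed=7)


@pytest.fixture(scope="session")
def toy_light(toy_model):
    return apply_perturbation(toy_model, asn_chi2_perturbation(-86.4))


@pytest.fixture(scope="session")
def cell():
    return UnitCell(10.0, 12.0, 14.0)


@pytest.fixture
def five_atom_model(cell):
    """Small asymmetric model used for direct-summation oracles."""
    return AtomModel(
        elements=["C", "N", "O", "C", "S"],
        res_ids=np.array([1, 1, 1, 2, 2]),
        res_names=["ALA", "ALA", "ALA", "CYS", "CYS"],
        atom_names=["CA", "N", "O", "CA", "SG"],
        xyz=np.array([
            [1.0, 2.0, 3.0],
            [2.5, 3.1, 1.2],
            [4.0, 7.7, 8.3],
            [6.2, 1.1, 9.9],
            [8.4, 9.0, 5.5],
        ]),
        occ=np.array([1.0, 0.8, 1.0, 0.5, 1.0]),
        b=np.array([5.0, 10.0, 15.0, 0.0, 20.0]),
        cell=cell,
    )
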