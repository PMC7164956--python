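"""Shared fixtures for the trxdiff test suite.

The expensive session-scoped fixtures (full noiseless recovery) are computed
once and reused by the pipeline and acceptance tests.
"""

import numpy as np
import pytest

import trxdiff as t


@pytest.fixture(scope="session")
def noiseless_truth():
    """Standard reference synthetic fixture, noiseless, seed 1."""
    return t.synthetic.make_fixture()


@pytest.fixture(scope="session")
def noiseless_recovery():
    """Full recovery run on the noiseless fixture (diffmap + alpha scan + PCCs)."""
    return t.run_recovery(t.RunConfig(simulate=True, seed=1))


@pytest.fixture
def cubic_cell():
    return t.UnitCell(20.0, 20.0, 20.0)


@pytest.fixture
def three_atom_model(cubic_cell):
    """Minimal C/N/O model used by the structure-factor oracle tests."""
    atoms = [
        t.Atom("C", "C1", "LIG", 1, "A", (3.1, 4.2, 5.3), b_factor=10.0),
        t.Atom("N", "N1", "LIG", 1, "A", (7.7, 2.9, 11.0), b_factor=15.0, occupancy=0.8),
        t.Atom("O", "O1", "LIG", 1, "A", (12.4, 14.8, 6.6), b_factor=8.0),
    ]
    return t.AtomicModel(atoms=atoms, cell=cubic_cell, space_group="P 1")
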