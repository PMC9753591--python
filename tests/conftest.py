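"""Shared fixtures: small water systems built programmatically."""

import numpy as np
import pytest

from efmag.backend import Backend
from efmag.cluster import Atom, Cluster, Monomer, _water_template
from efmag.cluster import make_cyclic_water_trimer as make_cyclic_trimer
from efmag.constants import ANGSTROM_TO_BOHR

# Global-minimum water dimer geometry (Smith et al. conformation, Angstrom):
# a near-linear hydrogen bond, donor O-H pointing at the acceptor oxygen.
_SMITH_DIMER_ANG = np.array([
    [-0.702196054, -0.056060256, 0.009942262],
    [-1.022193224, 0.846775782, -0.011488714],
    [0.257521062, 0.042121496, 0.005218999],
    [2.220871067, 0.026716792, 0.000620476],
    [2.597492682, -0.411663274, 0.766744858],
    [2.593135384, -0.449496183, -0.744782026],
])
_SMITH_SYMBOLS = ["O", "H", "H", "O", "H", "H"]


def water_at(origin, rotation=None) -> Monomer:
    coords = _water_template()
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    coords = coords + np.asarray(origin, dtype=float)
    return Monomer((Atom("O", coords[0]), Atom("H", coords[1]),
                    Atom("H", coords[2])))




def far_water_pair(separation: float = 500.0) -> Cluster:
    return Cluster([water_at(np.zeros(3)),
                    water_at(np.array([0.0, 0.0, separation]))])


@pytest.fixture(scope="session")
def water_monomer() -> Cluster:
    return Cluster([water_at(np.zeros(3))])


@pytest.fixture(scope="session")
def smith_dimer() -> Cluster:
    coords = _SMITH_DIMER_ANG * ANGSTROM_TO_BOHR
    mons = [
        Monomer(tuple(Atom(s, p) for s, p in
                      zip(_SMITH_SYMBOLS[:3], coords[:3]))),
        Monomer(tuple(Atom(s, p) for s, p in
                      zip(_SMITH_SYMBOLS[3:], coords[3:]))),
    ]
    return Cluster(mons, title="water dimer (global minimum)")


@pytest.fixture(scope="session")
def trimer() -> Cluster:
    return make_cyclic_trimer()


@pytest.fixture(scope="session")
def sto3g_backend_factory():
    def factory(cluster, **kwargs) -> Backend:
        return Backend.for_cluster(cluster, basis="sto-3g", **kwargs)
    return factory
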