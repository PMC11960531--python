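import numpy as np
import pytest

from sirnakit.dataset import load_table1
from sirnakit.ensemble import Topology
from sirnakit.structure import build_duplex


@pytest.fixture(scope="session")
def pairs():
    return load_table1()


@pytest.fixture(scope="session")
def built_parent(pairs):
    """Built structure of the first parent duplex (siSER-1)."""
    return build_duplex(pairs[0].parent)


@pytest.fixture(scope="session")
def built_modified(pairs):
    return build_duplex(pairs[0].modified)


def make_topology(
    names,
    elements,
    charges=None,
    sigma=None,
    epsilon=None,
    masses=None,
    radii=None,
    resids=None,
):
    """Minimal hand-built topology for feature unit tests."""
    n = len(names)
    z = np.zeros(n)
    return Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.zeros(n, dtype=int) if resids is None else np.array(resids),
        resnames=np.array(["X"] * n, dtype=object),
        roles=np.array(["guide"] * n, dtype=object),
        positions=np.ones(n, dtype=int),
        charges=z if charges is None else np.asarray(charges, float),
        sigma=z if sigma is None else np.asarray(sigma, float),
        epsilon=z if epsilon is None else np.asarray(epsilon, float),
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        radii=np.full(n, 1.5) if radii is None else np.asarray(radii, float),
    )
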