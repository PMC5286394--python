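import numpy as np
import pytest

from emplace.density import DensityMap, simulate_density
from emplace.structures import AtomicModel
from emplace.synthetic import generate_assembly, simulate_noisy_map


def make_model(coords, chain="A", resnums=None, atomname="CA",
               subunits=None, copies=None):
    """Cα-only model from an (n, 3) array (single chain by default)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if isinstance(chain, str):
        chains = [chain] * n
    else:
        chains = list(chain)
    if resnums is None:
        resnums = []
        seen = {}
        for c in chains:
            seen[c] = seen.get(c, 0) + 1
            resnums.append(seen[c])
    return AtomicModel(
        chain=np.asarray(chains, dtype=object),
        resnum=np.asarray(resnums),
        resname=np.asarray(["ALA"] * n, dtype=object),
        atomname=np.asarray([atomname] * n, dtype=object),
        xyz=coords,
        subunit_of_chain=subunits or {},
        copy_of_chain=copies or {},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    """One compact 80-residue body, no symmetry."""
    return generate_assembly(n_bodies=1, body_size=[80], symmetry="none", seed=5)


@pytest.fixture(scope="session")
def small_map(small_truth):
    """Noisy 27 Å map of the single-body truth."""
    return simulate_noisy_map(small_truth, 27.0, 0.1, 4.0, seed=6)


@pytest.fixture(scope="session")
def two_body_truth():
    """Two distinct bodies, no symmetry — the basic placement test case."""
    return generate_assembly(n_bodies=2, body_size=[90, 55], symmetry="none",
                             seed=7)


@pytest.fixture(scope="session")
def random_map(rng):
    vals = np.random.default_rng(0).normal(size=(12, 12, 12))
    return DensityMap(values=vals, voxel=3.0, origin=(-18.0, -18.0, -18.0),
                      resolution=9.0)
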