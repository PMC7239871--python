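import numpy as np
import pytest

from nanotess.builder import CoreSpec, LigandSpec, build_c60, build_core, graft_ligands
from nanotess.structure import AtomRecord, NanoStructure


@pytest.fixture(scope="session")
def c60():
    return build_c60()


@pytest.fixture(scope="session")
def gold_core():
    return build_core(CoreSpec("fcc-Au", diameter_nm=2.0, identifier="GNP-test"))


@pytest.fixture(scope="session")
def grafted_particle(gold_core):
    return graft_ligands(gold_core, [LigandSpec("CCS", 10)], seed=7)


@pytest.fixture(scope="session")
def fixture_r1():
    """The default synthetic fixture set (recipe R1), built once per session."""
    from nanotess.fixtures import SyntheticRecipe, generate_fixture_set

    structures, dataset = generate_fixture_set(SyntheticRecipe())
    return structures, dataset


def random_structure(n: int, seed: int, elements=("C",)) -> NanoStructure:
    """Random general-position point cloud as a structure (test helper)."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-5, 5, size=(n, 3))
    els = [elements[i % len(elements)] for i in range(n)]
    atoms = [AtomRecord(i + 1, els[i], tuple(coords[i])) for i in range(n)]
    return NanoStructure(identifier=f"rand{seed}", atoms=atoms)


def brute_force_delaunay(points: np.ndarray, tol: float = 1e-9) -> set:
    """Empty-circumsphere oracle: all 4-subsets whose circumsphere holds no
    other point strictly inside.  Valid for points in general position."""
    from itertools import combinations

    n = len(points)
    tetra = set()
    for quad in combinations(range(n), 4):
        p = points[list(quad)]
        a = 2 * (p[1:] - p[0])
        b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
        try:
            center = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue  # coplanar quadruple
        r2 = ((p[0] - center) ** 2).sum()
        others = [i for i in range(n) if i not in quad]
        d2 = ((points[others] - center) ** 2).sum(axis=1)
        if np.all(d2 > r2 * (1 - tol)):
            tetra.add(tuple(sorted(quad)))
    return tetra
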