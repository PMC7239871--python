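import collections

import numpy as np
import pytest

from nanotess.builder import (
    CNTSpec,
    CoreSpec,
    CPNTSpec,
    LigandSpec,
    build_cnt,
    build_core,
    build_cpnt,
    build_from_spec,
    cnt_diameter,
    embed_ligand,
    get_lattice,
    graft_ligands,
    surface_sites,
)
from nanotess.builder.cpnt import RING_SPACING, count_amide_bonds
from nanotess.errors import (
    CapacityError,
    InvalidChiralityError,
    SmilesError,
    TooSmallCoreError,
    UnknownMaterialError,
    UnknownResidueError,
)


# ---------------------------------------------------------------------------
# crystalline cores

def brute_force_sphere_count(lattice_key: str, diameter_nm: float) -> int:
    """Independent enumeration: replicate the cell over a generous block,
    snap the carving center to the site nearest the block centroid, count
    sites within the radius."""
    lat = get_lattice(lattice_key)
    cell = lat.cell_matrix()
    frac = np.array([xyz for _, xyz in lat.sites]) % 1.0
    pts = []
    for i in range(-5, 6):
        for j in range(-5, 6):
            for k in range(-5, 6):
                pts.append((frac + [i, j, k]) @ cell)
    pts = np.vstack(pts)
    center = pts[np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1))]
    r = diameter_nm * 10 / 2
    return int(np.sum(np.linalg.norm(pts - center, axis=1) <= r + 1e-9))


def test_sphere_count_matches_brute_force_enumeration():
    for key in ("fcc-Au", "zincblende-CdSe"):
        core = build_core(CoreSpec(key, diameter_nm=1.0))
        assert core.n_atoms == brute_force_sphere_count(key, 1.0)


def test_core_atoms_lie_on_lattice():
    core = build_core(CoreSpec("fcc-Au", diameter_nm=1.5))
    lat = get_lattice("fcc-Au")
    inv = np.linalg.inv(lat.cell_matrix())
    frac = core.coordinates() @ inv * 4  # fcc sites sit on quarter-integers x4=halves
    assert np.allclose(frac * 2, np.round(frac * 2), atol=1e-6)


def test_too_small_core_rejected():
    with pytest.raises(TooSmallCoreError):
        build_core(CoreSpec("fcc-Au", diameter_nm=0.2))


def test_unknown_material_rejected():
    with pytest.raises(UnknownMaterialError):
        build_core(CoreSpec("fcc-Unobtainium", diameter_nm=2.0))


def test_volume_scaling_of_atom_count():
    small = build_core(CoreSpec("fcc-Au", diameter_nm=2.0))
    big = build_core(CoreSpec("fcc-Au", diameter_nm=4.0))
    ratio = big.n_atoms / small.n_atoms
    assert abs(ratio - 8.0) / 8.0 < 0.15


def test_rod_longer_than_sphere():
    rod = build_core(CoreSpec("fcc-Au", shape="rod", diameter_nm=1.5, length_nm=3.0))
    sphere = build_core(CoreSpec("fcc-Au", diameter_nm=1.5))
    assert rod.n_atoms > sphere.n_atoms
    z = rod.coordinates()[:, 2]
    assert (z.max() - z.min()) <= 30.0 + 4.078  # within one lattice constant
    assert rod.shape == "rod" and rod.size["length"] == 3.0


def test_min_separation_invariant(gold_core):
    from scipy.spatial.distance import pdist

    lat = get_lattice("fcc-Au")
    assert pdist(gold_core.coordinates()).min() >= 0.5 * lat.min_site_separation()


def test_size_metadata_consistent_with_extent(gold_core):
    coords = gold_core.coordinates()
    extent = 2 * np.linalg.norm(coords, axis=1).max()
    stated = gold_core.size["diameter"] * 10
    assert abs(extent - stated) <= 4.078  # one lattice constant


# ---------------------------------------------------------------------------
# carbon nanotubes

def test_cnt_diameter_matches_rollup_formula():
    cnt = build_cnt(CNTSpec(5, 5, periods=1))
    expected = 2.46 * np.sqrt(75) / np.pi  # 6.78 Å
    assert cnt_diameter(5, 5) == pytest.approx(expected, rel=1e-12)
    assert cnt.size["diameter"] * 10 == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(6.78, abs=0.005)


def test_cnt_atoms_on_common_cylinder():
    cnt = build_cnt(CNTSpec(6, 2, periods=1))
    xy = cnt.coordinates()[:, :2]
    radii = np.linalg.norm(xy - xy.mean(axis=0), axis=1)
    assert radii.max() - radii.min() < 0.01
    assert set(cnt.elements()) == {"C"}


def test_cnt_invalid_chirality():
    with pytest.raises(InvalidChiralityError):
        CNTSpec(0, 0, periods=1)


def test_cnt_three_bonded_neighbors_except_ends():
    cnt = build_cnt(CNTSpec(6, 6, periods=3))
    degree = collections.Counter()
    for b in cnt.bonds:
        degree[b.a] += 1
        degree[b.b] += 1
    z = {a.serial: a.coords[2] for a in cnt.atoms}
    zmin, zmax = min(z.values()), max(z.values())
    for serial, deg in degree.items():
        at_end = z[serial] < zmin + 1.0 or z[serial] > zmax - 1.0
        assert deg == 3 or (deg == 2 and at_end)


def test_cnt_atom_count_per_period():
    # 4 (n^2 + nm + m^2) / d_R atoms per translational period
    cnt = build_cnt(CNTSpec(5, 5, periods=2))
    assert cnt.n_atoms == 2 * 4 * 75 // 15


# ---------------------------------------------------------------------------
# cyclic peptide nanotubes

def test_cpnt_ring_closure_eight_residues():
    ring = build_cpnt(CPNTSpec("A" * 8, ring_count=1, seed=1))
    assert count_amide_bonds(ring) == 8


def test_cpnt_ring_replication_and_axial_extent():
    one = build_cpnt(CPNTSpec("AGSAV", ring_count=1, seed=2))
    three = build_cpnt(CPNTSpec("AGSAV", ring_count=3, seed=2))
    assert three.n_atoms == 3 * one.n_atoms
    per_ring = one.n_atoms
    coords = three.coordinates()
    centroids = [coords[i * per_ring : (i + 1) * per_ring].mean(axis=0) for i in range(3)]
    extent = centroids[-1][2] - centroids[0][2]
    assert abs(extent - 2 * RING_SPACING) < 0.5


def test_cpnt_unknown_residue():
    with pytest.raises(UnknownResidueError):
        build_cpnt(CPNTSpec("AXZ", ring_count=1))


# ---------------------------------------------------------------------------
# ligands

def test_embed_ligand_valence_arithmetic():
    # ethanethiol CCS: heavy atoms C,C,S; hydrogens CH3(3) + CH2(2) + SH(1) = 6
    conf = embed_ligand("CCS", seed=0)
    assert sum(e != "H" for e in conf.elements) == 3
    assert sum(e == "H" for e in conf.elements) == 6
    assert conf.elements[conf.anchor] == "S"
    # propanethiol CCCS: 4 heavy + 8 H
    conf2 = embed_ligand("CCCS", seed=0)
    assert (sum(e != "H" for e in conf2.elements), sum(e == "H" for e in conf2.elements)) == (4, 8)


def test_embed_ligand_errors_and_determinism():
    with pytest.raises(SmilesError):
        embed_ligand("")
    with pytest.raises(SmilesError):
        embed_ligand("not a smiles(((")
    a = embed_ligand("OCCS", seed=11)
    b = embed_ligand("OCCS", seed=11)
    np.testing.assert_array_equal(a.coords, b.coords)


def test_graft_zero_ligands_is_identity(gold_core):
    out = graft_ligands(gold_core, [LigandSpec("CCS", 0)], seed=0)
    assert out is gold_core


def test_graft_capacity_error(gold_core):
    n_sites = len(surface_sites(gold_core))
    with pytest.raises(CapacityError, match=str(n_sites)):
        graft_ligands(gold_core, [LigandSpec("CCS", n_sites + 1)], seed=0)


def test_graft_conservation_and_bonds(gold_core):
    conf = embed_ligand("CCS", seed=3)
    out = graft_ligands(gold_core, [LigandSpec("CCS", 20)], seed=3)
    assert out.n_atoms == gold_core.n_atoms + 20 * conf.n_atoms
    core_serials = set(gold_core.serials())
    anchor_bonds = [
        b for b in out.bonds if (b.a in core_serials) != (b.b in core_serials)
    ]
    assert len(anchor_bonds) == 20
    assert len({(b.a if b.a in core_serials else b.b) for b in anchor_bonds}) == 20


def test_graft_never_moves_core_atoms(gold_core):
    out = graft_ligands(gold_core, [LigandSpec("OCCS", 8)], seed=9)
    np.testing.assert_array_equal(
        out.coordinates()[: gold_core.n_atoms], gold_core.coordinates()
    )
    ligand_frags = {a.fragment_id for a in out.atoms[gold_core.n_atoms:]}
    assert ligand_frags == set(range(1, 9))


def test_graft_no_interligand_clashes(grafted_particle, gold_core):
    from scipy.spatial.distance import cdist

    heavy = [
        (a.fragment_id, a.coords)
        for a in grafted_particle.atoms
        if a.fragment_id > 0 and a.element != "H"
    ]
    frags = sorted({f for f, _ in heavy})
    for i, fa in enumerate(frags):
        pa = np.array([c for f, c in heavy if f == fa])
        for fb in frags[i + 1 :]:
            pb = np.array([c for f, c in heavy if f == fb])
            assert cdist(pa, pb).min() >= 1.0


def test_graft_deterministic(gold_core):
    a = graft_ligands(gold_core, [LigandSpec("CCS", 12)], seed=4)
    b = graft_ligands(gold_core, [LigandSpec("CCS", 12)], seed=4)
    np.testing.assert_array_equal(a.coordinates(), b.coordinates())


# ---------------------------------------------------------------------------
# declarative dispatch

def test_build_from_spec_dispatch():
    s = build_from_spec({"kind": "c60"})
    assert s.n_atoms == 60
    s = build_from_spec(
        {"material": "fcc-Pd", "diameter_nm": 1.2,
         "ligands": [{"smiles": "CCS", "count": 3}]},
        seed=5,
    )
    assert s.material_class == "PdNP" and s.ligands == [("CCS", 3)]
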