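"""Ligand conformer embedding and random surface grafting.

Surface sites are core atoms whose coordination number (under the covalent
distance cutoff) is below the bulk coordination of the lattice.  Grafting
samples sites uniformly at random without replacement, keeps anchors apart by
a minimum separation that shrinks as the requested count grows, orients each
ligand's principal axis along the outward surface normal, and rejects
placements that bring heavy atoms of different ligands within 1.0 Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ..elements import covalent_radius
from ..errors import CapacityError, SmilesError
from ..structure import AtomRecord, BondRecord, NanoStructure
from .cores import coordination_numbers

CLASH_CUTOFF = 1.0  # Å, minimum allowed inter-ligand heavy-atom distance


@dataclass(frozen=True)
class LigandSpec:
    """A surface ligand: SMILES, copies per particle, and the anchor rule."""

    smiles: str
    count: int
    anchor_rule: str = "auto"  # auto: thiol S, else first heteroatom, else first heavy

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("ligand count must be >= 0")


@dataclass
class LigandConformer:
    """An embedded 3D conformer with explicit hydrogens."""

    smiles: str
    elements: list[str]
    coords: np.ndarray  # (n, 3) Å
    bonds: list[tuple[int, int]]  # 0-based atom index pairs
    anchor: int  # 0-based index of the anchoring atom

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def _pick_anchor(mol, rule: str) -> int:
    if rule not in ("auto", "first_heavy"):
        raise ValueError(f"unknown anchor rule {rule!r}")
    heavy = [a for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    if rule == "auto":
        for a in heavy:
            if a.GetSymbol() == "S":
                return a.GetIdx()
        for a in heavy:
            if a.GetSymbol() != "C":
                return a.GetIdx()
    return heavy[0].GetIdx()


def embed_ligand(smiles: str, seed: int = 0, anchor_rule: str = "auto") -> LigandConformer:
    """Embed one low-energy 3D conformer of *smiles* with explicit hydrogens.

    The conformer is force-field optimized (MMFF, falling back to UFF) and is
    deterministic for a fixed seed.
    """
    if not smiles:
        raise SmilesError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise SmilesError(f"3D embedding failed for {smiles!r}")
    if AllChem.MMFFHasAllMoleculeParams(mol):
        AllChem.MMFFOptimizeMolecule(mol, maxIters=1000)
    else:
        AllChem.UFFOptimizeMolecule(mol, maxIters=1000)
    return LigandConformer(
        smiles=smiles,
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=mol.GetConformer().GetPositions().copy(),
        bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()],
        anchor=_pick_anchor(mol, anchor_rule),
    )


def surface_sites(core: NanoStructure) -> np.ndarray:
    """Indices (0-based, atom order) of surface atoms of *core*.

    An atom is a surface site when its coordination number is below the bulk
    (maximum observed) coordination; if all atoms are equivalent the whole
    particle is treated as surface.
    """
    pos = core.coordinates()
    cn = coordination_numbers(pos, core.elements())
    bulk = cn.max()
    sites = np.nonzero(cn < bulk)[0]
    return sites if len(sites) else np.arange(len(pos))


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def graft_ligands(core: NanoStructure, ligands: list[LigandSpec],
                  seed: int = 0) -> NanoStructure:
    """Randomly graft ligand copies onto the surface of *core*.

    Core atoms are never moved or deleted; each grafted copy gets a fresh
    fragment id, its anchor bonded to a distinct surface atom.
    """
    total = sum(spec.count for spec in ligands)
    if total == 0:
        return core
    sites = surface_sites(core)
    if total > len(sites):
        raise CapacityError(
            f"requested {total} ligands but only {len(sites)} surface sites available"
        )
    rng = np.random.default_rng(seed)
    pos = core.coordinates()
    center = pos.mean(axis=0)
    site_pos = pos[sites]
    radius = float(np.linalg.norm(site_pos - center, axis=1).mean())
    # anchor separation target shrinks with count (even spreading on the sphere)
    min_sep = 0.8 * np.sqrt(4 * np.pi * radius**2 / total) if total > 1 else 0.0

    conformers = {
        spec.smiles: embed_ligand(spec.smiles, seed=seed, anchor_rule=spec.anchor_rule)
        for spec in ligands if spec.count > 0
    }
    queue = [spec.smiles for spec in ligands for _ in range(spec.count)]

    chosen: list[int] = []
    while True:
        order = rng.permutation(len(sites))
        chosen = []
        for idx in order:
            p = site_pos[idx]
            if all(np.linalg.norm(p - site_pos[j]) >= min_sep for j in chosen):
                chosen.append(idx)
            if len(chosen) == total:
                break
        if len(chosen) == total or min_sep < 1.0:
            break
        min_sep *= 0.8
    if len(chosen) < total:  # min-sep could not be honored; take distinct sites anyway
        remaining = [i for i in order if i not in chosen]
        chosen += remaining[: total - len(chosen)]

    atoms = list(core.atoms)
    bonds = list(core.bonds)
    serial = max(core.serials()) + 1
    placed_heavy: list[np.ndarray] = []
    for instance, (site_idx, smiles) in enumerate(zip(chosen, queue), start=1):
        conf = conformers[smiles]
        site_serial = core.atoms[sites[site_idx]].serial
        p = site_pos[site_idx]
        normal = p - center
        normal /= np.linalg.norm(normal)
        local = conf.coords - conf.coords[conf.anchor]
        heavy_centroid = np.mean(
            [local[i] for i, e in enumerate(conf.elements) if e != "H"], axis=0
        )
        if np.linalg.norm(heavy_centroid) > 1e-8:
            rot = _rotation_onto(heavy_centroid / np.linalg.norm(heavy_centroid), normal)
            local = local @ rot.T
        bond_len = covalent_radius(core.atoms[sites[site_idx]].element) + covalent_radius(
            conf.elements[conf.anchor]
        )
        placed = None
        for _ in range(12):  # azimuthal retries to avoid inter-ligand clashes
            spin = _axis_rotation(normal, rng.uniform(0, 2 * np.pi))
            cand = local @ spin.T + p + bond_len * normal
            heavy = cand[[i for i, e in enumerate(conf.elements) if e != "H"]]
            ok = all(
                np.min(np.linalg.norm(heavy[:, None, :] - prev[None, :, :], axis=-1))
                >= CLASH_CUTOFF
                for prev in placed_heavy
            )
            if ok:
                placed = cand
                break
        if placed is None:
            placed = cand  # accept the last candidate; clash pressure was unavoidable
        placed_heavy.append(placed[[i for i, e in enumerate(conf.elements) if e != "H"]])

        index_map = {}
        for i, (el, xyz) in enumerate(zip(conf.elements, placed)):
            atoms.append(AtomRecord(serial, el, tuple(xyz), fragment_id=instance))
            index_map[i] = serial
            serial += 1
        for a, b in conf.bonds:
            bonds.append(BondRecord(index_map[a], index_map[b]))
        bonds.append(BondRecord(site_serial, index_map[conf.anchor]))

    ligand_meta = [(spec.smiles, spec.count) for spec in ligands]
    return NanoStructure(
        identifier=core.identifier,
        atoms=atoms,
        bonds=bonds,
        material_class=core.material_class,
        shape=core.shape,
        size=dict(core.size),
        ligands=ligand_meta,
    )
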