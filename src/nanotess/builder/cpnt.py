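"""Cyclic peptide nanotubes: cyclize a residue sequence, stack rings along z.

Each ring is a head-to-tail cyclic peptide assembled from the residue sequence
(SMILES built residue-by-residue, embedded and force-field optimized with
RDKit).  Rings are stacked along the tube axis at a fixed 4.8 Å spacing with
every other ring flipped, mimicking the antiparallel beta-sheet-like stacking
of cyclic peptide nanotubes; inter-ring hydrogen bonds are implied by the
geometry and not stored as bond records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ..errors import NanotessError, UnknownResidueError
from ..structure import AtomRecord, BondRecord, NanoStructure

RING_SPACING = 4.8  # Å, axial spacing between stacked rings

# side-chain SMILES attached at the alpha carbon (Gly has none, Pro is special)
_SIDE_CHAINS = {
    "A": "C", "C": "CS", "D": "CC(=O)O", "E": "CCC(=O)O", "F": "Cc1ccccc1",
    "H": "Cc1c[nH]cn1", "I": "C(C)CC", "K": "CCCCN", "L": "CC(C)C",
    "M": "CCSC", "N": "CC(N)=O", "Q": "CCC(N)=O", "R": "CCCNC(=N)N",
    "S": "CO", "T": "C(C)O", "V": "C(C)C", "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
}


def _residue_fragment(code: str, first: bool, last: bool) -> str:
    """SMILES chunk for one residue; %99 closes the macrocycle, %98 Pro's ring."""
    open_macro = "%99" if first else ""
    if code == "G":
        ca = "C"
    elif code == "P":
        return f"N{open_macro}%98CCCC%98" + ("C(=O)%99" if last else "C(=O)")
    elif code in _SIDE_CHAINS:
        ca = f"C({_SIDE_CHAINS[code]})"
    else:
        raise UnknownResidueError(f"unknown amino-acid code {code!r}")
    carbonyl = "C(=O)%99" if last else "C(=O)"
    return f"N{open_macro}{ca}{carbonyl}"


def cyclic_peptide_smiles(sequence: str) -> str:
    """Head-to-tail cyclic peptide SMILES for a one-letter residue sequence."""
    if len(sequence) < 3:
        raise NanotessError("cyclic peptide needs at least 3 residues")
    k = len(sequence)
    return "".join(
        _residue_fragment(c, i == 0, i == k - 1) for i, c in enumerate(sequence)
    )


@dataclass(frozen=True)
class CPNTSpec:
    """Residue sequence of one ring and the number of stacked rings."""

    sequence: str
    ring_count: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise NanotessError("sequence length must be >= 3")
        if self.ring_count < 1:
            raise NanotessError("ring_count must be >= 1")


def _embed_ring(sequence: str, seed: int):
    """One optimized cyclic-peptide conformer, plane-aligned to z = 0."""
    smiles = cyclic_peptide_smiles(sequence)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise NanotessError(f"could not assemble cyclic peptide for {sequence!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.useRandomCoords = True
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise NanotessError(f"3D embedding failed for cyclic peptide {sequence!r}")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)

    coords = mol.GetConformer().GetPositions()
    # macrocycle backbone = the ring of size 3 * n_residues
    rings = [r for r in mol.GetRingInfo().AtomRings() if len(r) == 3 * len(sequence)]
    backbone = list(rings[0]) if rings else list(range(mol.GetNumAtoms()))
    ring_xyz = coords[backbone]
    centroid = ring_xyz.mean(axis=0)
    coords = coords - centroid
    # rotate the best-fit ring normal onto z
    _, _, vt = np.linalg.svd(ring_xyz - centroid)
    normal = vt[2]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(np.dot(normal, z))
    if np.linalg.norm(v) > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1 / (1 + c) if c > -0.999999 else 0.0)
        coords = coords @ rot.T
    elif c < 0:
        coords = coords * np.array([1.0, -1.0, -1.0])

    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    n_amide = sum(
        1
        for b in mol.GetBonds()
        if {b.GetBeginAtom().GetSymbol(), b.GetEndAtom().GetSymbol()} == {"C", "N"}
        and b.GetBeginAtomIdx() in backbone and b.GetEndAtomIdx() in backbone
        and _is_amide(b)
    )
    return elements, coords, bonds, n_amide


def _is_amide(bond) -> bool:
    for atom, other in ((bond.GetBeginAtom(), bond.GetEndAtom()),
                        (bond.GetEndAtom(), bond.GetBeginAtom())):
        if atom.GetSymbol() == "C":
            for nb in atom.GetNeighbors():
                if nb.GetSymbol() == "O" and atom.GetOwningMol().GetBondBetweenAtoms(
                    atom.GetIdx(), nb.GetIdx()
                ).GetBondTypeAsDouble() == 2.0:
                    return True
    return False


def build_cpnt(spec: CPNTSpec) -> NanoStructure:
    """Assemble a cyclic peptide nanotube from *spec*."""
    elements, ring_coords, ring_bonds, _ = _embed_ring(spec.sequence, spec.seed)
    per_ring = len(elements)
    atoms: list[AtomRecord] = []
    bonds: list[BondRecord] = []
    flip = np.diag([1.0, -1.0, -1.0])  # alternate rings are flipped (antiparallel)
    for r in range(spec.ring_count):
        xyz = ring_coords @ flip.T if r % 2 else ring_coords.copy()
        xyz = xyz + np.array([0.0, 0.0, r * RING_SPACING])
        off = r * per_ring
        for i, (el, c) in enumerate(zip(elements, xyz)):
            atoms.append(AtomRecord(off + i + 1, el, tuple(c), fragment_id=0))
        for a, b in ring_bonds:
            bonds.append(BondRecord(off + a + 1, off + b + 1))

    coords = np.array([a.coords for a in atoms])
    span = coords.max(axis=0) - coords.min(axis=0)
    diameter_nm = float(max(span[0], span[1])) / 10.0
    length_nm = float(span[2]) / 10.0
    struct = NanoStructure(
        identifier=f"CPNT-{spec.sequence}x{spec.ring_count}",
        atoms=atoms,
        bonds=sorted(set(bonds)),
        material_class="CPNT",
        shape="tube",
        size={"diameter": round(diameter_nm, 3), "length": round(length_nm, 3)},
    )
    return struct.centered()


def count_amide_bonds(structure: NanoStructure) -> int:
    """Count C–N bonds whose carbon also bonds an oxygen (amide linkages).

    For sequences without side-chain amides (Asn/Gln) this equals the number
    of backbone peptide bonds: one per residue per ring.
    """
    element = {a.serial: a.element for a in structure.atoms}
    neighbors: dict[int, set[int]] = {}
    for b in structure.bonds:
        neighbors.setdefault(b.a, set()).add(b.b)
        neighbors.setdefault(b.b, set()).add(b.a)
    count = 0
    for b in structure.bonds:
        pair = {element[b.a], element[b.b]}
        if pair != {"C", "N"}:
            continue
        carbon = b.a if element[b.a] == "C" else b.b
        if any(element[nb] == "O" for nb in neighbors.get(carbon, ())):
            count += 1
    return count
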