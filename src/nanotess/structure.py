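"""Core in-memory containers: atoms, bonds, and annotated nanostructures."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .elements import check_element
from .errors import DuplicateSerialError, EmptyStructureError, NanotessError

MATERIAL_CLASSES = (
    "GNP", "AgNP", "PtNP", "PdNP", "CNT", "C60", "QD", "MONP",
    "DnaNP", "Dendrimer", "CPNT", "unknown",
)

SHAPES = ("sphere", "rod", "tube", "irregular", "unknown")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: serial number, element, label, fragment grouping, Å coordinates.

    ``fragment_id`` 0 marks the core; each grafted ligand instance gets its own id.
    """

    serial: int
    element: str
    coords: tuple[float, float, float]
    name: str = ""
    fragment_id: int = 0

    def __post_init__(self):
        if self.serial < 1:
            raise NanotessError(f"atom serial must be positive, got {self.serial}")
        check_element(self.element)
        if not all(np.isfinite(self.coords)):
            raise NanotessError(f"non-finite coordinates for atom {self.serial}")
        if not self.name:
            object.__setattr__(self, "name", self.element)


@dataclass(frozen=True, order=True)
class BondRecord:
    """An unordered bonded pair of atom serials, stored once with a < b."""

    a: int
    b: int

    def __post_init__(self):
        if self.a == self.b:
            raise NanotessError(f"self-bond on serial {self.a}")
        if self.a > self.b:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)


@dataclass
class NanoStructure:
    """An annotated nanomaterial structure — the PDB-serializable unit.

    ``size`` holds dimensions in nm: ``{"diameter": d}`` for spheres/tubes or
    ``{"diameter": d, "length": L}`` for rods; empty when unknown.
    ``ligands`` is a list of (SMILES, count) pairs.
    """

    identifier: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord] = field(default_factory=list)
    material_class: str = "unknown"
    shape: str = "unknown"
    size: dict = field(default_factory=dict)
    ligands: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- accessors -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of Å coordinates, in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def serials(self) -> list[int]:
        return [a.serial for a in self.atoms]

    def bond_set(self) -> set[tuple[int, int]]:
        return {(b.a, b.b) for b in self.bonds}

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.identifier!r} has no atoms")
        serials = self.serials()
        if len(set(serials)) != len(serials):
            seen, dup = set(), None
            for s in serials:
                if s in seen:
                    dup = s
                    break
                seen.add(s)
            raise DuplicateSerialError(
                f"duplicate atom serial {dup} in structure {self.identifier!r}"
            )
        known = set(serials)
        for b in self.bonds:
            if b.a not in known or b.b not in known:
                raise NanotessError(
                    f"bond ({b.a}, {b.b}) references a missing atom serial"
                )
        for smiles, count in self.ligands:
            if count < 0:
                raise NanotessError(f"negative ligand count for {smiles!r}")
        if self.material_class not in MATERIAL_CLASSES:
            raise NanotessError(f"unknown material class {self.material_class!r}")
        if self.shape not in SHAPES:
            raise NanotessError(f"unknown shape {self.shape!r}")

    # -- transforms ------------------------------------------------------

    def centered(self) -> "NanoStructure":
        """Copy with the atom centroid translated to the origin."""
        coords = self.coordinates()
        shift = coords.mean(axis=0)
        atoms = [replace(a, coords=tuple(np.asarray(a.coords) - shift)) for a in self.atoms]
        out = NanoStructure(
            identifier=self.identifier, atoms=atoms, bonds=list(self.bonds),
            material_class=self.material_class, shape=self.shape,
            size=dict(self.size), ligands=list(self.ligands),
        )
        return out

    def renumbered(self, start: int = 1) -> "NanoStructure":
        """Copy with serials renumbered consecutively from *start*."""
        mapping = {a.serial: start + i for i, a in enumerate(self.atoms)}
        atoms = [replace(a, serial=mapping[a.serial]) for a in self.atoms]
        bonds = [BondRecord(mapping[b.a], mapping[b.b]) for b in self.bonds]
        return NanoStructure(
            identifier=self.identifier, atoms=atoms, bonds=bonds,
            material_class=self.material_class, shape=self.shape,
            size=dict(self.size), ligands=list(self.ligands),
        )
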