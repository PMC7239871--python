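"""Crystalline nanoparticle cores: replicate a unit cell and carve to shape.

A core is built by replicating the conventional unit cell of the material's
most stable crystal structure into a supercell and deleting every atom outside
the target solid — a sphere of the requested diameter, or a rod modeled as a
cylinder with hemispherical caps whose total length includes the caps.  The
carving center is snapped to the lattice site nearest the supercell centroid,
so atom positions remain exact lattice vectors relative to the center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..elements import covalent_radius
from ..errors import NanotessError, TooSmallCoreError
from ..structure import AtomRecord, BondRecord, NanoStructure
from .lattices import Lattice, get_lattice


@dataclass(frozen=True)
class CoreSpec:
    """Declarative core description: material key, shape, and nm dimensions."""

    material: str
    shape: str = "sphere"  # sphere | rod
    diameter_nm: float = 2.0
    length_nm: float | None = None  # rods: total length including caps
    identifier: str = ""

    def __post_init__(self):
        if self.diameter_nm <= 0:
            raise NanotessError("diameter must be positive")
        if self.shape == "rod":
            if self.length_nm is None or self.length_nm < self.diameter_nm:
                raise NanotessError("rod length must be >= diameter")
        elif self.shape != "sphere":
            raise NanotessError(f"unsupported core shape {self.shape!r}")


def _lattice_points(lattice: Lattice, radius: float):
    """All (element, position) lattice sites within a block covering *radius*."""
    cell = lattice.cell_matrix()
    frac = np.array([xyz for _, xyz in lattice.sites], dtype=float) % 1.0
    elems = [el for el, _ in lattice.sites]
    # interplanar heights give the replication count per axis
    inv = np.linalg.inv(cell)
    heights = 1.0 / np.linalg.norm(inv, axis=0)
    counts = np.ceil(radius / heights).astype(int) + 1
    shifts = np.array(
        [[i, j, k]
         for i in range(-counts[0], counts[0] + 1)
         for j in range(-counts[1], counts[1] + 1)
         for k in range(-counts[2], counts[2] + 1)],
        dtype=float,
    )
    pos = (shifts[:, None, :] + frac[None, :, :]).reshape(-1, 3) @ cell
    elements = np.array(elems * len(shifts))
    return elements, pos


def carve_positions(lattice: Lattice, shape: str, diameter_a: float,
                    length_a: float | None = None):
    """Return (elements, positions) of lattice points inside the target solid."""
    if shape == "sphere":
        reach = diameter_a / 2
    else:
        reach = length_a / 2
    elements, pos = _lattice_points(lattice, reach + max(lattice.lengths))

    center = pos[np.argmin(np.linalg.norm(pos - pos.mean(axis=0), axis=1))]
    rel = pos - center
    r = diameter_a / 2
    if shape == "sphere":
        keep = np.linalg.norm(rel, axis=1) <= r + 1e-9
    else:
        # cylinder along z with hemispherical caps; total length = length_a
        h = length_a / 2 - r
        z = np.clip(rel[:, 2], -h, h)
        axis_pt = np.zeros_like(rel)
        axis_pt[:, 2] = z
        keep = np.linalg.norm(rel - axis_pt, axis=1) <= r + 1e-9
    return elements[keep], rel[keep]


def build_core(spec: CoreSpec, connect: bool = False) -> NanoStructure:
    """Build a crystalline core from *spec*.

    With ``connect=True`` nearest-neighbor connectivity records are added using
    a 1.2 x (sum of covalent radii) distance cutoff; by default metal-metal
    bonds are not stored.
    """
    lattice = get_lattice(spec.material)
    d_a = spec.diameter_nm * 10.0
    if d_a < min(min(lattice.lengths), lattice.min_site_separation()):
        raise TooSmallCoreError(
            f"diameter {spec.diameter_nm} nm is below one lattice constant "
            f"of {spec.material}"
        )
    length_a = spec.length_nm * 10.0 if spec.length_nm else None
    elements, pos = carve_positions(lattice, spec.shape, d_a, length_a)
    if len(pos) == 0:
        raise TooSmallCoreError("no lattice point falls inside the requested solid")

    order = np.lexsort((pos[:, 0], pos[:, 1], pos[:, 2]))
    elements, pos = elements[order], pos[order]
    atoms = [
        AtomRecord(i + 1, el, tuple(xyz))
        for i, (el, xyz) in enumerate(zip(elements, pos))
    ]
    bonds: list[BondRecord] = []
    if connect:
        bonds = perceive_bonds(list(elements), pos)
    size = {"diameter": spec.diameter_nm}
    if spec.shape == "rod":
        size["length"] = spec.length_nm
    return NanoStructure(
        identifier=spec.identifier or f"{spec.material}-{spec.shape}",
        atoms=atoms,
        bonds=bonds,
        material_class=lattice.material_class,
        shape=spec.shape,
        size=size,
    )


def perceive_bonds(elements: list[str], pos: np.ndarray,
                   scale: float = 1.2, serial_offset: int = 1) -> list[BondRecord]:
    """Distance-cutoff bond perception: cutoff = scale x sum of covalent radii."""
    radii = np.array([covalent_radius(e) for e in elements])
    tree = cKDTree(pos)
    max_cut = scale * 2 * radii.max()
    bonds = []
    for i, j in tree.query_pairs(max_cut):
        cut = scale * (radii[i] + radii[j])
        if np.linalg.norm(pos[i] - pos[j]) <= cut:
            a, b = i + serial_offset, j + serial_offset
            bonds.append(BondRecord(min(a, b), max(a, b)))
    return sorted(bonds)


def coordination_numbers(pos: np.ndarray, elements: list[str],
                         scale: float = 1.2) -> np.ndarray:
    """Per-atom neighbor counts under the covalent-radius distance cutoff."""
    counts = np.zeros(len(pos), dtype=int)
    for b in perceive_bonds(elements, pos, scale=scale, serial_offset=0):
        counts[b.a] += 1
        counts[b.b] += 1
    return counts
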