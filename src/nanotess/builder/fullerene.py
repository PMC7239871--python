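"""Buckminsterfullerene (C60) from canonical truncated-icosahedron geometry.

The 60 vertices are the cyclic permutations of (0, ±1, ±3φ), (±1, ±(2+φ), ±2φ)
and (±2, ±(1+2φ), ±φ) with φ the golden ratio, scaled so the edge length
matches the mean C–C bond length of C60 (1.44 Å).  Bonds are the 90 polyhedron
edges, recovered by a distance cutoff.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from ..structure import AtomRecord, BondRecord, NanoStructure

CC_BOND = 1.44  # Å, mean C60 bond length


def _vertices() -> np.ndarray:
    phi = (1 + np.sqrt(5)) / 2
    seeds = [
        (0.0, 1.0, 3 * phi),
        (1.0, 2 + phi, 2 * phi),
        (2.0, 1 + 2 * phi, phi),
    ]
    pts = set()
    for seed in seeds:
        for signs in product((1, -1), repeat=3):
            base = tuple(s * c for s, c in zip(signs, seed))
            for perm in (base, (base[1], base[2], base[0]), (base[2], base[0], base[1])):
                pts.add(tuple(round(x, 9) for x in perm))
    arr = np.array(sorted(pts))
    assert arr.shape == (60, 3)
    return arr


def build_c60(identifier: str = "C60") -> NanoStructure:
    """Build buckminsterfullerene: 60 carbon atoms, 90 bonds."""
    verts = _vertices()
    verts = verts * (CC_BOND / 2.0)  # unit-edge length of the seed polyhedron is 2
    atoms = [AtomRecord(i + 1, "C", tuple(v)) for i, v in enumerate(verts)]
    cutoff = CC_BOND * 1.1
    bonds = []
    for i in range(60):
        for j in range(i + 1, 60):
            if np.linalg.norm(verts[i] - verts[j]) <= cutoff:
                bonds.append(BondRecord(i + 1, j + 1))
    diameter_nm = 2 * float(np.linalg.norm(verts, axis=1).mean()) / 10.0
    return NanoStructure(
        identifier=identifier,
        atoms=atoms,
        bonds=bonds,
        material_class="C60",
        shape="sphere",
        size={"diameter": round(diameter_nm, 3)},
    )
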