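"""Registry of default crystal lattices for nanoparticle cores.

Each entry stores the conventional unit cell (lengths in Å, angles in degrees)
and the fractional coordinates of the occupied sites.  The packaged defaults
are standard room-temperature experimental lattice constants; users can
register their own cells with :func:`register_lattice`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import UnknownMaterialError


@dataclass(frozen=True)
class Lattice:
    """A conventional unit cell with occupied fractional sites."""

    key: str
    lengths: tuple[float, float, float]  # a, b, c in Å
    angles: tuple[float, float, float] = (90.0, 90.0, 90.0)  # alpha, beta, gamma, deg
    sites: tuple[tuple[str, tuple[float, float, float]], ...] = ()
    material_class: str = "unknown"

    def __post_init__(self):
        if min(self.lengths) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0.0 < a < 180.0 for a in self.angles):
            raise ValueError("cell angles must lie in (0, 180) degrees")
        if not self.sites:
            raise ValueError("lattice needs at least one site")

    def cell_matrix(self) -> np.ndarray:
        """Row-vector cell matrix (rows = a, b, c lattice vectors, Å)."""
        a, b, c = self.lengths
        al, be, ga = np.radians(self.angles)
        va = np.array([a, 0.0, 0.0])
        vb = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz = np.sqrt(max(c**2 - cx**2 - cy**2, 0.0))
        return np.array([va, vb, [cx, cy, cz]])

    def min_site_separation(self) -> float:
        """Smallest distance between lattice sites (checked over a 3^3 block)."""
        cell = self.cell_matrix()
        frac = np.array([xyz for _, xyz in self.sites])
        pts = []
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    pts.append((frac + [i, j, k]) @ cell)
        pts = np.vstack(pts)
        base = frac @ cell
        d = np.linalg.norm(pts[None, :, :] - base[:, None, :], axis=-1)
        return float(d[d > 1e-9].min())


_FCC_SITES = ((0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5))


def _fcc(key: str, element: str, a: float, mclass: str) -> Lattice:
    return Lattice(key, (a, a, a), sites=tuple((element, s) for s in _FCC_SITES),
                   material_class=mclass)


def _zincblende(key: str, cation: str, anion: str, a: float) -> Lattice:
    cat = tuple((cation, s) for s in _FCC_SITES)
    ani = tuple((anion, (s[0] + 0.25, s[1] + 0.25, s[2] + 0.25)) for s in _FCC_SITES)
    return Lattice(key, (a, a, a), sites=cat + ani, material_class="QD")


_REGISTRY: dict[str, Lattice] = {}


def register_lattice(lattice: Lattice) -> None:
    _REGISTRY[lattice.key] = lattice


def get_lattice(key: str) -> Lattice:
    try:
        return _REGISTRY[key]
    except KeyError:
        raise UnknownMaterialError(
            f"unknown material key {key!r}; known: {sorted(_REGISTRY)}"
        ) from None


def available_materials() -> list[str]:
    return sorted(_REGISTRY)


for _lat in (
    _fcc("fcc-Au", "Au", 4.078, "GNP"),
    _fcc("fcc-Ag", "Ag", 4.085, "AgNP"),
    _fcc("fcc-Pt", "Pt", 3.924, "PtNP"),
    _fcc("fcc-Pd", "Pd", 3.891, "PdNP"),
    _zincblende("zincblende-CdSe", "Cd", "Se", 6.052),
    _zincblende("zincblende-CdS", "Cd", "S", 5.832),
    # rutile TiO2: Ti at (0,0,0),(1/2,1/2,1/2); O at +-(u,u,0) and +-(1/2+u,1/2-u,1/2), u=0.305
    Lattice(
        "rutile-TiO2", (4.594, 4.594, 2.959),
        sites=(
            ("Ti", (0.0, 0.0, 0.0)), ("Ti", (0.5, 0.5, 0.5)),
            ("O", (0.305, 0.305, 0.0)), ("O", (0.695, 0.695, 0.0)),
            ("O", (0.805, 0.195, 0.5)), ("O", (0.195, 0.805, 0.5)),
        ),
        material_class="MONP",
    ),
    # rocksalt oxides
    Lattice(
        "rocksalt-ZnO", (4.28, 4.28, 4.28),
        sites=tuple(("Zn", s) for s in _FCC_SITES)
        + tuple(("O", (s[0] + 0.5, s[1], s[2])) for s in _FCC_SITES),
        material_class="MONP",
    ),
    Lattice(
        "fluorite-CeO2", (5.411, 5.411, 5.411),
        sites=tuple(("Ce", s) for s in _FCC_SITES)
        + tuple(
            ("O", (s[0] + dx, s[1] + dy, s[2] + dz))
            for s in _FCC_SITES
            for dx, dy, dz in ((0.25, 0.25, 0.25), (0.75, 0.75, 0.75))
        ),
        material_class="MONP",
    ),
):
    register_lattice(_lat)
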