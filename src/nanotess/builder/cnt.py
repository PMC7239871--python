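"""Carbon nanotubes via the standard graphene roll-up construction.

A (n, m) tube is the graphene sheet rolled along the chiral vector
Ch = n*a1 + m*a2, giving diameter d = a*sqrt(n^2 + n*m + m^2)/pi with the
graphene lattice constant a = 2.46 Å.  The translational period along the tube
axis is |T| = sqrt(3)*|Ch|/d_R with d_R = gcd(2n + m, 2m + n).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np

from ..errors import InvalidChiralityError, NanotessError
from ..structure import AtomRecord, NanoStructure
from .cores import perceive_bonds

GRAPHENE_A = 2.46  # Å


@dataclass(frozen=True)
class CNTSpec:
    """Chiral indices and tube length (nm), or an explicit period count."""

    n: int
    m: int
    length_nm: float | None = None
    periods: int | None = None

    def __post_init__(self):
        if self.n < self.m or self.m < 0 or self.n < 1:
            raise InvalidChiralityError(
                f"invalid chiral indices ({self.n}, {self.m}): need n >= m >= 0, n >= 1"
            )
        if self.length_nm is None and self.periods is None:
            raise NanotessError("give either length_nm or periods")


def cnt_diameter(n: int, m: int, a: float = GRAPHENE_A) -> float:
    """Roll-up tube diameter in Å."""
    return a * np.sqrt(n * n + n * m + m * m) / np.pi


def build_cnt(spec: CNTSpec) -> NanoStructure:
    """Construct a pristine single-walled carbon nanotube."""
    n, m = spec.n, spec.m
    a = GRAPHENE_A
    a1 = a * np.array([np.sqrt(3) / 2, 0.5])
    a2 = a * np.array([np.sqrt(3) / 2, -0.5])
    ch = n * a1 + m * a2
    ch_len = np.linalg.norm(ch)
    d_r = gcd(2 * n + m, 2 * m + n)
    t1, t2 = (2 * m + n) // d_r, -(2 * n + m) // d_r
    tvec = t1 * a1 + t2 * a2
    t_len = np.linalg.norm(tvec)

    if spec.periods is not None:
        periods = spec.periods
    else:
        periods = max(1, round(spec.length_nm * 10.0 / t_len))

    # basis atoms of the graphene cell: A at origin, B at (a1 + a2)/3
    basis = [np.zeros(2), (a1 + a2) / 3.0]
    # enumerate graphene cells covering the Ch x (periods * T) rectangle,
    # with index bounds taken from the rectangle corners in (i, j) space
    corners_i = [0, n, periods * t1, n + periods * t1]
    corners_j = [0, m, periods * t2, m + periods * t2]
    i_lo, i_hi = min(corners_i) - 2, max(corners_i) + 2
    j_lo, j_hi = min(corners_j) - 2, max(corners_j) + 2
    to_frac = np.linalg.inv(np.array([ch, tvec]).T)
    pts = []
    eps = 1e-6
    for i in range(i_lo, i_hi + 1):
        for j in range(j_lo, j_hi + 1):
            cell = i * a1 + j * a2
            for off in basis:
                p = cell + off
                s, t = to_frac @ p
                s_w = s - np.floor(s + eps)
                if -eps <= t < periods - eps:
                    pts.append((round(s_w, 6) % 1.0, round(t, 6)))
    uniq = sorted(set(pts))

    radius = cnt_diameter(n, m) / 2.0
    coords = []
    for s, t in uniq:
        theta = 2 * np.pi * s
        coords.append((radius * np.cos(theta), radius * np.sin(theta), t * t_len))
    coords = np.array(coords)
    coords -= coords.mean(axis=0)

    elements = ["C"] * len(coords)
    atoms = [AtomRecord(i + 1, "C", tuple(c)) for i, c in enumerate(coords)]
    bonds = perceive_bonds(elements, coords)
    length_nm = periods * t_len / 10.0
    return NanoStructure(
        identifier=f"CNT-{n}-{m}",
        atoms=atoms,
        bonds=bonds,
        material_class="CNT",
        shape="tube",
        size={"diameter": 2 * radius / 10.0, "length": length_nm},
    )
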