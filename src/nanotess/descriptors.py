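"""Delaunay-tessellation nanodescriptors.

The atomic coordinates of a nanostructure are tessellated into Delaunay
tetrahedra.  Each tetrahedron is typed by the unordered multiset of its four
vertex atom types, drawn from a 6-letter alphabet {H, C, N, O, X, M} (X =
other nonmetal, M = metal/metalloid), giving C(6+4-1, 4) = 126 distinct
tetrahedron-fragment classes.  Class occurrences are converted to frequencies
(occurrence / total tetrahedra).  Each of 17 atomic properties is then folded
in: the representative value of property p for class c is the mean, over the
class's tetrahedron instances, of the sum of the four vertex atoms' element
property values, multiplied by the class frequency.  The result is a fixed
17 x 126 = 2142-component descriptor vector per structure.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from . import elements as _el
from .errors import AtomBudgetError, DegenerateGeometryError, MissingPropertyError
from .structure import NanoStructure

#: Default cap on tessellated atom count; larger structures raise, never subsample.
DEFAULT_ATOM_BUDGET = 200_000


@dataclass(frozen=True)
class AtomTypeScheme:
    """Maps element symbols onto a fixed alphabet of atom-type classes.

    The default scheme is the 6-class alphabet; a custom (total or partial)
    mapping can be supplied, in which case an element outside the mapping
    raises a named error during classification.
    """

    types: tuple[str, ...] = _el.ATOM_TYPES
    mapping: dict | None = None

    def type_of(self, symbol: str) -> str:
        if self.mapping is not None:
            try:
                return self.mapping[symbol]
            except KeyError:
                raise MissingPropertyError(
                    f"element {symbol!r} missing from atom-type scheme"
                ) from None
        return _el.atom_type(symbol)

    def n_classes(self) -> int:
        k = len(self.types)
        return (k * (k + 1) * (k + 2) * (k + 3)) // 24  # C(k+3, 4)


DEFAULT_SCHEME = AtomTypeScheme()


def all_tetrahedron_classes(scheme: AtomTypeScheme = DEFAULT_SCHEME) -> list[str]:
    """Canonical names of all tetrahedron classes (126 for the 6-type alphabet).

    A class name joins its four atom types in alphabet order, e.g. ``H-C-M-M``.
    """
    return [
        "-".join(combo)
        for combo in combinations_with_replacement(scheme.types, 4)
    ]


def descriptor_names(scheme: AtomTypeScheme = DEFAULT_SCHEME,
                     properties: tuple[str, ...] = _el.PROPERTY_NAMES) -> list[str]:
    """The 2142 descriptor column names, property-major: ``prop(class)``."""
    classes = all_tetrahedron_classes(scheme)
    return [f"{p}({c})" for p in properties for c in classes]


# ---------------------------------------------------------------------------
# tessellation

def tessellate(structure: NanoStructure, atom_budget: int = DEFAULT_ATOM_BUDGET) -> np.ndarray:
    """Delaunay tetrahedralization of the atom coordinates.

    Returns an (n_tetrahedra, 4) array of atom indices (order of
    ``structure.atoms``).  Raises for fewer than 4 atoms, (near-)degenerate
    geometry, or structures above the atom budget.
    """
    coords = structure.coordinates()
    n = len(coords)
    if n > atom_budget:
        raise AtomBudgetError(
            f"{n} atoms exceeds the tessellation budget of {atom_budget}; "
            "reduce the structure size"
        )
    if n < 4:
        raise DegenerateGeometryError(f"need >= 4 atoms, got {n}")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 3:
        raise DegenerateGeometryError(
            "atom positions are coplanar/collinear; no 3D tessellation exists"
        )
    try:
        tri = Delaunay(coords)
    except QhullError:
        # near-degenerate flat slabs: deterministic sub-nm jitter keyed to the id
        rng = np.random.default_rng(zlib.crc32(structure.identifier.encode()) % 2**31)
        warnings.warn(
            f"tessellation of {structure.identifier!r} needed a 1e-9 Å jitter",
            stacklevel=2,
        )
        tri = Delaunay(coords + rng.normal(0.0, 1e-9, size=coords.shape))
    return np.sort(tri.simplices, axis=1)


# ---------------------------------------------------------------------------
# classification and weighting

def _class_indices(tetrahedra: np.ndarray, structure: NanoStructure,
                   scheme: AtomTypeScheme) -> np.ndarray:
    type_order = {t: i for i, t in enumerate(scheme.types)}
    atom_type_idx = np.array(
        [type_order[scheme.type_of(el)] for el in structure.elements()]
    )
    key_of = {}
    for ci, combo in enumerate(combinations_with_replacement(range(len(scheme.types)), 4)):
        key_of[combo] = ci
    tetra_types = np.sort(atom_type_idx[tetrahedra], axis=1)
    return np.array([key_of[tuple(row)] for row in tetra_types])


def classify(tetrahedra: np.ndarray, structure: NanoStructure,
             scheme: AtomTypeScheme = DEFAULT_SCHEME) -> pd.Series:
    """Occurrence counts over all tetrahedron classes (126-long, named)."""
    counts = np.zeros(scheme.n_classes(), dtype=int)
    if len(tetrahedra):
        idx = _class_indices(np.asarray(tetrahedra), structure, scheme)
        np.add.at(counts, idx, 1)
    return pd.Series(counts, index=all_tetrahedron_classes(scheme), name="occurrence")


def to_frequency(counts: pd.Series) -> pd.Series:
    """Occurrence -> frequency: each count divided by the total count."""
    total = int(counts.sum())
    if total < 1:
        raise DegenerateGeometryError("zero tetrahedra; frequencies undefined")
    return (counts / total).rename("frequency")


@dataclass
class DescriptorVector:
    """The 2142 property-weighted descriptors of one structure.

    The raw 126 class frequencies are retained as auxiliary output.
    """

    structure_id: str
    values: pd.Series
    frequencies: pd.Series = field(repr=False)


def property_weight(structure: NanoStructure, tetrahedra: np.ndarray,
                    frequencies: pd.Series,
                    table: pd.DataFrame | None = None,
                    scheme: AtomTypeScheme = DEFAULT_SCHEME) -> DescriptorVector:
    """Fold the 17 atomic properties into the class frequencies.

    value(p, c) = frequency(c) * mean over instances of class c of the sum of
    the four vertex atoms' element-level values of property p.  Classes with
    no instances get 0.
    """
    if table is None:
        table = _el.property_table()
    symbols = structure.elements()
    missing = sorted({s for s in symbols if s not in table.index})
    if missing:
        raise MissingPropertyError(
            f"elements {missing} lack rows in the atomic property table"
        )
    prop_cols = list(table.columns)
    atom_props = table.loc[symbols, prop_cols].to_numpy(dtype=float)  # (n, 17)

    n_classes = scheme.n_classes()
    class_names = all_tetrahedron_classes(scheme)
    class_sums = np.zeros((n_classes, len(prop_cols)))
    class_counts = np.zeros(n_classes)
    if len(tetrahedra):
        tetra = np.asarray(tetrahedra)
        idx = _class_indices(tetra, structure, scheme)
        tetra_props = atom_props[tetra].sum(axis=1)  # (T, 17): per-instance sums
        np.add.at(class_sums, idx, tetra_props)
        np.add.at(class_counts, idx, 1)
    with np.errstate(invalid="ignore"):
        class_means = np.where(
            class_counts[:, None] > 0, class_sums / np.maximum(class_counts, 1)[:, None], 0.0
        )
    freq = frequencies.reindex(class_names).to_numpy(dtype=float)
    weighted = class_means * freq[:, None]  # (126, 17)

    names = [f"{p}({c})" for p in prop_cols for c in class_names]
    values = pd.Series(weighted.T.ravel(), index=names, name=structure.identifier)
    return DescriptorVector(structure.identifier, values, frequencies.copy())


def compute_descriptors(structure: NanoStructure,
                        scheme: AtomTypeScheme = DEFAULT_SCHEME,
                        table: pd.DataFrame | None = None,
                        atom_budget: int = DEFAULT_ATOM_BUDGET) -> DescriptorVector:
    """Full pipeline: tessellate, classify, normalize, property-weight."""
    tetra = tessellate(structure, atom_budget=atom_budget)
    counts = classify(tetra, structure, scheme)
    freq = to_frequency(counts)
    return property_weight(structure, tetra, freq, table=table, scheme=scheme)


def descriptor_matrix(structures, **kwargs) -> pd.DataFrame:
    """Stack descriptor vectors of many structures into a matrix (rows = ids)."""
    rows = [compute_descriptors(s, **kwargs).values for s in structures]
    return pd.DataFrame(rows)


def filter_descriptors(matrix: pd.DataFrame, threshold: float = 0.0):
    """Drop columns with (near-)zero variance across structures.

    Returns ``(reduced, kept, removed)`` with column order preserved.  The
    default threshold 0 removes exactly-constant columns.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 structures to filter descriptors")
    variances = matrix.var(axis=0, ddof=0)
    kept = [c for c in matrix.columns if variances[c] > threshold]
    removed = [c for c in matrix.columns if c not in set(kept)]
    if not kept:
        warnings.warn("all descriptor columns are constant; empty matrix", stacklevel=2)
    return matrix[kept], kept, removed
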