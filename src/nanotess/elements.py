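"""Periodic-table data: element symbols, atom-type classes, and the 17-property table.

The atomic property table packaged under ``data/atomic_properties.csv`` holds, per
element, the 17 physical properties used to weight tetrahedron-fragment descriptors:

======== ==========================================  ==============
column   property                                     units
======== ==========================================  ==============
R_cal    calculated atomic radius                     pm
R_cov    covalent radius                              pm
R_emp    empirical atomic radius                      pm
M        atomic mass                                  u
T_bol    boiling point                                K
rho      density                                      g/cm3
E_ea     electron affinity                            kJ/mol
chi      Pauling electronegativity                    –
dH_fus   heat of fusion                               kJ/mol
dH_vap   heat of vaporization                         kJ/mol
IE_1     first ionization energy                      kJ/mol
IE_2     second ionization energy                     kJ/mol
T_mel    melting point                                K
V_mol    molar volume                                 cm3/mol
Q        specific heat                                J/(g*K)
lambda   thermal conductivity                         W/(m*K)
q        common valence                               –
======== ==========================================  ==============

Values are compiled from standard element-data references. A genuinely undefined
value (e.g. the electron affinity of closed-shell metals) is stored as 0.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import MissingPropertyError, UnknownElementError

#: The 17 property column names, in canonical order.
PROPERTY_NAMES: tuple[str, ...] = (
    "R_cal", "R_cov", "R_emp", "M", "T_bol", "rho", "E_ea", "chi",
    "dH_fus", "dH_vap", "IE_1", "IE_2", "T_mel", "V_mol", "Q", "lambda", "q",
)

#: All IUPAC element symbols (Z = 1..118).
ALL_SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

_SYMBOL_SET = frozenset(ALL_SYMBOLS)

# Elements that are not metals or metalloids.  Metalloids (B, Si, Ge, As, Sb, Te)
# fall in the metal/metalloid class of the 6-letter atom-type alphabet.
NONMETALS = frozenset({
    "H", "He", "C", "N", "O", "F", "Ne", "P", "S", "Cl", "Ar",
    "Se", "Br", "Kr", "I", "Xe", "Rn",
})

#: The 6 atom-type classes of the tetrahedron-fragment alphabet, canonical order.
ATOM_TYPES: tuple[str, ...] = ("H", "C", "N", "O", "X", "M")


def is_element(symbol: str) -> bool:
    """True if *symbol* is a recognized element symbol."""
    return symbol in _SYMBOL_SET


def check_element(symbol: str) -> str:
    """Return *symbol* or raise :class:`UnknownElementError`."""
    if symbol not in _SYMBOL_SET:
        raise UnknownElementError(f"unknown element symbol: {symbol!r}")
    return symbol


def atom_type(symbol: str) -> str:
    """Map an element symbol to one of the 6 atom-type classes.

    H, C, N, O keep their own class; every other nonmetal maps to X; metals
    and metalloids map to M.  The mapping is total over the periodic table.
    """
    check_element(symbol)
    if symbol in ("H", "C", "N", "O"):
        return symbol
    return "X" if symbol in NONMETALS else "M"


def load_property_table() -> pd.DataFrame:
    """Load the packaged 17-property table, indexed by element symbol."""
    with resources.files("nanotess.data").joinpath("atomic_properties.csv").open() as fh:
        table = pd.read_csv(fh, index_col="symbol")
    assert tuple(table.columns) == PROPERTY_NAMES
    return table


_TABLE: pd.DataFrame | None = None


def property_table() -> pd.DataFrame:
    """Cached accessor for the packaged property table."""
    global _TABLE
    if _TABLE is None:
        _TABLE = load_property_table()
    return _TABLE


def property_row(symbol: str) -> pd.Series:
    """The 17-property row for one element; raises if the element has no row."""
    check_element(symbol)
    table = property_table()
    if symbol not in table.index:
        raise MissingPropertyError(
            f"element {symbol!r} has no row in the atomic property table"
        )
    return table.loc[symbol]


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Å (table stores pm)."""
    return float(property_row(symbol)["R_cov"]) / 100.0
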