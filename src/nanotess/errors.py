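"""Named exceptions raised across the toolkit."""


class NanotessError(Exception):
    """Base class for all toolkit errors."""


class UnknownElementError(NanotessError):
    """An element symbol is not in the packaged periodic table."""


class MissingPropertyError(NanotessError):
    """An element has no row in the atomic property table."""


class PDBParseError(NanotessError):
    """A PDB file could not be parsed; message names the offending line."""


class EmptyStructureError(NanotessError):
    """A structure (or file) contains no atom records."""


class DuplicateSerialError(NanotessError):
    """Two atom records share the same serial number."""


class UnknownMaterialError(NanotessError):
    """A material key is absent from the lattice registry."""


class TooSmallCoreError(NanotessError):
    """Requested core dimensions are below one lattice constant."""


class InvalidChiralityError(NanotessError):
    """Carbon-nanotube chiral indices (n, m) are invalid."""


class UnknownResidueError(NanotessError):
    """An amino-acid code is not recognized."""


class SmilesError(NanotessError):
    """A SMILES string could not be parsed or embedded."""


class CapacityError(NanotessError):
    """More ligands requested than available surface sites."""


class DegenerateGeometryError(NanotessError):
    """Too few or degenerate (coplanar/collinear) atom positions."""


class AtomBudgetError(NanotessError):
    """Structure exceeds the configured tessellation atom budget."""


class SplitError(NanotessError):
    """Dataset too small or fold configuration invalid."""


class DivergenceError(NanotessError):
    """Neural-network training produced a non-finite loss."""
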