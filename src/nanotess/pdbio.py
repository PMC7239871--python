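"""Three-part PDB files for nanomaterials: header remarks, atom records, connectivity.

A written file has (1) ``REMARK 300`` key:value lines carrying the structure
annotation (material class, shape, size in nm, per-ligand SMILES and count),
(2) one HETATM record per atom (nanomaterial atoms are not standard residues),
and (3) CONECT records covering every bond.  Serials beyond 99999 are written
in hybrid-36 notation so very large particles remain encodable; strict legacy
PDB consumers may not accept such files.
"""

from __future__ import annotations

import string
from pathlib import Path

import pandas as pd

from .errors import EmptyStructureError, NanotessError, PDBParseError
from .structure import MATERIAL_CLASSES, SHAPES, AtomRecord, BondRecord, NanoStructure

_UPPER = string.digits + string.ascii_uppercase
_LOWER = string.digits + string.ascii_lowercase


# ---------------------------------------------------------------------------
# hybrid-36 serial encoding

def hy36encode(value: int, width: int) -> str:
    """Encode a non-negative integer in hybrid-36 notation of the given width."""
    if value < 0:
        raise ValueError("hybrid-36 encodes non-negative integers only")
    dec_limit = 10 ** width
    if value < dec_limit:
        return str(value).rjust(width)
    block = 26 * 36 ** (width - 1)
    offset = 10 * 36 ** (width - 1)
    value -= dec_limit
    if value < block:
        return _to_base36(value + offset, _UPPER)
    value -= block
    if value < block:
        return _to_base36(value + offset, _LOWER)
    raise ValueError(f"value too large for width-{width} hybrid-36 field")


def _to_base36(value: int, digits: str) -> str:
    out = []
    while value:
        value, rem = divmod(value, 36)
        out.append(digits[rem])
    return "".join(reversed(out))


def hy36decode(field: str, width: int) -> int:
    """Decode a width-*width* hybrid-36 field back to an integer."""
    s = field.strip()
    if not s:
        raise ValueError("empty hybrid-36 field")
    if s.lstrip("-").isdigit():
        return int(s)
    offset = 10 * 36 ** (width - 1)
    block = 26 * 36 ** (width - 1)
    if s[0] in string.ascii_uppercase:
        return int(s, 36) - offset + 10 ** width
    if s[0] in string.ascii_lowercase:
        return int(s, 36) - offset + 10 ** width + block
    raise ValueError(f"malformed hybrid-36 field {field!r}")


# ---------------------------------------------------------------------------
# writing

def _remark_lines(s: NanoStructure) -> list[str]:
    lines = [f"REMARK 300 IDENTIFIER {s.identifier}"]
    lines.append(f"REMARK 300 MATERIAL {s.material_class}")
    lines.append(f"REMARK 300 SHAPE {s.shape}")
    if s.size:
        parts = " ".join(f"{k}={float(v):g}" for k, v in sorted(s.size.items()))
        lines.append(f"REMARK 300 SIZE_NM {parts}")
    for i, (smiles, count) in enumerate(s.ligands, start=1):
        lines.append(f"REMARK 300 LIGAND {i} SMILES {smiles}")
        lines.append(f"REMARK 300 LIGAND {i} COUNT {count}")
    return lines


def _atom_line(a: AtomRecord) -> str:
    serial = hy36encode(a.serial, 5)
    name = a.name[:4]
    if len(name) < 4:
        name = f" {name:<3s}"
    resname = "COR" if a.fragment_id == 0 else "LIG"
    resseq = hy36encode(a.fragment_id, 4)
    x, y, z = a.coords
    if max(abs(x), abs(y), abs(z)) >= 10000:
        raise NanotessError(f"coordinate overflow on atom {a.serial}: {a.coords}")
    return (
        f"HETATM{serial} {name} {resname} A{resseq}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
    )


def write_pdb(structure: NanoStructure, path, center: bool = False) -> None:
    """Write *structure* as a three-part PDB file.

    With ``center=True`` the atom centroid is translated to the origin first
    (builders already produce centroid-centered particles).
    """
    structure.validate()
    if center:
        structure = structure.centered()
    neighbors: dict[int, list[int]] = {}
    for b in structure.bonds:
        neighbors.setdefault(b.a, []).append(b.b)
        neighbors.setdefault(b.b, []).append(b.a)

    lines = _remark_lines(structure)
    lines += [_atom_line(a) for a in structure.atoms]
    for serial in sorted(neighbors):
        partners = sorted(neighbors[serial])
        for i in range(0, len(partners), 4):
            chunk = "".join(hy36encode(p, 5) for p in partners[i : i + 4])
            lines.append(f"CONECT{hy36encode(serial, 5)}{chunk}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reading

def _parse_size(text: str) -> dict:
    out = {}
    for part in text.split():
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = float(v)
    return out


def read_pdb(path) -> NanoStructure:
    """Parse a PDB file into a :class:`NanoStructure`.

    Header remarks populate the annotation metadata when present; otherwise the
    metadata is marked unknown.  Bonds come from CONECT records; a file without
    them yields an empty bond list.
    """
    path = Path(path)
    identifier = path.stem
    material, shape, size = "unknown", "unknown", {}
    ligands: dict[int, dict] = {}
    atoms: list[AtomRecord] = []
    bonds: set[tuple[int, int]] = set()

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        rec = raw[:6]
        if rec == "REMARK":
            fields = raw.split()
            if len(fields) >= 4 and fields[1] == "300":
                key = fields[2]
                if key == "IDENTIFIER":
                    identifier = fields[3]
                elif key == "MATERIAL" and fields[3] in MATERIAL_CLASSES:
                    material = fields[3]
                elif key == "SHAPE" and fields[3] in SHAPES:
                    shape = fields[3]
                elif key == "SIZE_NM":
                    size = _parse_size(" ".join(fields[3:]))
                elif key == "LIGAND" and len(fields) >= 6:
                    entry = ligands.setdefault(int(fields[3]), {})
                    if fields[4] == "SMILES":
                        entry["smiles"] = fields[5]
                    elif fields[4] == "COUNT":
                        entry["count"] = int(fields[5])
        elif rec in ("HETATM", "ATOM  "):
            try:
                serial = hy36decode(raw[6:11], 5)
                name = raw[12:16].strip()
                fragment = hy36decode(raw[22:26], 4) if raw[22:26].strip() else 0
                coords = (float(raw[30:38]), float(raw[38:46]), float(raw[46:54]))
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed atom record ({exc})")
            element = raw[76:78].strip()
            if not element:
                element = "".join(c for c in name if c.isalpha())[:2].capitalize()
            atoms.append(AtomRecord(serial, element, coords, name=name, fragment_id=fragment))
        elif rec == "CONECT":
            try:
                base = hy36decode(raw[6:11], 5)
                partners = []
                for start in range(11, min(len(raw), 31), 5):
                    fld = raw[start : start + 5]
                    if fld.strip():
                        partners.append(hy36decode(fld, 5))
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed CONECT record ({exc})")
            for p in partners:
                bonds.add((min(base, p), max(base, p)))

    if not atoms:
        raise EmptyStructureError(f"{path}: no atom records")
    ligand_list = [
        (ligands[i].get("smiles", ""), ligands[i].get("count", 0))
        for i in sorted(ligands)
    ]
    return NanoStructure(
        identifier=identifier,
        atoms=atoms,
        bonds=[BondRecord(a, b) for a, b in sorted(bonds)],
        material_class=material,
        shape=shape,
        size=size,
        ligands=ligand_list,
    )


# ---------------------------------------------------------------------------
# tabular export

def atoms_to_frame(structure: NanoStructure) -> pd.DataFrame:
    """Atom table: serial, element, name, fragment_id, x, y, z (Å)."""
    rows = [
        (a.serial, a.element, a.name, a.fragment_id, *a.coords)
        for a in structure.atoms
    ]
    return pd.DataFrame(rows, columns=["serial", "element", "name", "fragment_id", "x", "y", "z"])


def bonds_to_frame(structure: NanoStructure) -> pd.DataFrame:
    """Bond table with columns a, b (atom serials, a < b)."""
    return pd.DataFrame([(b.a, b.b) for b in structure.bonds], columns=["a", "b"])


def export_csv(structure: NanoStructure, atoms_path, bonds_path) -> None:
    atoms_to_frame(structure).to_csv(atoms_path, index=False)
    bonds_to_frame(structure).to_csv(bonds_path, index=False)
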