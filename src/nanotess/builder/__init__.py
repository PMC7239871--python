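"""Atomistic nanostructure construction from declarative specs."""

from .cnt import CNTSpec, build_cnt, cnt_diameter
from .cores import CoreSpec, build_core, carve_positions, coordination_numbers, perceive_bonds
from .cpnt import CPNTSpec, build_cpnt, count_amide_bonds, cyclic_peptide_smiles
from .fullerene import build_c60
from .lattices import Lattice, available_materials, get_lattice, register_lattice
from .ligands import LigandConformer, LigandSpec, embed_ligand, graft_ligands, surface_sites

__all__ = [
    "CNTSpec", "CPNTSpec", "CoreSpec", "Lattice", "LigandConformer", "LigandSpec",
    "available_materials", "build_c60", "build_cnt", "build_core", "build_cpnt",
    "carve_positions", "cnt_diameter", "coordination_numbers", "count_amide_bonds",
    "cyclic_peptide_smiles", "embed_ligand", "get_lattice", "graft_ligands",
    "perceive_bonds", "register_lattice", "surface_sites", "build_from_spec",
]


def build_from_spec(spec: dict, seed: int = 0):
    """Dispatch a declarative dict spec (e.g. parsed YAML) to the right builder.

    Recognized kinds: ``core`` (default; material/shape/diameter_nm[/length_nm]
    plus optional ``ligands`` entries of smiles/count), ``cnt`` (n, m,
    length_nm or periods), ``cpnt`` (sequence, ring_count), ``c60``.
    """
    kind = spec.get("kind", "core")
    if kind == "c60":
        return build_c60(spec.get("identifier", "C60"))
    if kind == "cnt":
        return build_cnt(CNTSpec(
            n=int(spec["n"]), m=int(spec["m"]),
            length_nm=spec.get("length_nm"), periods=spec.get("periods"),
        ))
    if kind == "cpnt":
        return build_cpnt(CPNTSpec(
            sequence=spec["sequence"], ring_count=int(spec.get("ring_count", 1)),
            seed=seed,
        ))
    if kind == "core":
        core = build_core(CoreSpec(
            material=spec["material"],
            shape=spec.get("shape", "sphere"),
            diameter_nm=float(spec.get("diameter_nm", 2.0)),
            length_nm=spec.get("length_nm"),
            identifier=spec.get("identifier", ""),
        ), connect=bool(spec.get("connect", False)))
        ligands = [
            LigandSpec(entry["smiles"], int(entry["count"]),
                       entry.get("anchor_rule", "auto"))
            for entry in spec.get("ligands", [])
        ]
        if ligands:
            core = graft_ligands(core, ligands, seed=seed)
        return core
    raise ValueError(f"unknown structure kind {kind!r}")
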