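"""Build a thiol-decorated gold nanoparticle and write it as a PDB file.

Carves a 2 nm sphere out of the fcc gold lattice, grafts 15 ethanethiol
ligands onto surface atoms, and writes the three-part PDB file (header
remarks, atom records, connectivity records).
"""

from nanotess.builder import CoreSpec, LigandSpec, build_core, graft_ligands
from nanotess.pdbio import write_pdb

core = build_core(CoreSpec("fcc-Au", shape="sphere", diameter_nm=2.0,
                           identifier="GNP-demo"))
print(f"core: {core.n_atoms} Au atoms carved from the fcc lattice")

particle = graft_ligands(core, [LigandSpec("CCS", 15)], seed=1)
ligand_atoms = particle.n_atoms - core.n_atoms
print(f"grafted particle: {particle.n_atoms} atoms "
      f"({ligand_atoms} in 15 ethanethiol ligands), {particle.n_bonds} bonds")

write_pdb(particle, "GNP-demo.pdb")
print("wrote GNP-demo.pdb  (REMARK header carries material/shape/size/ligands)")
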