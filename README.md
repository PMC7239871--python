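# nanotess

Atomistic nanostructure annotation, Delaunay-tessellation nanodescriptors,
and quantitative nanostructure–activity relationship (QNAR) modeling.

Experimental nanomaterial data (gold/silver/platinum/palladium particles,
quantum dots, metal oxides, carbon nanotubes, fullerenes, cyclic peptide
nanotubes, imported DNA-origami and dendrimer structures) only become useful
for machine learning once each material is represented as an explicit
atomistic structure and that structure is reduced to a fixed-length numerical
fingerprint. `nanotess` provides that pipeline for computational
nanotechnology and nanoinformatics groups:

1. **Builders** construct atomistic particles from declarative specs —
   crystalline cores carved from replicated unit cells (spheres, or rods with
   hemispherical caps), carbon nanotubes from the graphene roll-up
   (d = a·√(n² + nm + m²)/π, a = 2.46 Å), cyclic-peptide nanotubes stacked at
   4.8 Å with alternating ring flip, C60 from truncated-icosahedron geometry,
   and random surface grafting of SMILES-defined ligands.
2. **PDB I/O** stores each annotated structure as a three-part PDB file:
   `REMARK` header (material, shape, size in nm, ligand SMILES/counts),
   HETATM atom records, and CONECT connectivity; serials beyond 99,999 use
   hybrid-36 widening.
3. **Nanodescriptors**: the atom coordinates are Delaunay-tessellated; each
   tetrahedron is typed by the unordered multiset of its four vertex atom
   classes over the 6-letter alphabet {H, C, N, O, X = other nonmetal,
   M = metal/metalloid}, giving C(6+4−1, 4) = **126 tetrahedron classes**.
   Occurrences become frequencies, and 17 atomic properties (radii, mass,
   thermal constants, electronegativity, ionization energies, valence, …)
   are folded in as

   `value(p, c) = freq(c) · mean over instances of c [ Σ over 4 vertex atoms p(element) ]`

   producing a **2142-component** descriptor vector per structure.
4. **Diversity analysis**: zero-variance filtering, min-max normalization to
   [0, 1], exhaustive pairwise Euclidean distances (n(n−1)/2 pairs), and
   covariance PCA with explained-variance reporting.
5. **Modeling**: a seeded 80/20 split with 5-fold cross-validation;
   weighted-neighbor kNN (ŷ = Σ wᵢyᵢ/Σ wᵢ, wᵢ = e^(−dᵢ)) with simulated-
   annealing variable selection maximizing leave-one-out q²; and a
   feedforward network (512/128/64 hidden units, relu, dropout 0.2, RMSprop,
   MSE, 300 epochs). Reports R² (squared Pearson) and RMSE for pooled
   cross-validation and external prediction.

A synthetic fixture module generates small ligand-decorated particles with a
planted linear structure–activity signal, and a registry transcribes the
reference database census (705 structures over 11 material classes; endpoint
datasets of 147 logP, 213 zeta-potential, and 71 cellular-uptake entries).

## Worked example

```python
from nanotess.builder import CoreSpec, LigandSpec, build_core, graft_ligands
from nanotess.descriptors import compute_descriptors
from nanotess.pdbio import write_pdb

core = build_core(CoreSpec("fcc-Au", shape="sphere", diameter_nm=2.0,
                           identifier="GNP-demo"))
particle = graft_ligands(core, [LigandSpec("CCS", 15)], seed=1)
write_pdb(particle, "GNP-demo.pdb")
dv = compute_descriptors(particle)
print(particle.n_atoms, len(dv.values))
```

Running `examples/build_gold_nanoparticle.py` prints:

```
core: 249 Au atoms carved from the fcc lattice
grafted particle: 384 atoms (135 in 15 ethanethiol ligands), 135 bonds
wrote GNP-demo.pdb  (REMARK header carries material/shape/size/ligands)
```

249 gold atoms are the fcc lattice points inside a 2 nm sphere; each
ethanethiol (9 atoms) adds a sulfur–gold anchor bond, and the descriptor
vector always has 17 × 126 = 2142 entries. The other scripts under
`examples/` walk through descriptors, diversity analysis, kNN/DNN modeling,
and the database census, each printing the numbers it computes.

A thin CLI mirrors the stages:
`nanotess build|descriptors|distances|pca|split|train|evaluate|fixtures|registry`.

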