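# Methods

This note records the models and procedures implemented in `nanotess`, the
parameters that matter, and the design choices made where the underlying
methodology left the details open.

## Structure builders

**Crystalline cores.** A core is the set of lattice points of a replicated
conventional unit cell that fall inside a target solid. The carving center is
snapped to the lattice site nearest the supercell centroid, so every atom
position is an exact lattice vector relative to the center (verified to
1e-6 Å in tests). Spheres keep |r| ≤ d/2; rods are cylinders with
hemispherical caps whose *total* length includes the caps (cap handling is a
convention of this package — specs like "30 nm × 33 nm" map to diameter ×
total length). The packaged lattice registry holds standard room-temperature
experimental cells (fcc Au 4.078 Å, Ag 4.085 Å, Pt 3.924 Å, Pd 3.891 Å;
zincblende CdSe/CdS; rutile TiO2; rocksalt ZnO; fluorite CeO2) and is
user-extensible with `register_lattice`. A diameter below one lattice
constant raises rather than returning a fragment.

**Carbon nanotubes.** Standard graphene roll-up: chiral vector
Ch = n·a1 + m·a2 with a = 2.46 Å, diameter d = a·√(n²+nm+m²)/π, translation
period |T| = √3|Ch|/d_R, d_R = gcd(2n+m, 2m+n). A requested length in nm is
rounded to whole translational periods (at least one). All atoms sit exactly
on the cylinder (radius dispersion < 0.01 Å by construction); bonds come
from the covalent-radius cutoff below.

**Cyclic peptide nanotubes.** The ring is assembled as a head-to-tail cyclic
peptide SMILES from the one-letter sequence, embedded (ETKDG, seeded) and
MMFF-optimized with RDKit, then aligned so the macrocycle's best-fit plane is
normal to z. Rings stack at 4.8 Å axial spacing with every other ring flipped
(antiparallel β-sheet-like stacking); inter-ring hydrogen bonds are implied
by geometry and not stored as bond records. The 4.8 Å spacing is the
canonical β-sheet stacking distance for cyclic D,L-peptide nanotubes.

**C60.** Built from the canonical truncated-icosahedron vertex set scaled to
a 1.44 Å mean bond; the 90 edges are recovered by distance cutoff. This is a
direct geometric route to the same cage a SMILES-to-3D conversion produces,
without relying on embedding heuristics for a fused-ring cage.

**Bond perception.** Distance cutoff at 1.2 × the sum of covalent radii.
Metal cores carry no explicit metal–metal connectivity records by default
(viewers infer packing; a `connect=True` flag stores them), since explicit
bonding in close-packed metals is a representation choice, not chemistry.

**Ligand grafting.** Surface sites are core atoms whose coordination number
falls below the bulk (maximum observed) coordination. Sites are sampled
uniformly at random without replacement under a minimum inter-anchor
separation 0.8·√(4πR²/count) that relaxes geometrically if unsatisfiable;
requesting more ligands than surface sites raises a capacity error naming
the maximum. Each conformer (one seeded ETKDG embedding, MMFF/UFF minimized)
is translated so its anchor sits one covalent-bond length above the site
along the outward normal, its heavy-atom principal direction aligned with
that normal, with up to 12 seeded azimuthal retries to keep heavy atoms of
different ligands at least 1.0 Å apart. The anchor is the first thiol-type S,
else the first heteroatom, else the first heavy atom; ligand surface density
is always taken from the user-provided count, never predicted from
chemistry. Core atoms are never moved or deleted, and all builders are
deterministic given (spec, seed).

## PDB encoding

Files have three parts: `REMARK 300` key:value annotation lines
(IDENTIFIER, MATERIAL, SHAPE, SIZE_NM, LIGAND i SMILES/COUNT), HETATM atom
records (nanomaterial atoms are not standard residues; element right-
justified in columns 77–78, coordinates at 3-decimal Å), and CONECT records
covering every bond. The remark grammar is this package's own fixed
convention so metadata survives round trips; it is not claimed to match any
external repository's files byte-for-byte. Atom serials and fragment ids
beyond the legacy column widths are written in hybrid-36 notation
(A0000… then a0000…), accepted transparently on read; strict legacy PDB
consumers may reject such files. Fragment id 0 marks the core; each grafted
ligand instance gets its own id (residue name COR/LIG, id in the residue
sequence columns). Builders produce centroid-centered particles; the writer
preserves coordinates as given (an optional `center=True` recenters), which
keeps write∘read an exact identity at format precision.

## Nanodescriptors

The tessellation is the scipy/Qhull Delaunay triangulation of all atom
coordinates (no subsampling; structures above a configurable 200,000-atom
budget raise). Fewer than 4 atoms or a coplanar/collinear configuration is a
degeneracy error; near-degenerate flat slabs that Qhull rejects are retried
once with a deterministic 1e-9 Å jitter keyed to the structure id and logged.
Lattice cores contain many cospherical point groups, so their triangulation
is one of several valid Delaunay completions; the descriptor statistics are
insensitive to which completion Qhull returns, and on random general-position
point sets the output is verified against a brute-force empty-circumsphere
oracle.

**Atom-type alphabet.** Six classes {H, C, N, O, X, M}: H/C/N/O keep their
own class, X collects the remaining nonmetals (S, P, Se, halogens, noble
gases), M collects metals and metalloids. Six is the unique alphabet size for
which unordered 4-multisets give C(6+4−1, 4) = 126 tetrahedron classes; the
class semantics are this package's reading and are overridable via
`AtomTypeScheme`.

**Property weighting.** For each of the 17 atomic properties p and each
class c: value(p, c) = freq(c) × mean over the instances of c of the *sum*
of the four vertex atoms' element-level p. The per-tetrahedron sum (rather
than mean) keeps element-level sensitivity inside the coarse classes — two
M-M-M-M tetrahedra of Zn vs Ce differ fourfold in each property sum — which
matters most for metal-oxide particles with unusual metals. Classes without
instances are exactly 0. The packaged element table (data/atomic_properties.csv,
~50 elements × 17 properties with units documented in `nanotess.elements`)
is compiled from standard element-data references; genuinely undefined
values (e.g., electron affinities of closed-shell metals) are stored as 0.
An element without a table row raises a named error rather than silently
imputing.

Descriptors are invariant to rigid motions (tessellation and element content
are) and to uniform coordinate scaling (Delaunay topology is scale-free);
both are property-tested. Filtering removes exactly zero-variance columns by
default (the threshold is an argument, since a near-constant cutoff is a
defensible alternative).

## Diversity analysis

Min-max normalization maps each kept column onto [0, 1] using the min/max of
the full analyzed set — similarity thresholds such as "distance < 0.5" are
relative to this scaling, so subsets are not rescaled separately. Pairwise
distances are exhaustive (n(n−1)/2 unordered pairs) with min/max/mean
summaries. PCA mean-centers columns (no further standardization beyond the
min-max step), decomposes by SVD of the centered matrix, and fixes each
component's sign so its largest-magnitude loading is positive; explained
variance fractions are non-increasing and verified against scikit-learn.

## Modeling protocol

The endpoint dataset (n ≥ 10) is split 80/20 by a seeded shuffle with
|train| = round(0.8n); the shuffled training ids are dealt round-robin into
5 folds (sizes within 1). Min-max scaling is fitted on each fold's training
portion (and on the full training set for external prediction) and applied
to whatever is predicted — test ids never touch fitting, variable selection,
or normalization statistics, which is asserted by a dedicated leakage test.
Cross-validation metrics are computed on the pooled out-of-fold predictions
(one scatter, one R²); per-fold metrics are logged alongside.

**kNN.** Prediction is ŷ = Σ wᵢyᵢ/Σ wᵢ over the k nearest training points in
the Euclidean metric restricted to the selected descriptor subset, wᵢ =
exp(−dᵢ), ties broken by id order. Variable selection is simulated annealing
(single-column swap proposals, geometric cooling ×0.97 from T₀ = 0.05,
300 steps per subset size) over subset sizes {5, 10, 15, 20, 30} (capped at
the available columns), objective = leave-one-out q², with k searched over
1–5 at every evaluation. The anneal starts from the columns most correlated
with the endpoint — a standard initialization that speeds convergence; the
Metropolis criterion still allows the search to leave it. Final prediction
uses only the selected subset.

**DNN.** A fully connected regressor, input → 512 → 128 → 64 → 1 (the
natural four-weight-layer reading of a "five dense layer / three hidden
layer" stack), relu activations, inverted dropout 0.2 after each hidden
layer, RMSprop at its standard defaults (lr 0.001, decay 0.9), MSE loss,
minibatches of 32, 300 epochs. It is implemented directly in NumPy with all
randomness (Glorot initialization, dropout masks, batch order) drawn from a
single seed, so training is bit-reproducible; the target is standardized
internally (history is recorded on that scale) and predictions are mapped
back. Widths and epochs are configurable downward for desk-scale runs. A
non-finite loss raises a divergence error naming the seed.

**Metrics.** R² is the squared Pearson correlation between predicted and
experimental values — the common QSAR convention — so anti-correlated
predictions also score near 1 while RMSE exposes them; the coefficient-of-
determination definition is available behind a flag. Constant truth leaves
R² undefined (NaN), reported as such.

## Synthetic fixture (recipe R1)

The fixture emulates a curated endpoint dataset at desk scale: 150 spherical
cores drawn from fcc Au/Ag/Pt/Pd, diameters 1.2–2.2 nm, decorated with 3–12
copies of one thiol ligand from {ethanethiol, mercaptoethanol, cysteamine,
butanethiol, thioglycolic acid}, all built through the regular builder and
descriptor pipeline (cores of a few hundred atoms keep tessellation in
milliseconds — a scale choice, not a method change). After zero-variance
filtering, five well-spread, mutually non-duplicate (|r| < 0.9) descriptor
columns are chosen; the endpoint is y = β·z + ε on the min-max scaled
columns with β ~ N(0,1) and σ set so the planted signal variance is exactly
4× the noise variance (the theoretical R² ceiling is therefore 0.8). The
recipe's own seed (default 0) fixes the generated dataset; the modeling
protocol consumes a separate seed for the split and the annealed selection.
All recipe parameters are logged in the dataset metadata.

What passing the fixture benchmark shows — and does not show: it
demonstrates that descriptor computation is informative enough, and the
selection + weighted-kNN machinery sound enough, to recover a planted linear
signal at 4:1 signal-to-noise through the full leakage-free protocol. Real
measured endpoints are nonlinear in the descriptors, noisier, and curated
from heterogeneous sources; performance there is an empirical question the
fixture cannot answer.

## Known limitations

- Crystalline cores are ideal lattice fragments: no relaxation,
  reconstruction, or faceting; rods always carry hemispherical caps.
- Ligand grafting is geometric; orientation and clash handling are a
  documented convention, and ligand density is always user-specified.
- DNA-origami and dendrimer structures are import-only (read from PDB);
  alloys, micelles, mesoporous materials, and MOFs are out of scope.
- The atomic property table carries reference-grade but rounded values;
  results are insensitive to small property errors since properties enter
  as per-class linear weights.
- Delaunay triangulations of exactly cospherical lattice points are
  non-unique; descriptor values for highly symmetric cores can differ in the
  last significant digits between Qhull builds.
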