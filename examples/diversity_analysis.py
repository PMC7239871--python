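"""Chemical-space diversity of a small mixed set of nanostructures.

Builds particles of several material classes, computes descriptors, removes
constant columns, min-max normalizes, and reports pairwise Euclidean
distances and the top principal components.
"""

import pandas as pd

from nanotess.builder import CNTSpec, CoreSpec, build_c60, build_cnt, build_core
from nanotess.descriptors import compute_descriptors, filter_descriptors
from nanotess.diversity import normalize, pairwise_distances, pca

structures = [
    build_core(CoreSpec("fcc-Au", diameter_nm=1.5, identifier="GNP-a")),
    build_core(CoreSpec("fcc-Ag", diameter_nm=1.5, identifier="AgNP-a")),
    build_core(CoreSpec("fcc-Pt", diameter_nm=1.2, identifier="PtNP-a")),
    build_core(CoreSpec("zincblende-CdSe", diameter_nm=1.8, identifier="QD-a")),
    build_cnt(CNTSpec(6, 6, periods=4)),
    build_c60(),
]
matrix = pd.DataFrame([compute_descriptors(s).values for s in structures])
filtered, kept, removed = filter_descriptors(matrix)
print(f"{len(matrix)} structures; {len(kept)} informative descriptors "
      f"({len(removed)} constant columns removed)")

norm = normalize(filtered)
dist = pairwise_distances(norm)
s = dist.attrs["summary"]
print(f"{s['count']} pairwise distances: min {s['min']:.3f}, "
      f"mean {s['mean']:.3f}, max {s['max']:.3f}")
print("most similar pair:", dist.loc[dist.distance.idxmin(), ["id_i", "id_j"]].tolist())

res = pca(norm, k=3)
print("explained variance fractions:",
      " ".join(f"{v:.1%}" for v in res.explained_variance_ratio))
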