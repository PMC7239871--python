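"""Compute the 2142 Delaunay-tessellation nanodescriptors of a structure.

Builds buckminsterfullerene, tessellates its 60 atoms into Delaunay
tetrahedra, types each tetrahedron by its four vertex atom classes, converts
occurrences to frequencies, and weights them with 17 atomic properties.
"""

from nanotess.builder import build_c60
from nanotess.descriptors import compute_descriptors

c60 = build_c60()
dv = compute_descriptors(c60)

nonzero = dv.values[dv.values != 0]
print(f"descriptor vector length: {len(dv.values)}  (17 properties x 126 classes)")
print(f"tetrahedron classes observed: {(dv.frequencies > 0).sum()} "
      f"(all-carbon cage -> only the C-C-C-C class)")
print(f"frequency sum: {dv.frequencies.sum():.12f}")
print("sample nonzero descriptors:")
print(nonzero.head(5).to_string())
print("each value = class frequency x mean per-tetrahedron property sum")
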