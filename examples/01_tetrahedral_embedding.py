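"""Embed base preferences in the tetrahedron and map shifts to energies.

A PSAM column (four relative affinities) becomes a 3D point; strict
single-base preferences sit on the vertices and indifference at the
origin.  Differences between two TFs' points are shift vectors whose
endpoint inverse-maps to dddG/RT values.
"""

import numpy as np

import familycode as fc

# a column preferring C with ddG/RT penalties (1.6, 0, 1.6, 1.6)
w = np.exp(-np.array([1.6, 0.0, 1.6, 1.6]))
point = fc.tetra_from_affinities(w)
print("C-preferring column ->", np.round(point, 3))
print("  (closest vertex is C at", fc.VERTICES[1], ")")

# a shift of +0.5 along x, inverse-mapped to energies
dddg = fc.shift_to_dddg(np.zeros(3), np.array([0.5, 0.0, 0.0]))
print("shift +0.5 x -> dddG/RT per base:", np.round(dddg, 3))
print("  negative = base gained preference (A, C); positive = lost (G, T)")

# an exterior point (impossible frequency for T) pulled back to the
# 1% relative-affinity plane before inverse mapping
exterior = np.array([0.9, 0.9, -0.9])
interior = fc.regularize(exterior)
column = fc.psam_column_from_tetra(interior)
print("exterior", exterior, "->", np.round(interior, 3))
print("  reconstructed affinities:", np.round(column, 3), "(T floored at 0.01)")
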