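"""Locate the residue positions that determine base preference.

Generates a synthetic family in which residue 13 controls the binding
model at DNA position D3, then scans every (residue, DNA position)
pair with a MANOVA on the tetrahedral point clouds.
"""

import familycode as fc

fam, compendium, truth = fc.make_family(fc.SyntheticFamilySpec(seed=1))
amap = fc.scan_associations(compendium, fam)

frame = amap.to_frame().dropna().sort_values("p").head(3)
print(frame.to_string(index=False))
print()
print("planted determinant:", truth.determinant_cells())
print("best cell found:    ", [amap.best_cell()])
print("significant cells (Bonferroni P < 0.001):", int(amap.significant().sum()))
print("  the planted (residue, DNA position) pair dominates the map;")
print("  every other cell is statistical background.")
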