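"""Generate the four-phenotype synthetic cohort and inspect its morphometry.

Two healthy phenotypes (round lumens, basal-dominant ventilation), one with
reduced circularity only, and one with reduced circularity plus lower-lobe
constriction. Trees are written in both the lossless JSON and the mm-table
CSV formats.
"""

from pathlib import Path

from aerotree import generate_tree, generate_volume_change, morphometry_table, write_tree
from aerotree.synthetic_data import PHENOTYPES

out = Path("cohort_out")
out.mkdir(exist_ok=True)

segments = ["Trachea", "RMB", "TriRUL", "BronInt", "RB9+10", "LB10"]
for name, spec in PHENOTYPES.items():
    tree = generate_tree(spec)
    dv = generate_volume_change(spec)
    write_tree(tree, out / f"{name}.json")
    write_tree(tree, out / f"{name}.csv")
    table = morphometry_table(tree, names=segments)
    print(f"\n{name}  (U/(M+L)|v = {dv.uml_ratio:.3f})")
    print(table[["Cr", "Dave_mm", "Dh_mm"]].round(3))

print(
    "\nSevere phenotypes show lower Cr everywhere; the constricted phenotype"
    "\nadditionally loses ~40% of Dave in lower-lobe branches, and both shift"
    "\nventilation (U/(M+L)|v) toward the upper lobes."
)
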