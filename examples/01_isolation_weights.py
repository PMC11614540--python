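"""Phylogenetic-isolation weights on a three-society toy tree.

Societies A and B split 1 time unit ago inside a clade that split from C
5 units ago, so C is the most isolated society and should receive the
largest resampling weight.
"""

import tempfile
from pathlib import Path

from ethnoloco import isolation_weights, patristic_distances, read_tree

with tempfile.TemporaryDirectory() as tmp:
    tree_path = Path(tmp) / "toy.nwk"
    tree_path.write_text("((A:1,B:1):4,C:5);\n")
    tree = read_tree(tree_path)

dist = patristic_distances(tree)
print("pairwise time distances:")
print(dist, "\n")

weights = isolation_weights(dist)
print("isolation weights (mean distance to every other society, normalized):")
print(weights, "\n")

sub = isolation_weights(dist, ["A", "C"])
print("re-derived on the subsample {A, C} (NOT a renormalization):")
print(sub)
print(
    "\nC carries 5/11 of the full-sample weight because it is twice as "
    "isolated as A or B; on the two-society subsample both weights are 0.5."
)
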