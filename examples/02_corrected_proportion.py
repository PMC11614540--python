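"""Raw versus phylogenetically corrected trait proportions.

A binary trait carried by the two closely related societies A and B but
not by the isolated C: the raw proportion is 2/3, but weighting by
isolation shrinks it to 6/11 because A and B partly duplicate the same
phylogenetic information.
"""

import tempfile
from pathlib import Path

from ethnoloco import (
    analytic_weighted_value,
    corrected_proportion,
    isolation_weights,
    patristic_distances,
    read_tree,
)

with tempfile.TemporaryDirectory() as tmp:
    p = Path(tmp) / "toy.nwk"
    p.write_text("((A:1,B:1):4,C:5);\n")
    tree = read_tree(p)

weights = isolation_weights(patristic_distances(tree))
trait = {"A": 1, "B": 1, "C": 0}

exact = analytic_weighted_value(trait, weights)
est = corrected_proportion(trait, weights, n_resamples=1_000_000, seed=42)

print(f"raw proportion:            {est.raw_value:.4f}  (2 of 3 societies)")
print(f"analytic corrected value:  {exact:.4f}  (= 6/11)")
print(f"resampled corrected value: {est.corrected_value:.4f} +- {est.mc_se:.4f} (MC s.e.)")
print(
    "\nThe resampled estimate agrees with the closed-form weighted "
    "expectation to within Monte-Carlo error."
)
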