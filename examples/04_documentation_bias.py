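"""How incomplete ethnographic documentation depresses presence counts.

Generates a perfectly documented synthetic corpus, then thins it with
decreasing documentation probability (whole society x modality cells
drop out together) and measures how many truly present traits are still
recovered by aggregation.
"""

from ethnoloco import GeneratorConfig, Modality, aggregate_society_codes, degrade, generate

cfg = GeneratorConfig(
    n_societies=200, documentation_prob=1.0, myth_rate=0.0,
    none_quote_rate=0.0, seed=99,
)
bundle = generate(cfg)
truth_present = sum(t[m].present for t in bundle.truth_codes for m in Modality)
print(f"truly present society x modality cells: {truth_present}")

print("\ndocumentation prob -> recovered presence (share of truth)")
for p in (1.0, 0.8, 0.6, 0.4, 0.2):
    thinned = degrade(bundle.quotes, p, seed=5)
    by_soc = {}
    for q in thinned:
        by_soc.setdefault(q.society_id, []).append(q)
    recovered = sum(
        aggregate_society_codes(by_soc.get(t.society_id, []), t.society_id)[m].present
        for t in bundle.truth_codes
        for m in Modality
    )
    print(f"  p = {p:.1f}: {recovered:4d}  ({100 * recovered / truth_present:5.1f}%)")

print(
    "\nRecovered presence tracks the documentation probability almost "
    "linearly: observed cross-cultural counts are a lower bound on true "
    "engagement when documentation is incomplete."
)
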