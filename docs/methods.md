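# Methods

## Scope and data model

The pipeline consumes three inputs: a quote-level database of coded
ethnographic passages on locomotor behaviour, a society covariate table,
and a rooted time-calibrated phylogeny of societies in Newick. It never
interprets prose: coding decisions (proficiency thresholds, functional
domain assignment, exclusion of myth/legend material) are the coder's,
made at quote level; the pipeline's job is deterministic aggregation,
weighting and summary.

A quote documents at most one modality (running, climbing, swimming or
diving; passages describing two modalities are entered as two rows) with
a proficiency evidence level (`none` / `basic` / `higher`), a set of
functional domains, an optional special activity (persistence hunting ↔
running, honey climbing ↔ climbing, underwater hunting ↔ diving), and
optional gender evidence. `none` means the passage is relevant but does
not document engagement; such quotes carry no further variables. Two
functional domains are modality-restricted: *observation* applies only
to climbing and *travel* only to running and swimming. These
applicability rules are enforced as hard parse errors on input and
re-checked as diagnostics on in-memory code tables.

### Sample eligibility

A society enters the analysis when (a) its cumulative dependence on
gathering + hunting + fishing strictly exceeds 56 percent and (b) at
least two non-excluded locomotion-relevant quotes exist for it. Excluded
quotes (myth/story/legend, non-traditional lifeways, ambiguous terms)
count toward nothing, including the two-quote gate: they are not
information on locomotor behaviour. Both thresholds are parameters
(`dependence_threshold`, `min_quotes`).

### Aggregation precedence

Per society × modality: presence is existential (any quote at `basic` or
`higher`); proficiency is the maximum under `not_documented < basic <
higher`, with `basic` as the default whenever engagement is documented;
functional domains and special activities are set unions; a modality
with no engaging quote gets the fully blank row. Aggregation is
order-independent and monotone: adding a non-excluded quote can only add
information.

Gender is resolved from the evidence multiset by explicit precedence:
no evidence → `insufficient_info`; an exclusivity statement stands only
while no evidence shows the other gender engaging, where "engaging"
includes any bias statement in either direction and any
both-genders-engage statement (a bias toward one gender asserts that
both engage); a contradicted exclusivity or a one-sided bias yields the
bias code; both genders evidenced without surviving directional
statements yield `both_no_bias`; directional statements on both sides
are a conflict, resolved as `both_no_bias` with a logged warning rather
than an error — mixed documentation is read as egalitarian engagement.
This is the weakest rule set consistent with the coding behaviour the
statistics assume (e.g. a female-exclusive aquatic code must survive
anecdotes that merely *mention* men, but not evidence of male
engagement). Quotes whose functional domains include child play carry
no gender evidence, even when other domains co-occur; this is the
conservative reading of the rule that children's play does not inform
adult gender engagement. The resolver is gender-symmetric by
construction (swapping female↔male labels everywhere swaps the output),
a property the test suite checks exhaustively for all evidence multisets
up to size three.

## Phylogenetic correction

"Time distance" between societies is implemented as patristic distance —
the sum of branch lengths along the unique tree path — rather than twice
the age of the most recent common ancestor. The two coincide on an
ultrametric tree, and patristic distance remains well defined when the
supertree is slightly non-ultrametric; the tree reader emits a warning
(diagnostic only) when root-to-tip depths vary by more than 1 percent.
Distances and weights are invariant to a global rescaling of branch
lengths, so the tree's absolute time units never matter.

A society's phylogenetic isolation is its mean distance to every *other*
society **in the subsample under analysis**; weights are these
isolations normalized to sum to one. Weights are always recomputed on
the exact denominator of a statistic (e.g. the societies with documented
subsistence climbing, when estimating the honey-climbing share), never
renormalized from the full-sample weights — the two differ whenever the
subsample's internal distances differ from the full sample's. A society
missing from the tree is a hard error, not a silent drop: silently
reweighting a reduced sample changes the estimand.

The corrected proportion is estimated by i.i.d. multinomial resampling
of single societies with probability equal to their weight (default
1,000,000 draws, configurable) rather than by whole-sample bootstrap
replicates: only point proportions are reported, and the estimator's
expectation — `sum_i w_i x_i` — is identical, which lets a closed-form
oracle pin the resampler's semantics in tests. Categorical shares are
computed from a single draw vector, so they partition the draws and sum
to one exactly. The reported Monte-Carlo error is the plug-in binomial
standard error; no confidence-interval machinery is attached because no
interval statistics are produced downstream. The default RNG seed is
20242553; all randomness flows through named, seedable `numpy`
generators, and the CLI derives stage-local seeds from one run seed by
hashing stage names so stages are independently rerunnable and the
five-subcommand chain reproduces `run-all` byte for byte.

### Which statistics are corrected

Correction policy is per-statistic, not global: modality presence,
versatility histogram, Venn regions, higher-proficiency shares and
special-activity shares carry corrected values; ecological breakdowns,
functional-domain shares, gender shares and the coastal split are raw
counts. Every output table carries a `corrected` tag. The coastal split
uses a 50 km threshold with strict inequality for "inland"; exactly
50 km counts as coastal.

### Biome simplification

The 14 WWF Major Habitat Type names (Olson terrestrial biomes) are
mapped to six analysis biomes (Boreal Forest/Taiga, Temperate Forest,
Tropical Forest, Desert, Grassland, Tundra). The map ships as an
editable TSV (`src/ethnoloco/data/biome_map.tsv`) rather than code;
name matching normalizes case, whitespace and the `&`/`and` spelling.
An unrecognized habitat name is a hard error naming the category.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not any real society's values.

* **Tree**: an ultrametric pure-birth (Yule) construction — exponential
  waiting times with rate `k·λ` while `k` lineages are active, all tips
  at the present. A configurable fraction of tips (default 0.45,
  matching the heavy regional over-representation the correction is
  designed for) is grafted as a separately simulated Yule clade whose
  depth is a small fraction of tree depth (default 0.15), producing many
  closely related, low-isolation societies. The construction is written
  in-package (~40 lines) for exact control of ultrametric depths and
  grafting; the emitted Newick is parsed back through `dendropy` by the
  same reader the pipeline uses, which the tests exploit as a round-trip
  guarantee.
* **Ecology**: biomes drawn from a configurable distribution (default
  roughly matching a worldwide forager sample: 30% tropical forest, 30%
  grassland/desert, 18% temperate forest, 22% boreal/tundra), temperature
  normal per biome, coast distance lognormal, foraging dependence drawn
  to pass the eligibility gate (total 65–95%, Dirichlet split).
* **Traits**: running universal; climbing, swimming, diving present with
  base probabilities 0.85/0.88/0.55 gated by biome temperature cutoffs
  (no diving below 4 °C, no swimming below −4 °C, no climbing below
  −11 °C), diving forced to imply swimming; higher-proficiency
  probabilities 0.30/0.65/0.18/0.20 per modality; functional domains and
  special activities drawn respecting the applicability mask; gender
  codes drawn from a distribution dominated by egalitarian engagement.
  These defaults are fixed once as a realistic forager-world
  configuration and are not tuned per analysis.
* **Documentation model**: each society × modality cell is documented
  with probability `documentation_prob` (default 0.9) — all-or-none, the
  same semantics as the `degrade` operation used for bias curves; quote
  counts are `1 + Poisson(mean_quotes − 1)`; excluded myth quotes appear
  at `myth_rate`; relevant-but-non-documenting quotes at
  `none_quote_rate`. Quote sets are constructed so that aggregation
  reproduces the truth cell exactly whenever the cell is documented:
  proficiency, domain unions, special activities and gender evidence are
  distributed across quotes without adding or losing information.
* **Gender reporting bias**: female-indicating evidence
  (female-exclusive, female-bias, both-engage) can be dropped with
  probability `female_dropout`, emulating the direction of ethnographic
  under-reporting of female engagement. The default is 0 so that the
  faithful-observer identity — perfect documentation recovers the truth
  exactly — holds under the documented two-knob condition
  (`documentation_prob = 1`, `myth_rate = 0`); the dropout is an opt-in
  bias experiment.

What the generator does **not** emulate: real covariate values of any
documented society, spatial (non-phylogenetic) autocorrelation,
correlated documentation effort across modalities within an
ethnographer, and inter-coder disagreement. Passing tests therefore
demonstrate the pipeline's correctness and the estimator's behaviour
under known structure, not the accuracy of any empirical claim about
real ethnographic data.

## Numerical and design choices

* Proportions are exact rationals of counts wherever no resampling is
  involved; resampled values are reproducible bit-for-bit under a fixed
  seed.
* Distance matrices are validated (symmetry, non-negativity, zero
  diagonal); an all-zero matrix (degenerate star of zero lengths) is an
  error rather than uniform weights.
* A two-society subsample always yields weights (0.5, 0.5) regardless of
  distance — the single off-diagonal entry normalizes away.
* Masked summary cells (observation × non-climbing, travel ×
  climbing/diving) are reported as not-applicable with NaN proportions,
  never as zero, so they cannot be mistaken for observed absences.
* Empty denominators (no society coded for gender in a modality; no
  subsistence societies for a special activity) yield NaN proportions
  and are reported as such.
* Problem sizes in the test suite and acceptance script (10^4–10^6
  resamples, 20-seed replicate sets, a 500-society recovery world) were
  chosen as the smallest sizes at which the Monte-Carlo tolerances
  (4 standard errors) are meaningful.

## Known limitations

* The aggregation rules are a reconstruction of coder-level practice
  from the coding statements the statistics imply; real deposited
  databases may encode edge cases (e.g. per-modality minimum quote
  thresholds) differently. Presence here requires a single engaging
  quote.
* The gender resolver collapses conflicting directional evidence to
  egalitarian engagement with a warning; it cannot represent "disputed".
* Patristic distance on a non-ultrametric tree weights tips with longer
  root-to-tip paths as more isolated; if a supertree's depth variation
  is an artefact, weights inherit it (hence the 1% diagnostic).
* The Monte-Carlo standard error describes resampling noise only; it
  says nothing about coding or documentation uncertainty, which the
  `degrade` curves show can dominate.
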