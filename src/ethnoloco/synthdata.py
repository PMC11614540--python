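"""Synthetic data generator for the whole pipeline.

Emulates the three inputs the analysis consumes — a time-calibrated
society tree, a society covariate table and a quote-level locomotor
database — with the statistical structure the method assumes:

* a pure-birth (Yule) ultrametric tree in which a configurable fraction
  of the tips sit inside one deliberately shallow clade, mimicking the
  regional over-representation (many closely related societies) that the
  phylogenetic correction exists to counter;
* biome-stratified ecologies with biome-specific temperature models;
* ground-truth society-level trait codes drawn from a trait model in
  which presence probabilities depend on ecology (e.g. no diving below a
  cold cutoff, diving implies swimming);
* quote records sampled from the truth under a documentation model:
  per society x modality, all quotes are observed with a documentation
  probability (all-or-none), myth-flagged excluded quotes appear at a
  configurable rate, and female-indicating gender evidence can be
  dropped to emulate gendered reporting bias.

With documentation probability 1 and myth rate 0 the quote corpus
aggregates back to the ground truth exactly (the faithful-observer
identity), which is the core parameter-recovery check for the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ethnoloco.coding import ModalityCode, Presence, SocietyCodes, write_codes
from ethnoloco.ethnodata import (
    APPLICABLE_MODALITIES,
    Biome6,
    FunctionalDomain,
    GenderCode,
    GenderEvidence,
    Modality,
    Proficiency,
    QuoteRecord,
    SocietyRecord,
    SpecialActivity,
    ExclusionReason,
    load_biome_map,
    write_quotes,
    write_societies,
)

__all__ = ["GeneratorConfig", "SyntheticBundle", "generate", "degrade", "yule_newick"]


def _default_biome_probs() -> dict[str, float]:
    # roughly the biome spread of a worldwide hunter-gatherer sample
    return {
        "TropicalForest": 0.30,
        "Grassland": 0.19,
        "Desert": 0.11,
        "TemperateForest": 0.18,
        "BorealForestTaiga": 0.13,
        "Tundra": 0.09,
    }


def _default_biome_temp() -> dict[str, tuple[float, float]]:
    # mean annual temperature (degrees C): biome mean and s.d.
    return {
        "TropicalForest": (24.0, 3.0),
        "Grassland": (15.0, 6.0),
        "Desert": (18.0, 5.0),
        "TemperateForest": (8.0, 4.0),
        "BorealForestTaiga": (-4.0, 4.0),
        "Tundra": (-12.0, 4.0),
    }


def _default_presence() -> dict[str, float]:
    # base presence probabilities per modality (before temperature gating)
    return {"running": 1.0, "climbing": 0.85, "swimming": 0.88, "diving": 0.55}


def _default_min_temp() -> dict[str, float]:
    # modality absent below these mean annual temperatures (degrees C)
    return {"running": -100.0, "climbing": -11.0, "swimming": -4.0, "diving": 4.0}


def _default_higher() -> dict[str, float]:
    return {"running": 0.30, "climbing": 0.65, "swimming": 0.18, "diving": 0.20}


def _default_gender() -> dict[str, float]:
    return {
        "both_no_bias": 0.52,
        "male_bias": 0.15,
        "female_bias": 0.03,
        "male_exclusive": 0.04,
        "female_exclusive": 0.01,
        "insufficient_info": 0.25,
    }


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic world.

    All probabilities are in [0, 1]; temperatures in degrees Celsius;
    tree time units are arbitrary (the isolation weights are invariant
    to a global rescaling of branch lengths).
    """

    n_societies: int = 53
    clustered_clade_fraction: float = 0.45
    birth_rate: float = 1.0
    tree_age: float = 100.0
    clade_depth_fraction: float = 0.15
    biome_probs: dict[str, float] = field(default_factory=_default_biome_probs)
    biome_temp: dict[str, tuple[float, float]] = field(default_factory=_default_biome_temp)
    presence_probs: dict[str, float] = field(default_factory=_default_presence)
    min_temp: dict[str, float] = field(default_factory=_default_min_temp)
    higher_probs: dict[str, float] = field(default_factory=_default_higher)
    subsistence_prob: float = 0.65
    domain_prob: float = 0.25
    special_prob: float = 0.40
    gender_probs: dict[str, float] = field(default_factory=_default_gender)
    documentation_prob: float = 0.9
    mean_quotes: float = 3.0
    myth_rate: float = 0.05
    none_quote_rate: float = 0.2
    female_dropout: float = 0.0
    seed: int = 20242553

    def validate(self) -> None:
        if self.n_societies < 3:
            raise ValueError("n_societies must be >= 3")
        if not 0.0 <= self.clustered_clade_fraction < 1.0:
            raise ValueError("clustered_clade_fraction must be in [0, 1)")
        for name, p in [
            ("documentation_prob", self.documentation_prob),
            ("myth_rate", self.myth_rate),
            ("none_quote_rate", self.none_quote_rate),
            ("female_dropout", self.female_dropout),
            ("subsistence_prob", self.subsistence_prob),
            ("domain_prob", self.domain_prob),
            ("special_prob", self.special_prob),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for d in (self.presence_probs, self.higher_probs, self.biome_probs,
                  self.gender_probs):
            for k, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {k}={p} outside [0, 1]")
        if abs(sum(self.biome_probs.values()) - 1.0) > 1e-6:
            raise ValueError("biome_probs must sum to 1")
        if abs(sum(self.gender_probs.values()) - 1.0) > 1e-6:
            raise ValueError("gender_probs must sum to 1")
        if self.birth_rate <= 0 or self.tree_age <= 0:
            raise ValueError("birth_rate and tree_age must be positive")
        if not 0.0 < self.clade_depth_fraction < 1.0:
            raise ValueError("clade_depth_fraction must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        data["biome_temp"] = {k: tuple(v) for k, v in data.get("biome_temp", {}).items()}
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Pure-birth ultrametric tree with a grafted shallow clade


class _Node:
    __slots__ = ("children", "start", "end", "label")

    def __init__(self, start: float):
        self.children: list[_Node] = []
        self.start = start
        self.end: float | None = None
        self.label: str | None = None


def _yule(n: int, rate: float, rng: np.random.Generator) -> tuple[_Node, float]:
    """Ultrametric pure-birth tree: waiting time between the k-th and the
    (k+1)-th lineage is exponential with rate k*birth_rate; all tips end
    at the present."""
    root = _Node(0.0)
    if n == 1:
        root.end = rng.exponential(1.0 / rate)
        return root, root.end
    t = 0.0
    active = [root]
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (k * rate))
        v = active.pop(rng.integers(len(active)))
        v.end = t
        v.children = [_Node(t), _Node(t)]
        active.extend(v.children)
    depth = t + rng.exponential(1.0 / (n * rate))
    for leaf in active:
        leaf.end = depth
    return root, depth


def _scale(node: _Node, factor: float) -> None:
    node.start *= factor
    if node.end is not None:
        node.end *= factor
    for c in node.children:
        _scale(c, factor)


def _shift(node: _Node, offset: float) -> None:
    node.start += offset
    if node.end is not None:
        node.end += offset
    for c in node.children:
        _shift(c, offset)


def _leaves(node: _Node) -> list[_Node]:
    if not node.children:
        return [node]
    out: list[_Node] = []
    for c in node.children:
        out.extend(_leaves(c))
    return out


def _to_newick(node: _Node, parent_start: float) -> str:
    length = (node.end if not node.children else node.children[0].start) - parent_start
    if not node.children:
        length = node.end - parent_start
        return f"{node.label}:{length:.10g}"
    inner = ",".join(_to_newick(c, node.end) for c in node.children)
    return f"({inner}):{node.end - parent_start:.10g}"


def _serialize(root: _Node) -> str:
    if not root.children:
        return f"({root.label}:{root.end - root.start:.10g});"
    inner = ",".join(_to_newick(c, root.end) for c in root.children)
    return f"({inner});"


def yule_newick(
    n: int,
    clade_fraction: float,
    rng: np.random.Generator,
    birth_rate: float = 1.0,
    tree_age: float = 100.0,
    clade_depth_fraction: float = 0.15,
    ids: Sequence[str] | None = None,
) -> tuple[str, list[str], list[str]]:
    """Ultrametric Yule tree with one shallow over-sampled clade.

    A background Yule tree of depth ``tree_age`` supplies the deep
    structure; one of its pendant edges is replaced by a rescaled Yule
    clade of depth roughly ``clade_depth_fraction * tree_age`` holding
    ``round(clade_fraction * n)`` tips.  Returns (newick, all ids in tip
    order, clade ids).
    """
    if ids is None:
        ids = [f"soc{i + 1:03d}" for i in range(n)]
    ids = list(ids)
    n_clade = int(round(clade_fraction * n))
    if n_clade < 2:
        root, depth = _yule(n, birth_rate, rng)
        _scale(root, tree_age / depth)
        root.end = root.end if not root.children else root.end
        for leaf, label in zip(_leaves(root), ids):
            leaf.label = label
        return _serialize(root), ids, []
    n_bg = n - n_clade + 1
    bg_root, bg_depth = _yule(n_bg, birth_rate, rng)
    _scale(bg_root, tree_age / bg_depth)
    bg_leaves = _leaves(bg_root)
    # graft onto the leaf with the longest pendant edge so the clade stays shallow
    host = max(bg_leaves, key=lambda l: l.end - l.start)
    pendant = host.end - host.start
    clade_depth = min(clade_depth_fraction * tree_age, 0.9 * pendant)
    clade_root, cd = _yule(n_clade, birth_rate, rng)
    _scale(clade_root, clade_depth / cd)
    _shift(clade_root, tree_age - clade_depth)
    # host leaf becomes the clade's stem node
    host.end = tree_age - clade_depth
    host.children = clade_root.children if clade_root.children else [clade_root]
    clade_ids = []
    others = [l for l in _leaves(bg_root) if l not in _leaves(host)]
    host_leaves = _leaves(host)
    pool = list(ids)
    for leaf in others:
        leaf.label = pool.pop(0)
    for leaf in host_leaves:
        label = pool.pop(0)
        leaf.label = label
        clade_ids.append(label)
    return _serialize(bg_root), ids, clade_ids


# ---------------------------------------------------------------------------
# Societies, truth codes, quotes


def _biome_mht_names() -> dict[str, list[str]]:
    inv: dict[str, list[str]] = {}
    for name, biome in load_biome_map().items():
        inv.setdefault(biome.value, []).append(name.title())
    return inv


def _draw_society(
    sid: str, cfg: GeneratorConfig, rng: np.random.Generator, mht_names
) -> SocietyRecord:
    biomes = list(cfg.biome_probs)
    biome = biomes[rng.choice(len(biomes), p=np.asarray(list(cfg.biome_probs.values())))]
    mu, sd = cfg.biome_temp[biome]
    temp = float(rng.normal(mu, sd))
    total = float(rng.uniform(65.0, 95.0))
    shares = rng.dirichlet([2.0, 2.0, 2.0]) * total
    coast = float(np.round(rng.lognormal(mean=3.0, sigma=1.3), 1))
    mht = mht_names[biome][int(rng.integers(len(mht_names[biome])))]
    return SocietyRecord(
        society_id=sid,
        name=sid.upper(),
        dependence_gathering=round(float(shares[0]), 1),
        dependence_hunting=round(float(shares[1]), 1),
        dependence_fishing=round(float(shares[2]), 1),
        mht_category=mht,
        mean_annual_temp_C=round(temp, 1),
        coast_distance_km=coast,
        biome6=Biome6(biome),
    )


_SPECIAL_FOR = {
    Modality.running: SpecialActivity.persistence_hunting,
    Modality.climbing: SpecialActivity.honey_climbing,
    Modality.diving: SpecialActivity.underwater_hunting,
}

_GENDER_EVIDENCE_FOR = {
    GenderCode.both_no_bias: GenderEvidence.both_no_bias,
    GenderCode.male_bias: GenderEvidence.male_bias,
    GenderCode.female_bias: GenderEvidence.female_bias,
    GenderCode.male_exclusive: GenderEvidence.male_exclusive,
    GenderCode.female_exclusive: GenderEvidence.female_exclusive,
}

_FEMALE_INDICATING = {
    GenderEvidence.female_exclusive,
    GenderEvidence.female_bias,
    GenderEvidence.both_no_bias,
}


def _draw_truth_code(
    society: SocietyRecord, modality: Modality, cfg: GeneratorConfig,
    rng: np.random.Generator, swim_present: bool | None = None,
) -> ModalityCode:
    p = cfg.presence_probs[modality.value]
    if society.mean_annual_temp_C < cfg.min_temp[modality.value]:
        p = 0.0
    if modality is Modality.diving and swim_present is False:
        p = 0.0  # diving implies swimming
    if rng.random() >= p:
        return ModalityCode()
    proficiency = (
        Proficiency.higher
        if rng.random() < cfg.higher_probs[modality.value]
        else Proficiency.basic
    )
    domains = set()
    if rng.random() < cfg.subsistence_prob:
        domains.add(FunctionalDomain.subsistence)
    for dom in FunctionalDomain:
        if dom is FunctionalDomain.subsistence:
            continue
        allowed = APPLICABLE_MODALITIES.get(dom)
        if allowed is not None and modality not in allowed:
            continue
        if rng.random() < cfg.domain_prob:
            domains.add(dom)
    activities = set()
    if (
        modality in _SPECIAL_FOR
        and FunctionalDomain.subsistence in domains
        and rng.random() < cfg.special_prob
    ):
        activities.add(_SPECIAL_FOR[modality])
    genders = list(cfg.gender_probs)
    gender = GenderCode(
        genders[rng.choice(len(genders), p=np.asarray(list(cfg.gender_probs.values())))]
    )
    return ModalityCode(
        presence=Presence.present,
        proficiency=proficiency,
        functional_domains=frozenset(domains),
        special_activities=frozenset(activities),
        gender=gender,
    )


def _quotes_for(
    society_id: str, modality: Modality, code: ModalityCode,
    cfg: GeneratorConfig, rng: np.random.Generator,
) -> list[QuoteRecord]:
    """Emit a quote set whose aggregation reproduces ``code`` exactly
    (before documentation dropout)."""
    quotes: list[QuoteRecord] = []

    def doc_id() -> str:
        return f"doc{int(rng.integers(1, 400)):03d}"

    if code.present:
        n_quotes = 1 + int(rng.poisson(max(cfg.mean_quotes - 1.0, 0.0)))
        profs = [Proficiency.basic] * n_quotes
        if code.proficiency is Proficiency.higher:
            profs[int(rng.integers(n_quotes))] = Proficiency.higher
        domain_assignment: list[set[FunctionalDomain]] = [set() for _ in range(n_quotes)]
        for dom in code.functional_domains:
            domain_assignment[int(rng.integers(n_quotes))].add(dom)
        activity_slot: dict[int, SpecialActivity] = {}
        for act in code.special_activities:
            free = [i for i in range(n_quotes) if i not in activity_slot]
            activity_slot[free[int(rng.integers(len(free)))] if free else 0] = act
        gender_evidence = _GENDER_EVIDENCE_FOR.get(code.gender)
        if gender_evidence is not None and cfg.female_dropout > 0:
            if gender_evidence in _FEMALE_INDICATING and rng.random() < cfg.female_dropout:
                gender_evidence = None  # reporting bias: female engagement unrecorded
        gender_slot = None
        if gender_evidence is not None:
            eligible = [
                i for i in range(n_quotes)
                if FunctionalDomain.child_play not in domain_assignment[i]
            ]
            if eligible:
                gender_slot = eligible[int(rng.integers(len(eligible)))]
            else:
                # every quote is child-play; add a plain one for the gender evidence
                domain_assignment.append(set())
                profs.append(Proficiency.basic)
                gender_slot = len(domain_assignment) - 1
                n_quotes += 1
        for i in range(n_quotes):
            quotes.append(
                QuoteRecord(
                    society_id=society_id,
                    document_id=doc_id(),
                    page=str(int(rng.integers(1, 500))),
                    modality=modality,
                    proficiency_evidence=profs[i],
                    functional_domains=frozenset(domain_assignment[i]),
                    special_activity=activity_slot.get(i),
                    gender_evidence=gender_evidence if i == gender_slot else None,
                )
            )
    elif rng.random() < cfg.none_quote_rate:
        # relevant passage that does not document engagement
        quotes.append(
            QuoteRecord(
                society_id=society_id,
                document_id=doc_id(),
                page=str(int(rng.integers(1, 500))),
                modality=modality,
                proficiency_evidence=Proficiency.none,
            )
        )
    if rng.random() < cfg.myth_rate:
        quotes.append(
            QuoteRecord(
                society_id=society_id,
                document_id=doc_id(),
                page=str(int(rng.integers(1, 500))),
                modality=modality,
                proficiency_evidence=Proficiency.basic,
                excluded=True,
                exclusion_reason=ExclusionReason.myth_story_legend,
                note="mythical episode",
            )
        )
    return quotes


@dataclass
class SyntheticBundle:
    """Everything one synthetic world consists of."""

    config: GeneratorConfig
    newick: str
    societies: list[SocietyRecord]
    truth_codes: list[SocietyCodes]
    quotes: list[QuoteRecord]
    clade_ids: list[str]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "societies": outdir / "societies.tsv",
            "truth_codes": outdir / "truth_codes.tsv",
            "quotes": outdir / "quotes.tsv",
            "config": outdir / "generator.yaml",
        }
        paths["tree"].write_text(self.newick + "\n", encoding="utf-8")
        write_societies(self.societies, paths["societies"])
        write_codes(self.truth_codes, paths["truth_codes"])
        write_quotes(self.quotes, paths["quotes"])
        self.config.to_yaml(paths["config"])
        return paths


def generate(cfg: GeneratorConfig) -> SyntheticBundle:
    """Generate a consistent synthetic world from one seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    newick, ids, clade_ids = yule_newick(
        cfg.n_societies,
        cfg.clustered_clade_fraction,
        rng,
        birth_rate=cfg.birth_rate,
        tree_age=cfg.tree_age,
        clade_depth_fraction=cfg.clade_depth_fraction,
    )
    mht_names = _biome_mht_names()
    societies = [_draw_society(sid, cfg, rng, mht_names) for sid in ids]
    truth: list[SocietyCodes] = []
    quotes: list[QuoteRecord] = []
    for soc in societies:
        codes: dict[Modality, ModalityCode] = {}
        swim = _draw_truth_code(soc, Modality.swimming, cfg, rng)
        codes[Modality.swimming] = swim
        for m in (Modality.running, Modality.climbing, Modality.diving):
            codes[m] = _draw_truth_code(soc, m, cfg, rng, swim_present=swim.present)
        truth.append(SocietyCodes(society_id=soc.society_id, codes=codes))
        for m in Modality:
            if rng.random() >= cfg.documentation_prob:
                continue  # whole society x modality cell goes unrecorded
            quotes.extend(_quotes_for(soc.society_id, m, codes[m], cfg, rng))
    return SyntheticBundle(
        config=cfg,
        newick=newick,
        societies=societies,
        truth_codes=truth,
        quotes=quotes,
        clade_ids=clade_ids,
    )


def degrade(
    quotes: Sequence[QuoteRecord], documentation_prob: float, seed: int = 0
) -> list[QuoteRecord]:
    """Thin the quote corpus: each society x modality cell survives
    all-or-none with the given probability.  Used to trace how presence
    counts decay as documentation gets poorer."""
    if not 0.0 <= documentation_prob <= 1.0:
        raise ValueError("documentation_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cells = sorted({(q.society_id, q.modality) for q in quotes})
    keep = {cell for cell in cells if rng.random() < documentation_prob}
    return [q for q in quotes if (q.society_id, q.modality) in keep]
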