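"""Domain types, tabular readers/writers and validators for the quote-level
locomotor database and the society covariate table.

The unit of raw data is the :class:`QuoteRecord`: one coded ethnographic
passage documenting (or failing to document) engagement in one locomotor
modality for one society.  Societies carry ecological covariates
(:class:`SocietyRecord`).  Files are plain UTF-8 tables, tab-separated by
preference (comma accepted), one header row; enumerations are parsed
case-insensitively and serialized in canonical ``snake_case``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Modality",
    "LocomotorDomain",
    "NON_BIPEDAL",
    "Proficiency",
    "FunctionalDomain",
    "SpecialActivity",
    "GenderEvidence",
    "GenderCode",
    "ExclusionReason",
    "Biome6",
    "QuoteRecord",
    "SocietyRecord",
    "TableParseError",
    "APPLICABLE_MODALITIES",
    "MODALITY_FOR_ACTIVITY",
    "biome_simplify",
    "load_biome_map",
    "read_quotes",
    "write_quotes",
    "read_societies",
    "write_societies",
    "eligible_societies",
]

_ID_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9_.\-]*$")


class LocomotorDomain(str, Enum):
    terrestrial = "terrestrial"
    arboreal = "arboreal"
    aquatic = "aquatic"


class Modality(str, Enum):
    """One of the four coded locomotor modalities."""

    running = "running"
    climbing = "climbing"
    swimming = "swimming"
    diving = "diving"

    @property
    def domain(self) -> LocomotorDomain:
        return _MODALITY_DOMAIN[self]


_MODALITY_DOMAIN = {
    Modality.running: LocomotorDomain.terrestrial,
    Modality.climbing: LocomotorDomain.arboreal,
    Modality.swimming: LocomotorDomain.aquatic,
    Modality.diving: LocomotorDomain.aquatic,
}

#: Climbing, swimming and diving — every modality other than running.
NON_BIPEDAL = (Modality.climbing, Modality.swimming, Modality.diving)


class Proficiency(str, Enum):
    """Quote-level proficiency evidence, ordered none < basic < higher.

    ``none`` means the passage is relevant to locomotion but does not
    document or clearly imply engagement; such quotes carry no further
    variables.
    """

    none = "none"
    basic = "basic"
    higher = "higher"

    @property
    def rank(self) -> int:
        return _PROFICIENCY_RANK[self]


_PROFICIENCY_RANK = {Proficiency.none: 0, Proficiency.basic: 1, Proficiency.higher: 2}


class FunctionalDomain(str, Enum):
    subsistence = "subsistence"
    non_edible_resources = "non_edible_resources"
    travel = "travel"
    child_play = "child_play"
    leisure = "leisure"
    ritual = "ritual"
    conflict = "conflict"
    protection = "protection"
    observation = "observation"


#: Functional domains restricted to particular modalities: 'observation'
#: is only applicable to climbing, 'travel' only to running and swimming.
APPLICABLE_MODALITIES = {
    FunctionalDomain.observation: frozenset({Modality.climbing}),
    FunctionalDomain.travel: frozenset({Modality.running, Modality.swimming}),
}


class SpecialActivity(str, Enum):
    persistence_hunting = "persistence_hunting"
    honey_climbing = "honey_climbing"
    underwater_hunting = "underwater_hunting"


MODALITY_FOR_ACTIVITY = {
    SpecialActivity.persistence_hunting: Modality.running,
    SpecialActivity.honey_climbing: Modality.climbing,
    SpecialActivity.underwater_hunting: Modality.diving,
}


class GenderEvidence(str, Enum):
    """Quote-level evidence on gendered engagement."""

    female_exclusive = "female_exclusive"
    male_exclusive = "male_exclusive"
    female_bias = "female_bias"
    male_bias = "male_bias"
    both_no_bias = "both_no_bias"


class GenderCode(str, Enum):
    """Society-level gender code (one per society x modality)."""

    female_exclusive = "female_exclusive"
    male_exclusive = "male_exclusive"
    female_bias = "female_bias"
    male_bias = "male_bias"
    both_no_bias = "both_no_bias"
    insufficient_info = "insufficient_info"


class ExclusionReason(str, Enum):
    myth_story_legend = "myth_story_legend"
    non_traditional_lifeway = "non_traditional_lifeway"
    ambiguous_term = "ambiguous_term"


class Biome6(str, Enum):
    """Six-way simplification of the WWF Major Habitat Types."""

    BorealForestTaiga = "BorealForestTaiga"
    TemperateForest = "TemperateForest"
    TropicalForest = "TropicalForest"
    Desert = "Desert"
    Grassland = "Grassland"
    Tundra = "Tundra"


class TableParseError(ValueError):
    """Raised when a tabular input contains invalid rows; the message lists
    every offending row with its row number."""


@dataclass(frozen=True)
class QuoteRecord:
    """One coded ethnographic passage.

    Invariants (enforced by :meth:`validate`):

    * a special activity must match its modality (persistence hunting is
      running, honey climbing is climbing, underwater hunting is diving);
    * ``proficiency_evidence == none`` implies no functional domains, no
      special activity and no gender evidence;
    * domain applicability: observation only with climbing, travel only
      with running or swimming;
    * an exclusion reason is only meaningful on an excluded record.
    """

    society_id: str
    document_id: str = ""
    page: str = ""
    modality: Modality = Modality.running
    proficiency_evidence: Proficiency = Proficiency.none
    functional_domains: frozenset[FunctionalDomain] = field(default_factory=frozenset)
    special_activity: SpecialActivity | None = None
    gender_evidence: GenderEvidence | None = None
    excluded: bool = False
    exclusion_reason: ExclusionReason | None = None
    note: str = ""

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not _ID_RE.match(self.society_id or ""):
            problems.append(f"bad society_id {self.society_id!r}")
        if self.special_activity is not None:
            want = MODALITY_FOR_ACTIVITY[self.special_activity]
            if self.modality is not want:
                problems.append(
                    f"special_activity {self.special_activity.value} requires "
                    f"modality {want.value}, got {self.modality.value}"
                )
        if self.proficiency_evidence is Proficiency.none:
            if self.functional_domains or self.special_activity or self.gender_evidence:
                problems.append(
                    "proficiency_evidence=none forbids functional_domains, "
                    "special_activity and gender_evidence"
                )
        for dom in self.functional_domains:
            allowed = APPLICABLE_MODALITIES.get(dom)
            if allowed is not None and self.modality not in allowed:
                problems.append(
                    f"domain {dom.value} not applicable to {self.modality.value}"
                )
        if self.exclusion_reason is not None and not self.excluded:
            problems.append("exclusion_reason given on a non-excluded record")
        return problems


@dataclass(frozen=True)
class SocietyRecord:
    """A society with its subsistence-dependence and ecological covariates."""

    society_id: str
    name: str
    dependence_gathering: float
    dependence_hunting: float
    dependence_fishing: float
    mht_category: str
    mean_annual_temp_C: float
    coast_distance_km: float
    biome6: Biome6 | None = None

    @property
    def forage_dependence(self) -> float:
        """Cumulative percent dependence on gathering, hunting and fishing."""
        return (
            self.dependence_gathering
            + self.dependence_hunting
            + self.dependence_fishing
        )

    def validate(self) -> list[str]:
        problems: list[str] = []
        if not _ID_RE.match(self.society_id or ""):
            problems.append(f"bad society_id {self.society_id!r}")
        for label, v in (
            ("dependence_gathering", self.dependence_gathering),
            ("dependence_hunting", self.dependence_hunting),
            ("dependence_fishing", self.dependence_fishing),
        ):
            if not 0.0 <= v <= 100.0:
                problems.append(f"{label}={v} outside [0, 100]")
        if self.forage_dependence > 100.0 + 1e-9:
            problems.append(f"dependence sum {self.forage_dependence} exceeds 100")
        if self.coast_distance_km < 0:
            problems.append("coast_distance_km must be non-negative")
        return problems


# ---------------------------------------------------------------------------
# Biome simplification


def load_biome_map(path: str | Path | None = None) -> dict[str, Biome6]:
    """Load the MHT-name -> six-biome map (editable TSV; package default)."""
    if path is None:
        with resources.files("ethnoloco.data").joinpath("biome_map.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return {
        _canon_mht(row.mht_category): Biome6(row.biome6)
        for row in table.itertuples()
    }


def _canon_mht(name: str) -> str:
    # normalise '&' vs 'and', whitespace and case so hand-edited tables match
    s = re.sub(r"\s+", " ", name.replace("&", "and")).strip().lower()
    return s


def biome_simplify(
    mht_category: str, biome_map: dict[str, Biome6] | None = None
) -> Biome6:
    """Map one of the 14 WWF Major Habitat Type names to its simplified biome.

    Raises ``KeyError`` naming the category when it is not in the map.
    """
    bmap = biome_map if biome_map is not None else _default_biome_map()
    key = _canon_mht(mht_category)
    if key not in bmap:
        raise KeyError(f"unknown WWF Major Habitat Type: {mht_category!r}")
    return bmap[key]


_BIOME_MAP_CACHE: dict[str, Biome6] | None = None


def _default_biome_map() -> dict[str, Biome6]:
    global _BIOME_MAP_CACHE
    if _BIOME_MAP_CACHE is None:
        _BIOME_MAP_CACHE = load_biome_map()
    return _BIOME_MAP_CACHE


# ---------------------------------------------------------------------------
# Tabular IO

QUOTE_COLUMNS = [
    "society_id",
    "document_id",
    "page",
    "modality",
    "proficiency_evidence",
    "functional_domains",
    "special_activity",
    "gender_evidence",
    "excluded",
    "exclusion_reason",
    "note",
]

SOCIETY_COLUMNS = [
    "society_id",
    "name",
    "dependence_gathering",
    "dependence_hunting",
    "dependence_fishing",
    "mht_category",
    "mean_annual_temp_C",
    "coast_distance_km",
]


def _sniff_delimiter(path: Path) -> str:
    header = path.read_text(encoding="utf-8").splitlines()[0]
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise TableParseError(f"{path}: missing required columns {missing}")
    return table


def _parse_enum(cls, raw: str, row: int, field_name: str, errors: list[str]):
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return cls(raw.lower())
    except ValueError:
        choices = ", ".join(m.value for m in cls)
        errors.append(f"row {row}: unknown {field_name} {raw!r} (one of: {choices})")
        return None


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in {"1", "true", "yes", "y"}


def read_quotes(path: str | Path) -> list[QuoteRecord]:
    """Parse the quote-level database.

    Every row is parsed or rejected with a row-number diagnostic; any
    invalid row makes the whole read fail with a :class:`TableParseError`
    listing all offending rows.
    """
    table = _read_table(path, QUOTE_COLUMNS)
    errors: list[str] = []
    records: list[QuoteRecord] = []
    for i, row in enumerate(table.itertuples(index=False), start=2):  # 1 = header
        modality = _parse_enum(Modality, row.modality, i, "modality", errors)
        prof = _parse_enum(
            Proficiency, row.proficiency_evidence, i, "proficiency_evidence", errors
        )
        domains: set[FunctionalDomain] = set()
        for tok in str(row.functional_domains).split(";"):
            if tok.strip():
                dom = _parse_enum(FunctionalDomain, tok, i, "functional_domain", errors)
                if dom is not None:
                    domains.add(dom)
        special = _parse_enum(
            SpecialActivity, row.special_activity, i, "special_activity", errors
        )
        gender = _parse_enum(
            GenderEvidence, row.gender_evidence, i, "gender_evidence", errors
        )
        reason = _parse_enum(
            ExclusionReason, row.exclusion_reason, i, "exclusion_reason", errors
        )
        if modality is None:
            errors.append(f"row {i}: modality is required")
            continue
        rec = QuoteRecord(
            society_id=str(row.society_id).strip(),
            document_id=str(row.document_id).strip(),
            page=str(row.page).strip(),
            modality=modality,
            proficiency_evidence=prof or Proficiency.none,
            functional_domains=frozenset(domains),
            special_activity=special,
            gender_evidence=gender,
            excluded=_parse_bool(str(row.excluded)),
            exclusion_reason=reason,
            note=str(row.note),
        )
        for problem in rec.validate():
            errors.append(f"row {i}: {problem}")
        records.append(rec)
    if errors:
        raise TableParseError(
            f"{path}: {len(errors)} invalid value(s):\n" + "\n".join(errors)
        )
    return records


def write_quotes(records: Iterable[QuoteRecord], path: str | Path) -> None:
    """Serialize quote records as a TSV (canonical snake_case values)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(QUOTE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.society_id,
                    r.document_id,
                    r.page,
                    r.modality.value,
                    r.proficiency_evidence.value,
                    ";".join(sorted(d.value for d in r.functional_domains)),
                    r.special_activity.value if r.special_activity else "",
                    r.gender_evidence.value if r.gender_evidence else "",
                    "true" if r.excluded else "false",
                    r.exclusion_reason.value if r.exclusion_reason else "",
                    r.note,
                ]
            )


def read_societies(
    path: str | Path, biome_map: dict[str, Biome6] | None = None
) -> list[SocietyRecord]:
    """Parse the society covariate table; ``biome6`` is derived from
    ``mht_category`` via :func:`biome_simplify`."""
    table = _read_table(path, SOCIETY_COLUMNS)
    errors: list[str] = []
    records: list[SocietyRecord] = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        try:
            biome = biome_simplify(str(row.mht_category), biome_map)
        except KeyError as exc:
            errors.append(f"row {i}: {exc.args[0]}")
            continue
        try:
            rec = SocietyRecord(
                society_id=str(row.society_id).strip(),
                name=str(row.name).strip(),
                dependence_gathering=float(row.dependence_gathering),
                dependence_hunting=float(row.dependence_hunting),
                dependence_fishing=float(row.dependence_fishing),
                mht_category=str(row.mht_category).strip(),
                mean_annual_temp_C=float(row.mean_annual_temp_C),
                coast_distance_km=float(row.coast_distance_km),
                biome6=biome,
            )
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        for problem in rec.validate():
            errors.append(f"row {i}: {problem}")
        records.append(rec)
    if errors:
        raise TableParseError(
            f"{path}: {len(errors)} invalid value(s):\n" + "\n".join(errors)
        )
    return records


def write_societies(records: Iterable[SocietyRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SOCIETY_COLUMNS + ["biome6"])
        for r in records:
            writer.writerow(
                [
                    r.society_id,
                    r.name,
                    _fmt(r.dependence_gathering),
                    _fmt(r.dependence_hunting),
                    _fmt(r.dependence_fishing),
                    r.mht_category,
                    _fmt(r.mean_annual_temp_C),
                    _fmt(r.coast_distance_km),
                    r.biome6.value if r.biome6 else "",
                ]
            )


def _fmt(x: float) -> str:
    return format(float(x), "g")


# ---------------------------------------------------------------------------
# Sample eligibility


def eligible_societies(
    societies: Sequence[SocietyRecord],
    quotes: Sequence[QuoteRecord],
    dependence_threshold: float = 56.0,
    min_quotes: int = 2,
) -> tuple[list[SocietyRecord], pd.DataFrame]:
    """Apply the sample-eligibility gates.

    A society is retained when its cumulative dependence on gathering,
    hunting and fishing strictly exceeds ``dependence_threshold`` percent
    and at least ``min_quotes`` non-excluded locomotion-relevant quotes
    were identified for it.  Returns the retained societies (input order)
    and an exclusion report with one row per dropped society.
    """
    n_quotes: dict[str, int] = {}
    for q in quotes:
        if not q.excluded:
            n_quotes[q.society_id] = n_quotes.get(q.society_id, 0) + 1
    kept: list[SocietyRecord] = []
    dropped: list[dict] = []
    for soc in societies:
        reasons = []
        if not soc.forage_dependence > dependence_threshold:
            reasons.append("low_forage_dependence")
        if n_quotes.get(soc.society_id, 0) < min_quotes:
            reasons.append("insufficient_quotes")
        if reasons:
            dropped.append(
                {
                    "society_id": soc.society_id,
                    "reason": ";".join(reasons),
                    "forage_dependence": soc.forage_dependence,
                    "n_quotes": n_quotes.get(soc.society_id, 0),
                }
            )
        else:
            kept.append(soc)
    report = pd.DataFrame(
        dropped, columns=["society_id", "reason", "forage_dependence", "n_quotes"]
    )
    return kept, report
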