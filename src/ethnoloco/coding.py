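"""Aggregation of quote-level codes into society-level trait codes.

One :class:`SocietyCodes` record summarises everything the quote database
says about one society: per modality, whether engagement is documented at
all, the highest proficiency evidenced, the union of functional domains
and special activities, and a single resolved gender code.

The aggregation is deterministic and order-independent: presence is an
existential over quotes, proficiency is a maximum under the ordering
``not_documented < basic < higher`` (basic being the default whenever any
engagement is documented), domains and activities are set unions, and
gender follows an explicit precedence over the evidence multiset
(:func:`resolve_gender`).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from ethnoloco.ethnodata import (
    FunctionalDomain,
    GenderCode,
    GenderEvidence,
    Modality,
    Proficiency,
    QuoteRecord,
    SpecialActivity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Presence",
    "ModalityCode",
    "SocietyCodes",
    "aggregate_society_codes",
    "resolve_gender",
    "validate_codes",
    "read_codes",
    "write_codes",
]


class Presence(str, Enum):
    not_documented = "not_documented"
    present = "present"


@dataclass(frozen=True)
class ModalityCode:
    """Society-level code for one modality."""

    presence: Presence = Presence.not_documented
    proficiency: Proficiency = Proficiency.none
    functional_domains: frozenset[FunctionalDomain] = field(default_factory=frozenset)
    special_activities: frozenset[SpecialActivity] = field(default_factory=frozenset)
    gender: GenderCode = GenderCode.insufficient_info

    @property
    def present(self) -> bool:
        return self.presence is Presence.present


NOT_DOCUMENTED = ModalityCode()


@dataclass(frozen=True)
class SocietyCodes:
    society_id: str
    codes: dict[Modality, ModalityCode] = field(default_factory=dict)

    def __post_init__(self):
        for m in Modality:
            self.codes.setdefault(m, NOT_DOCUMENTED)

    def __getitem__(self, modality: Modality) -> ModalityCode:
        return self.codes[modality]

    @property
    def n_non_bipedal(self) -> int:
        """Number of non-bipedal modalities (climb, swim, dive) present."""
        return sum(
            self.codes[m].present
            for m in (Modality.climbing, Modality.swimming, Modality.diving)
        )


# ---------------------------------------------------------------------------
# Gender resolution

_FEMALE_SIDE = {GenderEvidence.female_exclusive, GenderEvidence.female_bias}
_MALE_SIDE = {GenderEvidence.male_exclusive, GenderEvidence.male_bias}


def resolve_gender(evidence: Iterable[GenderEvidence]) -> GenderCode:
    """Resolve a multiset of quote-level gender evidence to one code.

    Precedence, weakest rules first:

    1. no evidence -> ``insufficient_info``;
    2. an exclusivity statement stands only while no evidence shows the
       other gender engaging (a bias statement toward either gender, or a
       both-engage statement, counts as engagement of both genders);
    3. a contradicted exclusivity, or any one-sided bias, yields the
       corresponding bias code;
    4. both genders evidenced with no surviving directional statement
       yields ``both_no_bias``;
    5. directional statements on both sides conflict: resolved as
       ``both_no_bias`` with a logged warning.
    """
    ev = list(evidence)
    if not ev:
        return GenderCode.insufficient_info
    evset = set(ev)
    # engagement: who is evidenced to take part at all?
    female_engaged = bool(
        evset
        & {
            GenderEvidence.female_exclusive,
            GenderEvidence.female_bias,
            GenderEvidence.male_bias,
            GenderEvidence.both_no_bias,
        }
    )
    male_engaged = bool(
        evset
        & {
            GenderEvidence.male_exclusive,
            GenderEvidence.male_bias,
            GenderEvidence.female_bias,
            GenderEvidence.both_no_bias,
        }
    )
    if GenderEvidence.male_exclusive in evset and not female_engaged:
        return GenderCode.male_exclusive
    if GenderEvidence.female_exclusive in evset and not male_engaged:
        return GenderCode.female_exclusive
    male_leaning = bool(evset & _MALE_SIDE)
    female_leaning = bool(evset & _FEMALE_SIDE)
    if male_leaning and female_leaning:
        logger.warning(
            "conflicting gender evidence %s resolved to both_no_bias",
            sorted(e.value for e in evset),
        )
        return GenderCode.both_no_bias
    if male_leaning:
        return GenderCode.male_bias
    if female_leaning:
        return GenderCode.female_bias
    return GenderCode.both_no_bias


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_society_codes(
    quotes: Sequence[QuoteRecord], society_id: str
) -> SocietyCodes:
    """Combine the quote-level codes of one society into a SocietyCodes.

    Excluded quotes contribute nothing.  A modality with no engaging quote
    (every quote at proficiency ``none``, or no quote at all) yields the
    ``not_documented`` row with no further variables.  Quotes whose
    functional domains include child play contribute no gender evidence.
    """
    mine = [q for q in quotes if q.society_id == society_id and not q.excluded]
    codes: dict[Modality, ModalityCode] = {}
    for modality in Modality:
        qs = [q for q in mine if q.modality is modality]
        engaging = [q for q in qs if q.proficiency_evidence is not Proficiency.none]
        if not engaging:
            codes[modality] = NOT_DOCUMENTED
            continue
        proficiency = (
            Proficiency.higher
            if any(q.proficiency_evidence is Proficiency.higher for q in engaging)
            else Proficiency.basic
        )
        domains = frozenset().union(*(q.functional_domains for q in engaging))
        activities = frozenset(
            q.special_activity for q in engaging if q.special_activity is not None
        )
        gender = resolve_gender(
            q.gender_evidence
            for q in engaging
            if q.gender_evidence is not None
            and FunctionalDomain.child_play not in q.functional_domains
        )
        codes[modality] = ModalityCode(
            presence=Presence.present,
            proficiency=proficiency,
            functional_domains=domains,
            special_activities=activities,
            gender=gender,
        )
    return SocietyCodes(society_id=society_id, codes=codes)


def validate_codes(all_codes: Sequence[SocietyCodes]) -> list[str]:
    """Report (never enforce) data-level expectations.

    Currently one check: every society documented to dive should also be
    documented to swim (diving implies surface swimming in practice).
    """
    diagnostics = []
    for sc in all_codes:
        if sc[Modality.diving].present and not sc[Modality.swimming].present:
            diagnostics.append(
                f"{sc.society_id}: diving present but swimming not documented"
            )
    return diagnostics


# ---------------------------------------------------------------------------
# IO: one row per society, grouped columns per modality

_CODE_FIELDS = ["presence", "proficiency", "functional_domains", "special_activities", "gender"]


def _code_columns() -> list[str]:
    return ["society_id"] + [
        f"{m.value}_{f}" for m in Modality for f in _CODE_FIELDS
    ]


def write_codes(all_codes: Iterable[SocietyCodes], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_code_columns())
        for sc in all_codes:
            row: list[str] = [sc.society_id]
            for m in Modality:
                c = sc[m]
                row += [
                    c.presence.value,
                    c.proficiency.value if c.present else "not_documented",
                    ";".join(sorted(d.value for d in c.functional_domains)),
                    ";".join(sorted(a.value for a in c.special_activities)),
                    c.gender.value,
                ]
            writer.writerow(row)


def read_codes(path: str | Path) -> list[SocietyCodes]:
    import pandas as pd

    sep = "\t" if "\t" in Path(path).read_text(encoding="utf-8").splitlines()[0] else ","
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    out: list[SocietyCodes] = []
    for _, row in table.iterrows():
        codes: dict[Modality, ModalityCode] = {}
        for m in Modality:
            presence = Presence(row[f"{m.value}_presence"])
            if presence is Presence.not_documented:
                codes[m] = NOT_DOCUMENTED
                continue
            prof_raw = row[f"{m.value}_proficiency"]
            codes[m] = ModalityCode(
                presence=presence,
                proficiency=Proficiency(prof_raw),
                functional_domains=frozenset(
                    FunctionalDomain(t)
                    for t in row[f"{m.value}_functional_domains"].split(";")
                    if t
                ),
                special_activities=frozenset(
                    SpecialActivity(t)
                    for t in row[f"{m.value}_special_activities"].split(";")
                    if t
                ),
                gender=GenderCode(row[f"{m.value}_gender"]),
            )
        out.append(SocietyCodes(society_id=row["society_id"], codes=codes))
    return out
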