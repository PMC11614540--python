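import numpy as np
import pytest

from ethnoloco.coding import ModalityCode, Presence, SocietyCodes
from ethnoloco.ethnodata import (
    Biome6,
    FunctionalDomain,
    GenderCode,
    Modality,
    Proficiency,
    SocietyRecord,
    SpecialActivity,
)

TOY_NEWICK = "((A:1,B:1):4,C:5);"

_MOD_BY_LETTER = {
    "R": Modality.running,
    "C": Modality.climbing,
    "S": Modality.swimming,
    "D": Modality.diving,
}


def make_codes(
    society_id,
    present="",
    higher="",
    domains=None,
    specials=None,
    gender=None,
):
    """Build a SocietyCodes from compact letter strings (R/C/S/D)."""
    domains = domains or {}
    specials = specials or {}
    gender = gender or {}
    codes = {}
    for letter, m in _MOD_BY_LETTER.items():
        if letter not in present:
            codes[m] = ModalityCode()
            continue
        codes[m] = ModalityCode(
            presence=Presence.present,
            proficiency=Proficiency.higher if letter in higher else Proficiency.basic,
            functional_domains=frozenset(domains.get(letter, ())),
            special_activities=frozenset(specials.get(letter, ())),
            gender=gender.get(letter, GenderCode.insufficient_info),
        )
    return SocietyCodes(society_id=society_id, codes=codes)


def make_society(
    society_id,
    temp=15.0,
    coast=10.0,
    biome=Biome6.Grassland,
    dep=(40.0, 30.0, 10.0),
):
    mht = {
        Biome6.Grassland: "Temperate Grasslands, Savannas and Shrublands",
        Biome6.TropicalForest: "Tropical and Subtropical Moist Broadleaf Forests",
        Biome6.TemperateForest: "Temperate Conifer Forests",
        Biome6.Desert: "Deserts and Xeric Shrublands",
        Biome6.BorealForestTaiga: "Boreal Forests/Taiga",
        Biome6.Tundra: "Tundra",
    }[biome]
    return SocietyRecord(
        society_id=society_id,
        name=society_id,
        dependence_gathering=dep[0],
        dependence_hunting=dep[1],
        dependence_fishing=dep[2],
        mht_category=mht,
        mean_annual_temp_C=temp,
        coast_distance_km=coast,
        biome6=biome,
    )


def random_codes(rng: np.random.Generator, society_id: str) -> SocietyCodes:
    present = "".join(l for l in "RCSD" if rng.random() < 0.6)
    higher = "".join(l for l in present if rng.random() < 0.3)
    genders = list(GenderCode)
    gender = {l: genders[int(rng.integers(len(genders)))] for l in present}
    domains = {}
    for l in present:
        m = _MOD_BY_LETTER[l]
        pool = [
            d
            for d in FunctionalDomain
            if d not in (FunctionalDomain.travel, FunctionalDomain.observation)
        ]
        if m is Modality.climbing:
            pool.append(FunctionalDomain.observation)
        if m in (Modality.running, Modality.swimming):
            pool.append(FunctionalDomain.travel)
        domains[l] = {d for d in pool if rng.random() < 0.3}
    specials = {}
    if "R" in present and FunctionalDomain.subsistence in domains.get("R", set()):
        if rng.random() < 0.5:
            specials["R"] = {SpecialActivity.persistence_hunting}
    return make_codes(society_id, present, higher, domains, specials, gender)


@pytest.fixture
def toy_tree_path(tmp_path):
    p = tmp_path / "toy.nwk"
    p.write_text(TOY_NEWICK + "\n", encoding="utf-8")
    return p


@pytest.fixture
def toy_codes():
    """Four societies engaging in {C,S,D}, {C}, {S}, {} (running for all)."""
    return [
        make_codes("s1", "RCSD"),
        make_codes("s2", "RC"),
        make_codes("s3", "RS"),
        make_codes("s4", "R"),
    ]
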