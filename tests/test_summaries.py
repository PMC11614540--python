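"""Headline summary statistics on toy and random code sets."""

import numpy as np
import pandas as pd
import pytest

from ethnoloco.ethnodata import (
    Biome6,
    FunctionalDomain,
    GenderCode,
    Modality,
    SpecialActivity,
)
from ethnoloco.summaries import (
    coastal_split,
    ecology_breakdown,
    functional_domain_proportions,
    gender_proportions,
    higher_proficiency_shares,
    modality_presence_counts,
    special_activity_stats,
    summarize_all,
    venn_proportions,
    versatility_histogram,
)

from conftest import make_codes, make_society


def _uniform_weights(codes):
    ids = [c.society_id for c in codes]
    n = len(ids)
    return pd.DataFrame(
        {"raw_isolation": np.ones(n), "weight": np.full(n, 1.0 / n)}, index=ids
    )


class TestPresenceAndVersatility:
    def test_toy_counts(self, toy_codes):
        t = modality_presence_counts(toy_codes).set_index("modality")
        assert t.loc["climbing", "n_present"] == 2
        assert t.loc["swimming", "n_present"] == 2
        assert t.loc["diving", "n_present"] == 1
        assert t.loc["running", "raw_prop"] == 1.0

    def test_all_present_sample(self):
        codes = [make_codes(f"s{i}", "RCSD") for i in range(3)]
        t = modality_presence_counts(codes)
        assert (t["raw_prop"] == 1.0).all()

    def test_toy_histogram(self, toy_codes):
        t = versatility_histogram(toy_codes).set_index("stratum")
        assert t.loc["0", "count"] == 1
        assert t.loc["1", "count"] == 2
        assert t.loc["2", "count"] == 0
        assert t.loc["3", "count"] == 1
        assert t.loc["any_non_bipedal", "count"] == 3
        assert t.loc["all_three_domains", "count"] == 1  # s1 only

    def test_all_absent_mass_at_zero(self):
        codes = [make_codes(f"s{i}", "R") for i in range(4)]
        t = versatility_histogram(codes).set_index("stratum")
        assert t.loc["0", "count"] == 4
        assert t.loc["any_non_bipedal", "count"] == 0

    def test_corrected_shares_sum_to_one(self, toy_codes):
        w = _uniform_weights(toy_codes)
        t = versatility_histogram(toy_codes, w, n_resamples=2000, seed=2)
        strata = t.set_index("stratum").loc[["0", "1", "2", "3"], "corrected_prop"]
        assert strata.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_weights_recover_raw(self, toy_codes):
        w = _uniform_weights(toy_codes)
        t = modality_presence_counts(toy_codes, w, n_resamples=200_000, seed=4)
        for _, row in t.iterrows():
            assert abs(row.corrected_prop - row.raw_prop) <= 4 * max(row.mc_se, 1e-4)


class TestVenn:
    def test_toy_uniform_regions(self, toy_codes):
        w = _uniform_weights(toy_codes)
        t = venn_proportions(toy_codes, w, n_resamples=100_000, seed=6).set_index(
            "region"
        )
        assert t.loc["C", "count"] == 1
        assert t.loc["S", "count"] == 1
        assert t.loc["CSD", "count"] == 1
        assert t.loc["none", "count"] == 1
        for region in ("C", "S", "CSD", "none"):
            assert t.loc[region, "corrected_prop"] == pytest.approx(0.25, abs=0.01)
        assert t["count"].drop("none").sum() == 3

    def test_regions_partition_any_non_bipedal_mass(self, toy_codes):
        w = _uniform_weights(toy_codes)
        venn = venn_proportions(toy_codes, w, n_resamples=5000, seed=8)
        hist = versatility_histogram(toy_codes, w, n_resamples=5000, seed=8)
        venn_mass = venn.set_index("region")["corrected_prop"].drop("none").sum()
        any_nb = hist.set_index("stratum").loc["any_non_bipedal", "corrected_prop"]
        assert venn_mass == pytest.approx(any_nb, abs=1e-12)

    def test_diving_only_region_empty_when_dive_implies_swim(self):
        codes = [make_codes("s1", "RSD"), make_codes("s2", "RS"), make_codes("s3", "R")]
        t = venn_proportions(codes).set_index("region")
        assert t.loc["D", "count"] == 0 and t.loc["CD", "count"] == 0


class TestEcology:
    def test_min_swim_temperature(self):
        codes = [make_codes(f"s{i}", "RS") for i in range(3)]
        socs = [
            make_society("s0", temp=-3.0),
            make_society("s1", temp=4.0),
            make_society("s2", temp=12.0),
        ]
        t = ecology_breakdown(codes, socs)["temperature"].set_index("modality")
        assert t.loc["swimming", "min_temp_C"] == -3.0

    def test_diving_confined_to_tropical_forest(self):
        codes = [make_codes("s1", "RSD"), make_codes("s2", "RS")]
        socs = [
            make_society("s1", biome=Biome6.TropicalForest, temp=25.0),
            make_society("s2", biome=Biome6.Tundra, temp=-10.0),
        ]
        t = ecology_breakdown(codes, socs)["by_biome"]
        dive = t[t.modality == "diving"].set_index("biome6")
        assert dive.loc["TropicalForest", "n_present"] == 1
        assert (dive.drop("TropicalForest")["n_present"] == 0).all()

    def test_below_zero_counts(self):
        codes = [make_codes("s1", "RCS"), make_codes("s2", "R"), make_codes("s3", "RC")]
        socs = [
            make_society("s1", temp=-3.0),
            make_society("s2", temp=-16.0),
            make_society("s3", temp=5.0),
        ]
        t = ecology_breakdown(codes, socs)["temperature"].set_index("modality")
        assert t.loc["climbing", "n_below_0C_present"] == 1
        assert t.loc["climbing", "n_below_0C_total"] == 2

    def test_biome_totals_equal_whole_sample_counts(self):
        rng = np.random.default_rng(0)
        from conftest import random_codes

        codes = [random_codes(rng, f"s{i}") for i in range(30)]
        biomes = list(Biome6)
        socs = [
            make_society(f"s{i}", biome=biomes[int(rng.integers(len(biomes)))])
            for i in range(30)
        ]
        by_biome = ecology_breakdown(codes, socs)["by_biome"]
        whole = modality_presence_counts(codes).set_index("modality")
        for m in Modality:
            total = by_biome[by_biome.modality == m.value]["n_present"].sum()
            assert total == whole.loc[m.value, "n_present"]


class TestFunctionalDomains:
    def test_toy_ratio(self):
        codes = [
            make_codes("s1", "RC", domains={"C": {FunctionalDomain.subsistence}}),
            make_codes("s2", "RC", domains={"C": {FunctionalDomain.subsistence}}),
            make_codes("s3", "RC", domains={"C": {FunctionalDomain.leisure}}),
        ]
        t, diags = functional_domain_proportions(codes)
        row = t[(t.modality == "climbing") & (t.domain == "subsistence")].iloc[0]
        assert row.raw_prop == pytest.approx(2 / 3)
        assert diags == []

    def test_masked_cells_not_applicable_never_zero(self, toy_codes):
        t, _ = functional_domain_proportions(toy_codes)
        obs = t[t.domain == "observation"].set_index("modality")
        assert bool(obs.loc["climbing", "applicable"])
        for m in ("running", "swimming", "diving"):
            assert not bool(obs.loc[m, "applicable"])
            assert np.isnan(obs.loc[m, "raw_prop"])
        trav = t[t.domain == "travel"].set_index("modality")
        assert bool(trav.loc["running", "applicable"]) and bool(
            trav.loc["swimming", "applicable"]
        )
        assert not bool(trav.loc["climbing", "applicable"])

    def test_domain_in_masked_cell_diagnosed(self):
        codes = [make_codes("s1", "RD")]
        # force an illegal observation code onto diving
        from ethnoloco.coding import ModalityCode, Presence, SocietyCodes
        from ethnoloco.ethnodata import Proficiency

        bad = SocietyCodes(
            "s1",
            {
                Modality.diving: ModalityCode(
                    presence=Presence.present,
                    proficiency=Proficiency.basic,
                    functional_domains=frozenset({FunctionalDomain.observation}),
                )
            },
        )
        _, diags = functional_domain_proportions([bad])
        assert diags and "observation" in diags[0]

    def test_absent_modality_has_zero_denominator(self):
        codes = [make_codes("s1", "R")]
        t, _ = functional_domain_proportions(codes)
        assert (t[t.modality == "diving"]["denominator"] == 0).all()


class TestSpecialActivities:
    def test_all_subsistence_runners_persistence_hunt(self):
        codes = [
            make_codes(
                "s%d" % i,
                "R",
                domains={"R": {FunctionalDomain.subsistence}},
                specials={"R": {SpecialActivity.persistence_hunting}},
            )
            for i in range(3)
        ]
        t = special_activity_stats(codes).set_index("activity")
        assert t.loc["persistence_hunting", "raw_prop"] == 1.0

    def test_subsample_weights_from_toy_tree(self, toy_tree_path):
        from ethnoloco.phyloweight import patristic_distances, read_tree

        dist = patristic_distances(read_tree(toy_tree_path))
        codes = [
            make_codes("A", "C", domains={"C": {FunctionalDomain.subsistence}},
                       specials={"C": {SpecialActivity.honey_climbing}}),
            make_codes("B", "C", domains={"C": {FunctionalDomain.subsistence}}),
            make_codes("C", "C", domains={"C": {FunctionalDomain.subsistence}}),
        ]
        t = special_activity_stats(codes, dist, n_resamples=300_000, seed=13)
        row = t.set_index("activity").loc["honey_climbing"]
        # analytic oracle: honey climber A carries weight 3/11
        assert abs(row.corrected_prop - 3 / 11) <= 4 * row.mc_se
        assert row.denominator == 3 and row.numerator == 1

    def test_denominator_excludes_non_subsistence(self):
        codes = [
            make_codes("s1", "R", domains={"R": {FunctionalDomain.leisure}}),
            make_codes("s2", "R", domains={"R": {FunctionalDomain.subsistence}}),
        ]
        t = special_activity_stats(codes).set_index("activity")
        assert t.loc["persistence_hunting", "denominator"] == 1


class TestGender:
    def test_toy_ratio_and_denominator(self):
        codes = [
            make_codes("s1", "R", gender={"R": GenderCode.male_bias}),
            make_codes("s2", "R", gender={"R": GenderCode.both_no_bias}),
            make_codes("s3", "R", gender={"R": GenderCode.both_no_bias}),
            make_codes("s4", "R", gender={"R": GenderCode.both_no_bias}),
            make_codes("s5", "R"),  # insufficient info: not in the denominator
        ]
        t = gender_proportions(codes)
        run = t[t.modality == "running"].set_index("gender")
        assert (run["denominator"] == 4).all()
        assert run.loc["male_bias", "raw_prop"] == pytest.approx(0.25)

    def test_all_insufficient_reported_as_empty(self):
        codes = [make_codes("s1", "R"), make_codes("s2", "R")]
        t = gender_proportions(codes)
        assert (t["denominator"] == 0).all()
        assert t["raw_prop"].isna().all()


class TestCoastal:
    def test_toy_inland_count(self):
        codes = [make_codes(f"s{i}", "RS") for i in range(3)]
        socs = [
            make_society("s0", coast=10.0),
            make_society("s1", coast=60.0),
            make_society("s2", coast=200.0),
        ]
        t = coastal_split(codes, socs).set_index("modality")
        assert t.loc["swimming", "n_inland"] == 2
        assert t.loc["swimming", "n_coastal"] == 1

    def test_exactly_50km_is_coastal(self):
        codes = [make_codes("s0", "RS")]
        socs = [make_society("s0", coast=50.0)]
        t = coastal_split(codes, socs).set_index("modality")
        assert t.loc["swimming", "n_coastal"] == 1

    def test_all_at_coast(self):
        codes = [make_codes(f"s{i}", "RSD") for i in range(2)]
        socs = [make_society(f"s{i}", coast=0.0) for i in range(2)]
        t = coastal_split(codes, socs)
        assert (t["n_inland"] == 0).all()


def test_summarize_all_bundle_is_consistent(toy_tree_path):
    from ethnoloco.phyloweight import patristic_distances, read_tree
    from ethnoloco.summaries import summaries_to_json
    import json

    codes = [make_codes("A", "RCSD"), make_codes("B", "RC"), make_codes("C", "RS")]
    socs = [make_society(x) for x in "ABC"]
    dist = patristic_distances(read_tree(toy_tree_path))
    bundle = summarize_all(codes, socs, dist, n_resamples=2000, seed=17)
    assert bundle["n_societies"] == 3
    assert bundle["modality_presence"]["corrected"].all()
    json.dumps(summaries_to_json(bundle))  # JSON-serializable
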