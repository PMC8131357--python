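"""Roster construction: scanner, confidence, extrapolation, merge, filter."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pollidiv.roster import (DataError, Roster, RosterEntry, TaxonEvidence,
                             assign_confidence, compile_roster,
                             evidence_from_corpus, extract_binomials,
                             extrapolate_groups, filter_records)
from pollidiv.simulate import SimConfig, generate_corpus


# --- binomial scanner -------------------------------------------------------

def test_extract_single_binomial(toy_taxonomy):
    assert extract_binomials("Bombus terrestris visited flowers",
                             toy_taxonomy) == {"Bombus"}


def test_extract_requires_reference_match(toy_taxonomy):
    # Ficus is a plant, absent from the animal reference list
    got = extract_binomials("Ficus carica and Apis mellifera co-occur",
                            toy_taxonomy)
    assert got == {"Apis"}


@pytest.mark.parametrize("text", [
    "no binomials here at all",
    "Capitalised Words without epithets",
    "Apis X malformed",                   # epithet not lowercase
    "Apis is mentioned alone",            # epithet shorter than 3 letters
])
def test_extract_rejects_malformed(text, toy_taxonomy):
    assert extract_binomials(text, toy_taxonomy) == set()


def test_extract_empty_taxonomy_errors(toy_taxonomy):
    with pytest.raises(DataError):
        extract_binomials("Apis mellifera", toy_taxonomy.iloc[0:0])


# --- evidence and confidence ------------------------------------------------

def test_evidence_record_validation():
    with pytest.raises(ValueError):
        TaxonEvidence("Apis", 2, negative=True)     # both positive and negative
    with pytest.raises(ValueError):
        TaxonEvidence("Apis", 7)


def test_best_evidence_wins():
    ev = [TaxonEvidence("Apis", 3), TaxonEvidence("Apis", 2)]
    conf, block = assign_confidence(ev)
    assert conf == {"Apis": 2} and block == set()
    ev = [TaxonEvidence("Apis", 1), TaxonEvidence("Apis", 4),
          TaxonEvidence("Apis", 4)]
    assert assign_confidence(ev)[0] == {"Apis": 1}


def test_negative_only_goes_to_blocklist():
    ev = [TaxonEvidence("Thomisus", None, negative=True)]
    conf, block = assign_confidence(ev)
    assert "Thomisus" not in conf and block == {"Thomisus"}


def test_positive_beats_negative_for_the_genus_itself():
    ev = [TaxonEvidence("Apis", 2),
          TaxonEvidence("Apis", None, negative=True)]
    conf, block = assign_confidence(ev)
    assert conf == {"Apis": 2} and block == set()


# --- extrapolation ----------------------------------------------------------

def test_family_from_two_subfamily_branches(toy_taxonomy):
    # evidence in 2 of 3 Apidae subfamilies, nothing blocked
    groups = extrapolate_groups({"Apis": 1, "Xylocopa": 3}, set(),
                                toy_taxonomy)
    assert {(e.taxon, e.level) for e in groups} == {("Apidae", "family")}


def test_single_genus_family_yields_nothing(toy_taxonomy):
    # the elephant-shrew case: keep only the genus, no group entry
    groups = extrapolate_groups({"Elephantulus": 2}, set(), toy_taxonomy)
    assert groups == []


def test_blocklist_blocks_family_but_not_lower_groups(toy_taxonomy):
    # Apinae has 3 confident genera in 3 tribes; Nomada (Nomadinae) blocked
    conf = {"Apis": 1, "Bombus": 2, "Euglossa": 2, "Xylocopa": 3,
            "Ceratina": 4}
    groups = extrapolate_groups(conf, {"Nomada"}, toy_taxonomy)
    got = {(e.taxon, e.level) for e in groups}
    assert ("Apidae", "family") not in got
    assert ("Apinae", "subfamily") in got
    assert ("Xylocopinae", "subfamily") in got


def test_genera_without_subfamily_form_own_branches(toy_taxonomy):
    # Syrphidae genera sit directly under the family: 2 confident -> family
    groups = extrapolate_groups({"Eristalis": 2, "Syrphus": 3}, set(),
                                toy_taxonomy)
    assert {(e.taxon, e.level) for e in groups} == {("Syrphidae", "family")}


def test_min_branches_configurable(toy_taxonomy):
    conf = {"Eristalis": 2, "Syrphus": 3}
    assert extrapolate_groups(conf, set(), toy_taxonomy, min_branches=3) == []
    with pytest.raises(ValueError):
        extrapolate_groups(conf, set(), toy_taxonomy, min_branches=1)


def test_orphan_genus_is_data_error(toy_taxonomy):
    bad = toy_taxonomy.copy()
    bad.loc[0, "family"] = None
    with pytest.raises(DataError):
        extrapolate_groups({"Apis": 1}, set(), bad)


# --- compile + precedence ---------------------------------------------------

def test_direct_confidence_beats_extrapolation(toy_taxonomy):
    groups = [RosterEntry("Apidae", "family", "extrapolated", "extrapolated")]
    roster = compile_roster({"Apis": 2}, groups, toy_taxonomy)
    assert roster.genus_confidence()["Apis"] == 2
    assert ("Apidae", "family") in roster.group_set()
    assert "Bombus" in roster.covered_genera


def test_expert_removal_of_group_keeps_direct_genus(toy_taxonomy):
    groups = [RosterEntry("Apidae", "family", "extrapolated", "extrapolated")]
    roster = compile_roster({"Apis": 2}, groups, toy_taxonomy,
                            edits=[("remove", "Apidae", "family")])
    assert ("Apidae", "family") not in roster.group_set()
    assert "Bombus" not in roster.covered_genera   # extrapolation-only genus gone
    assert roster.genus_confidence()["Apis"] == 2  # direct evidence retained


def test_expert_add_and_remove_missing_warns(toy_taxonomy):
    with pytest.warns(UserWarning):
        roster = compile_roster({}, [], toy_taxonomy,
                                edits=[("remove", "Vespidae", "family"),
                                       ("add", "Elephantulus", "genus")])
    assert [e.provenance for e in roster.entries] == ["expert_added"]


def test_empty_inputs_empty_roster(toy_taxonomy):
    roster = compile_roster({}, [], toy_taxonomy)
    assert roster.entries == [] and roster.covered_genera == set()


def test_compile_is_idempotent(toy_taxonomy):
    groups = [RosterEntry("Syrphidae", "family", "extrapolated",
                          "extrapolated")]
    r1 = compile_roster({"Apis": 1, "Bombus": 3}, groups, toy_taxonomy)
    r2 = compile_roster(r1.genus_confidence(),
                        [e for e in r1.entries if e.level != "genus"],
                        toy_taxonomy)
    assert r1.to_frame().equals(r2.to_frame())
    assert r1.covered_genera == r2.covered_genera


@given(st.dictionaries(
    st.sampled_from(["Apis", "Bombus", "Xylocopa", "Eristalis", "Syrphus"]),
    st.integers(min_value=1, max_value=4), max_size=5))
def test_no_genus_carries_two_confidences(direct):
    import pandas as pd
    tax = pd.DataFrame({
        "genus": ["Apis", "Bombus", "Xylocopa", "Eristalis", "Syrphus"],
        "tribe": [None] * 5, "subfamily": [None] * 5,
        "family": ["Apidae"] * 3 + ["Syrphidae"] * 2,
        "order": ["Hymenoptera"] * 3 + ["Diptera"] * 2,
        "class": ["Insecta"] * 5})
    groups = extrapolate_groups(direct, set(), tax)
    roster = compile_roster(direct, groups, tax)
    conf = roster.genus_confidence()
    names = [e.taxon for e in roster.entries if e.level == "genus"]
    assert len(names) == len(set(names))
    assert conf == direct


# --- survey filtering -------------------------------------------------------

def make_survey():
    return pd.DataFrame({
        "SS": ["st1"] * 4, "SSB": ["b1"] * 4,
        "SSBS": ["s1", "s1", "s1", "s2"],
        "Genus": ["Apis", "Bombus", "Thomisus", "Thomisus"],
        "Family": ["Apidae", "Apidae", "Thomisidae", "Thomisidae"],
        "Measurement": [1.0, 2.0, 3.0, 4.0],
    })


def test_filter_keeps_roster_records_and_drops_empty_sites(toy_taxonomy):
    roster = compile_roster({"Apis": 1, "Bombus": 2}, [], toy_taxonomy)
    out = filter_records(make_survey(), roster)
    assert len(out) == 2 and set(out.SSBS) == {"s1"}   # s2 only non-roster


def test_filter_identity_when_roster_covers_all(toy_taxonomy):
    roster = compile_roster({"Apis": 1, "Bombus": 2, "Thomisus": 4}, [],
                            toy_taxonomy)
    out = filter_records(make_survey(), roster)
    assert out.equals(make_survey())


def test_filter_uses_group_expansion(toy_taxonomy):
    groups = [RosterEntry("Apidae", "family", "extrapolated", "extrapolated")]
    roster = compile_roster({}, groups, toy_taxonomy)
    out = filter_records(make_survey(), roster)
    assert set(out.Genus) == {"Apis", "Bombus"}


def test_filter_missing_columns(toy_taxonomy):
    roster = compile_roster({"Apis": 1}, [], toy_taxonomy)
    with pytest.raises(DataError):
        filter_records(make_survey().drop(columns=["Genus"]), roster)


# --- full chain against planted truth --------------------------------------

@pytest.mark.parametrize("seed", range(8))
def test_full_chain_recovers_planted_roster(seed):
    cfg = SimConfig(seed=seed)
    corpus, tax, truth = generate_corpus(cfg)
    ev = evidence_from_corpus(corpus, tax)
    conf, block = assign_confidence(ev)
    groups = extrapolate_groups(conf, block, tax)
    roster = compile_roster(conf, groups, tax, blocklist=block)
    assert conf == truth.direct_confidence
    assert block == truth.blocklist
    assert roster.group_set() == truth.group_entries
    assert roster.covered_genera | set(conf) == truth.pollinator_genera
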