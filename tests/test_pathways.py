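"""Pathway-completeness logic and cross-strain summaries."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from symsift.pathways import (
    CapabilityVerdict,
    EnzymeProfile,
    Enzyme,
    EntrySubstrate,
    PathwayDef,
    PathwayStep,
    VERDICT_ORDER,
    evaluate_pathway,
    load_pathway_defs,
    save_pathway_defs,
    summarize_strains,
)

DXP = "1-deoxy-d-xylulose-5-phosphate"

MEP_ENZYMES = ["dxs", "dxr", "ispd", "ispe", "ispf", "ispg", "isph"]


def defs_by_id():
    return {d.pathway_id: d for d in load_pathway_defs()}


def mep_profile(strain="s", **status):
    entries = {k: "present" for k in MEP_ENZYMES}
    entries.update(status)
    return EnzymeProfile(strain, entries)


class TestDefinitions:
    def test_builtin_set_covers_the_five_pathways(self):
        ids = set(defs_by_id())
        assert ids == {
            "MEP_00900",
            "SAM_00270",
            "ZEATIN_00908",
            "IAA_00380",
            "ADENINE_SALVAGE_00230",
        }

    def test_empty_step_rejected(self):
        with pytest.raises(ValueError):
            PathwayDef("p", "p", [], [], [PathwayStep("s", [])])

    def test_entry_substrate_must_map_to_a_step(self):
        enz = Enzyme("e", "e", "e", ["1.1.1.1"])
        with pytest.raises(ValueError):
            PathwayDef(
                "p",
                "p",
                [],
                [EntrySubstrate("x", 5)],
                [PathwayStep("s", [enz])],
            )

    def test_unknown_enzyme_key_in_logic_rejected(self, tmp_path):
        import json

        doc = {
            "enzymes": {},
            "pathways": [
                {"id": "p", "steps": [{"name": "s", "alternatives": ["ghost"]}]}
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="unknown enzyme key"):
            load_pathway_defs(path)

    def test_round_trip_preserves_structure(self, tmp_path):
        defs = load_pathway_defs()
        out = tmp_path / "defs.json"
        save_pathway_defs(defs, out)
        back = load_pathway_defs(out)
        assert [d.pathway_id for d in back] == [d.pathway_id for d in defs]
        for a, b in zip(defs, back):
            assert [s.name for s in a.steps] == [s.name for s in b.steps]
            assert [
                [e.key for e in s.alternatives] for s in a.steps
            ] == [[e.key for e in s.alternatives] for s in b.steps]
            assert a.entry_substrates == b.entry_substrates


class TestEvaluateMep:
    def test_symbiont_style_profile_is_incapable(self):
        # dxs gene lost and ispG frameshifted: the host-suppliable DXP entry
        # cannot rescue the broken penultimate step
        profile = mep_profile(dxs="absent", ispg="pseudogene")
        v = evaluate_pathway(profile, defs_by_id()["MEP_00900"])
        assert v.verdict == "incapable"
        causes = {
            e["key"]: e["cause"] for step in v.missing_steps for e in step["enzymes"]
        }
        assert causes == {"dxs": "absent", "ispg": "pseudogene"}

    def test_dxs_only_loss_is_conditional_on_dxp(self):
        v = evaluate_pathway(mep_profile(dxs="absent"), defs_by_id()["MEP_00900"])
        assert v.verdict == "conditional"
        assert v.required_supplements == [DXP]

    def test_complete_profile_is_capable(self):
        v = evaluate_pathway(mep_profile(), defs_by_id()["MEP_00900"])
        assert v.verdict == "capable"
        assert v.missing_steps == []

    def test_ec_number_keys_resolve_like_symbols(self):
        profile = EnzymeProfile(
            "s",
            {
                "2.2.1.7": "absent",
                "1.1.1.267": "present",
                "2.7.7.60": "present",
                "2.7.1.148": "present",
                "4.6.1.12": "present",
                "1.17.7.1": "present",
                "1.17.7.4": "present",
            },
        )
        v = evaluate_pathway(profile, defs_by_id()["MEP_00900"])
        assert v.verdict == "conditional"
        assert v.required_supplements == [DXP]


class TestEvaluateSam:
    def test_reduced_genome_needs_host_methionine(self):
        profile = EnzymeProfile(
            "s",
            {"asd": "present", "LASS": "present", "metC": "present", "metK": "present"},
        )
        v = evaluate_pathway(profile, defs_by_id()["SAM_00270"])
        # methionine synthesis itself is broken ...
        missing = {step["step"] for step in v.missing_steps}
        assert "methionine synthesis" in missing
        # ... but SAM is reachable given host-supplied L-methionine
        assert v.verdict == "conditional"
        assert v.required_supplements == ["L-methionine"]
        assert "L-homoserine" not in v.required_supplements


class TestEvaluateOthers:
    def test_mia_genes_support_trna_cytokinin_route(self):
        profile = EnzymeProfile("s", {"miaA": "present", "miaB": "present"})
        v = evaluate_pathway(profile, defs_by_id()["ZEATIN_00908"])
        assert v.verdict == "capable"

    def test_no_iaa_enzymes_means_incapable(self):
        v = evaluate_pathway(EnzymeProfile("s", {}), defs_by_id()["IAA_00380"])
        assert v.verdict == "incapable"

    def test_verdict_invariants_enforced(self):
        with pytest.raises(ValueError):
            CapabilityVerdict("s", "p", "conditional")


def toy_pathway():
    ez = {k: Enzyme(k, k, k, []) for k in "abcd"}
    return PathwayDef(
        "TOY",
        "toy",
        ["product"],
        [EntrySubstrate("start", 0), EntrySubstrate("mid", 2)],
        [PathwayStep(k, [ez[k]]) for k in "abcd"],
    )


def oracle_verdict(statuses):
    """Independent enumeration oracle for the 4-step toy pathway."""
    sat = [s == "present" for s in statuses]
    if all(sat):
        return "capable"
    unsat = [i for i, ok in enumerate(sat) if not ok]
    if all(i < 2 for i in unsat):  # the 'mid' substrate enters before step 2
        return "conditional"
    return "incapable"


class TestToyPathwayOracle:
    def test_exhaustive_truth_table_agreement(self):
        pw = toy_pathway()
        for statuses in itertools.product(
            ["present", "absent", "pseudogene"], repeat=4
        ):
            profile = EnzymeProfile("s", dict(zip("abcd", statuses)))
            v = evaluate_pathway(profile, pw)
            assert v.verdict == oracle_verdict(statuses), statuses

    def test_pseudogene_is_equivalent_to_absent(self):
        pw = toy_pathway()
        for statuses in itertools.product(
            ["present", "absent", "pseudogene"], repeat=4
        ):
            swapped = ["absent" if s == "pseudogene" else s for s in statuses]
            v1 = evaluate_pathway(EnzymeProfile("s", dict(zip("abcd", statuses))), pw)
            v2 = evaluate_pathway(EnzymeProfile("s", dict(zip("abcd", swapped))), pw)
            assert v1.verdict == v2.verdict

    @given(
        st.lists(
            st.sampled_from(["present", "absent", "pseudogene"]),
            min_size=4,
            max_size=4,
        ),
        st.integers(0, 3),
    )
    def test_adding_an_enzyme_never_downgrades(self, statuses, which):
        pw = toy_pathway()
        before = evaluate_pathway(EnzymeProfile("s", dict(zip("abcd", statuses))), pw)
        upgraded = list(statuses)
        upgraded[which] = "present"
        after = evaluate_pathway(EnzymeProfile("s", dict(zip("abcd", upgraded))), pw)
        assert VERDICT_ORDER[after.verdict] >= VERDICT_ORDER[before.verdict]


class TestSummarizeStrains:
    def test_complete_strains_lose_nothing(self):
        pw = toy_pathway()
        profiles = [
            EnzymeProfile(f"s{i}", {k: "present" for k in "abcd"}) for i in range(4)
        ]
        s = summarize_strains(profiles, pw)
        assert all(v == 0.0 for v in s.missing_fraction.values())
        assert s.verdict_fractions["capable"] == 1.0
        assert s.missing_count_distribution == {0: 4}

    def test_fractions_match_brute_force_column_tallies(self):
        pw = toy_pathway()
        matrix = {
            "s1": {"a": "present", "b": "absent", "c": "present", "d": "present"},
            "s2": {"a": "pseudogene", "b": "absent", "c": "present", "d": "present"},
            "s3": {"a": "present", "b": "present", "c": "absent", "d": "present"},
            "s4": {"a": "present", "b": "present", "c": "present", "d": "absent"},
        }
        profiles = [EnzymeProfile(k, v) for k, v in matrix.items()]
        s = summarize_strains(profiles, pw)
        for enzyme in "abcd":
            expected = sum(
                1 for row in matrix.values() if row[enzyme] != "present"
            ) / len(matrix)
            assert s.missing_fraction[enzyme] == pytest.approx(expected)

    def test_one_in_five_conditional_mirror(self):
        # 1 of 5 strains lacks only dxs (rescuable by DXP); the rest also
        # lost ispG -> conditional fraction 20%
        mep = defs_by_id()["MEP_00900"]
        profiles = [mep_profile("s0", dxs="absent")] + [
            mep_profile(f"s{i}", dxs="absent", ispg="absent") for i in range(1, 5)
        ]
        s = summarize_strains(profiles, mep)
        assert s.verdict_fractions["conditional"] == pytest.approx(0.20)
        assert s.verdict_fractions["incapable"] == pytest.approx(0.80)
        assert s.missing_fraction["dxs"] == 1.0
        assert s.missing_fraction["ispg"] == pytest.approx(0.80)
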