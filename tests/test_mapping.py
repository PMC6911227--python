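"""Mapping paths, hierarchy resolution, provenance, and map I/O."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phemap import (
    PathLabel,
    PhecodeMap,
    Resource,
    TerminologyError,
    Vocabulary,
    build_fixture_bundle,
    build_map,
    is_strict_ancestor,
    read_map,
    resolve_hierarchy,
    write_map,
)
from phemap.mapping import (
    MappingRecord,
    concept_path,
    cui_shortcut_path,
    direct_string_match,
    gems_path,
)


def _rec(code, phecode, vocab=Vocabulary.ICD10CM):
    from phemap.mapping import Hop

    hop = Hop(vocab, code, Vocabulary.PHECODE, phecode,
              Resource.STRING_MATCH)
    return MappingRecord(vocab, code, phecode, PathLabel.A_DIRECT_STRING,
                         ((hop,),))


class TestDirectStringMatch:
    def test_presbyopia_matches(self, bundle):
        records = direct_string_match(
            bundle.code_table(Vocabulary.ICD10CM), bundle.phecodes,
            Vocabulary.ICD10CM,
        )
        hits = {(r.source_code, r.phecode) for r in records}
        assert ("H52.4", "367.4") in hits

    def test_case_insensitive(self, bundle):
        codes = bundle.code_table(Vocabulary.ICD10CM).copy()
        codes.loc[codes["code"] == "H52.4", "description"] = "PRESBYOPIA"
        records = direct_string_match(codes, bundle.phecodes,
                                      Vocabulary.ICD10CM)
        assert any(r.source_code == "H52.4" and r.phecode == "367.4"
                   for r in records)

    def test_no_shared_descriptions(self, bundle):
        codes = bundle.code_table(Vocabulary.ICD10CM).copy()
        codes["description"] = "nothing shared " + codes["code"]
        assert direct_string_match(codes, bundle.phecodes,
                                   Vocabulary.ICD10CM) == []


class TestGemsPath:
    def test_e119_chain(self, bundle):
        hits = {(r.source_code, r.phecode) for r in gems_path(bundle)}
        assert ("E11.9", "250.2") in hits

    def test_two_gems_targets_two_records(self, bundle):
        records = [r for r in gems_path(bundle) if r.source_code == "I25.708"]
        assert {r.phecode for r in records} == {"411.3", "411.4"}

    def test_dead_end_chain_yields_nothing(self, bundle):
        # GEMS target with no phecode-map entry
        gems = bundle.edge_table(Resource.GEMS).copy()
        gems.loc[len(gems)] = ["ICD10CM", "H52.4", "ICD9CM", "999.99", 1]
        bundle2 = bundle.__class__(
            codes=bundle.codes,
            edges={**bundle.edges, Resource.GEMS: gems},
            phecodes=bundle.phecodes,
        )
        assert not any(r.source_code == "H52.4" for r in gems_path(bundle2))

    def test_matches_bruteforce_two_hop_join(self, bundle):
        gems = bundle.edge_table(Resource.GEMS)
        i9 = bundle.edge_table(Resource.ICD9_PHECODE_MAP)
        expected = {
            (g["source_code"], m["target_code"])
            for _, g in gems.iterrows()
            for _, m in i9.iterrows()
            if g["target_code"] == m["source_code"]
        }
        got = {(r.source_code, r.phecode) for r in gems_path(bundle)}
        assert got == expected


class TestConceptPath:
    def test_l0100_five_hop_ohdsi_chain(self, bundle):
        records = concept_path(bundle, Vocabulary.ICD10CM,
                               Resource.OHDSI_REL)
        rec = next(r for r in records if r.source_code == "L01.00")
        assert rec.phecode == "686.2"
        assert rec.path_label is PathLabel.E_SNOMED_OHDSI
        chain = rec.provenance[0]
        assert [h.target_code for h in chain] == [
            "C0021099", "48277006", "140480", "44832600", "684", "686.2"
        ]

    def test_broken_chain_dropped(self, bundle):
        edges = dict(bundle.edges)
        # remove the CUI->SNOMED hop: chain can no longer complete
        cui = edges[Resource.UMLS_CUI]
        edges[Resource.UMLS_CUI] = cui[cui["source_vocab"] != "CUI"]
        bundle2 = bundle.__class__(codes=bundle.codes, edges=edges,
                                   phecodes=bundle.phecodes)
        assert concept_path(bundle2, Vocabulary.ICD10CM,
                            Resource.OHDSI_REL) == []

    def test_b211_two_nlm_records(self, bundle):
        records = [
            r for r in concept_path(bundle, Vocabulary.ICD10,
                                    Resource.NLM_MAP)
            if r.source_code == "B21.1"
        ]
        assert {r.phecode for r in records} == {"071.1", "202.2"}
        assert all(r.path_label is PathLabel.D_SNOMED_NLM for r in records)

    def test_nlm_one_to_many_excluded_by_default(self, bundle):
        edges = dict(bundle.edges)
        nlm = edges[Resource.NLM_MAP].copy()
        # make SNOMED 86406008 map to two ICD-9-CM codes
        nlm.loc[len(nlm)] = ["SNOMED", "86406008", "ICD9CM", "250.0", 0]
        bundle2 = bundle.__class__(codes=bundle.codes,
                                   edges={**edges, Resource.NLM_MAP: nlm},
                                   phecodes=bundle.phecodes)
        default = concept_path(bundle2, Vocabulary.ICD10, Resource.NLM_MAP)
        # the one-to-many source contributes nothing by default
        assert {r.phecode for r in default
                if r.source_code == "B21.1"} == {"202.2"}
        permissive = concept_path(bundle2, Vocabulary.ICD10,
                                  Resource.NLM_MAP,
                                  include_nlm_one_to_many=True)
        assert {"071.1", "202.2", "250.2"} <= {
            r.phecode for r in permissive if r.source_code == "B21.1"
        }

    def test_ohdsi_cycle_terminates(self, bundle):
        edges = dict(bundle.edges)
        rel = edges[Resource.OHDSI_REL].copy()
        rel.loc[len(rel)] = ["OHDSI_CONCEPT", "44832600", "OHDSI_CONCEPT",
                             "140480", 0]  # back-edge: cycle
        bundle2 = bundle.__class__(codes=bundle.codes,
                                   edges={**edges, Resource.OHDSI_REL: rel},
                                   phecodes=bundle.phecodes)
        records = concept_path(bundle2, Vocabulary.ICD10CM,
                               Resource.OHDSI_REL)
        assert {r.phecode for r in records
                if r.source_code == "L01.00"} == {"686.2"}


class TestResolveHierarchy:
    def test_parent_dropped_for_child(self):
        kept = resolve_hierarchy([_rec("I10", "401"), _rec("I10", "401.1")])
        assert {r.phecode for r in kept} == {"401.1"}

    def test_unrelated_families_both_kept(self):
        kept = resolve_hierarchy(
            [_rec("D57.812", "282.5"), _rec("D57.812", "289.5")]
        )
        assert {r.phecode for r in kept} == {"282.5", "289.5"}

    def test_transitive_three_level_chain(self):
        kept = resolve_hierarchy(
            [_rec("X11", "250"), _rec("X11", "250.2"), _rec("X11", "250.23")]
        )
        assert {r.phecode for r in kept} == {"250.23"}

    def test_idempotent(self):
        records = [_rec("I10", "401"), _rec("I10", "401.1"),
                   _rec("I10", "250.2")]
        once = resolve_hierarchy(records)
        assert resolve_hierarchy(once) == once

    @given(
        st.sets(
            st.from_regex(r"\A(250|401|008)(\.[0-9]{1,2})?\Z"),
            min_size=1, max_size=8,
        )
    )
    @settings(max_examples=200)
    def test_agrees_with_bruteforce_ancestor_filter(self, phecodes):
        records = [_rec("Z99", p) for p in phecodes]
        got = {r.phecode for r in resolve_hierarchy(records)}
        brute = {
            p for p in phecodes
            if not any(is_strict_ancestor(p, q) for q in phecodes if q != p)
        }
        assert got == brute
        # output-minimal: no retained ancestor/descendant pair
        for p, q in itertools.permutations(got, 2):
            assert not is_strict_ancestor(p, q)


class TestBuildMap:
    def test_resolves_all_worked_examples(self, map10cm, map10):
        assert map10cm.phecodes_for("H52.4") == {"367.4"}
        assert map10cm.phecodes_for("E11.9") == {"250.2"}
        assert map10cm.phecodes_for("L01.00") == {"686.2"}
        assert map10cm.phecodes_for("I10") == {"401.1"}
        assert map10cm.phecodes_for("D57.812") == {"282.5", "289.5"}
        assert map10cm.phecodes_for("I25.708") == {"411.3", "411.4"}
        assert map10.phecodes_for("B21.1") == {"071.1", "202.2"}

    def test_decoys_stay_unmapped(self, bundle, map10cm):
        decoys = {
            c for c in bundle.code_table(Vocabulary.ICD10CM)["code"]
            if c.startswith("X5") or c == "Z00.00"
        }
        assert decoys and not (decoys & map10cm.source_codes())

    def test_icd10_never_uses_gems(self, map10):
        assert all(r.path_label is not PathLabel.B_GEMS for r in map10)

    def test_empty_bundle_empty_map(self, bundle):
        empty = bundle.__class__(codes={}, edges={},
                                 phecodes=bundle.phecodes)
        assert len(build_map(empty, Vocabulary.ICD10CM)) == 0

    def test_bad_vocab_rejected(self, bundle):
        with pytest.raises(TerminologyError):
            build_map(bundle, Vocabulary.ICD9CM)

    def test_monotone_in_edges(self, bundle, map10cm):
        """Adding an edge never removes a retained-or-refined mapping."""
        edges = dict(bundle.edges)
        gems = edges[Resource.GEMS].copy()
        gems.loc[len(gems)] = ["ICD10CM", "H52.4", "ICD9CM", "401.9", 1]
        bigger = build_map(
            bundle.__class__(codes=bundle.codes,
                             edges={**edges, Resource.GEMS: gems},
                             phecodes=bundle.phecodes),
            Vocabulary.ICD10CM,
        )
        for rec in map10cm:
            kept = bigger.phecodes_for(rec.source_code)
            assert rec.phecode in kept or any(
                is_strict_ancestor(rec.phecode, q) for q in kept
            )

    def test_provenance_chains_replay(self, map10cm, map10, bundle):
        """Each hop of every provenance chain exists in its edge table."""
        for pmap in (map10cm, map10):
            for rec in pmap:
                for chain in rec.provenance:
                    assert chain[-1].target_code == rec.phecode
                    for hop in chain:
                        if hop.resource is Resource.STRING_MATCH:
                            continue  # derived, not a bundle edge
                        table = bundle.edge_table(hop.resource)
                        match = (
                            (table["source_vocab"] == hop.source_vocab.value)
                            & (table["source_code"] == hop.source_code)
                            & (table["target_vocab"] == hop.target_vocab.value)
                            & (table["target_code"] == hop.target_code)
                        )
                        assert match.any(), f"missing edge {hop}"


class TestMapIO:
    def test_roundtrip_identity(self, map10cm, tmp_path):
        path = write_map(map10cm, tmp_path / "map.csv")
        again = read_map(path)
        assert again.to_frame().equals(map10cm.to_frame())

    def test_one_row_per_source_phecode_path(self, map10cm, tmp_path):
        frame = map10cm.to_frame()
        keys = frame[["source_code", "phecode", "path_label"]]
        assert not keys.duplicated().any()

    def test_empty_map_header_only(self, tmp_path):
        path = write_map(PhecodeMap([]), tmp_path / "empty.csv")
        text = path.read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("source_vocab")

    def test_deterministic_ordering(self, bundle, tmp_path):
        a = write_map(build_map(bundle, "ICD10CM"), tmp_path / "a.csv")
        b = write_map(build_map(bundle, "ICD10CM"), tmp_path / "b.csv")
        assert a.read_bytes() == b.read_bytes()
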