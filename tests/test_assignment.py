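import random

import pytest
from hypothesis import given, strategies as st

from pollenid.assignment import (
    CALL_AMBIGUOUS,
    CALL_GENUS,
    CALL_SPECIES,
    CALL_UNIDENTIFIABLE,
    MatchHit,
    assign_taxonomy,
    flag_for_external_lookup,
    match_reference,
    reconcile_markers,
)
from pollenid.errors import ValidationError
from pollenid.refdb import ReferenceDB, ReferenceRecord

from helpers import random_dna, with_substitutions


def _hit(species, pct, marker="rbcL"):
    return MatchHit(species, species.split()[0], pct, marker)


class TestMatchReference:
    def test_exact_query_hits_100(self, small_db):
        ref = small_db.lookup("Fagus sylvatica", "rbcL")
        hits = match_reference(ref.sequence, small_db, "rbcL")
        assert hits[0].species == "Fagus sylvatica"
        assert hits[0].identity_pct == 100.0

    def test_near_and_far_references_ranked(self):
        rng = random.Random(10)
        a = random_dna(rng, 500)
        b = with_substitutions(rng, a, rng.sample(range(500), 30))
        db = ReferenceDB(
            [
                ReferenceRecord("1", "Alpha one", "rbcL", "common", "", a),
                ReferenceRecord("2", "Beta two", "rbcL", "common", "", b),
            ]
        )
        query = with_substitutions(rng, a, [3, 250])
        hits = match_reference(query, db, "rbcL")
        assert [h.species for h in hits] == ["Alpha one", "Beta two"]
        assert hits[0].identity_pct == pytest.approx(99.6)
        assert hits[1].identity_pct == pytest.approx(94.0, abs=0.4)

    def test_congeneric_pair_pattern(self, small_db):
        # reference pair 0 and 2 substitutions from the query: 100 / 99.6
        query = small_db.lookup("Acer campestre", "rbcL").sequence
        hits = match_reference(query, small_db, "rbcL")
        assert hits[0].species == "Acer campestre"
        assert hits[0].identity_pct == 100.0
        assert hits[1].species == "Acer platanoides"
        assert hits[1].identity_pct == pytest.approx(99.6)

    def test_no_records_for_marker_rejected(self):
        db = ReferenceDB(
            [ReferenceRecord("1", "Alpha one", "rbcL", "common", "", "ACGTACGT")]
        )
        with pytest.raises(ValidationError, match="trnH"):
            match_reference("ACGTACGT", db, "trnH-psbA")

    def test_prefilter_agrees_with_full_alignment(self, small_db):
        rng = random.Random(12)
        query = with_substitutions(
            rng, small_db.lookup("Acer campestre", "rbcL").sequence, [17]
        )
        fast = match_reference(query, small_db, "rbcL", prefilter=True)
        slow = match_reference(query, small_db, "rbcL", prefilter=False)
        assert [(h.species, round(h.identity_pct, 6)) for h in fast[:2]] == [
            (h.species, round(h.identity_pct, 6)) for h in slow[:2]
        ]


class TestAssignTaxonomy:
    def test_single_full_match_is_species_call(self):
        r = assign_taxonomy([_hit("Fagus sylvatica", 100.0)])
        assert (r.call_level, r.call_name) == (CALL_SPECIES, "Fagus sylvatica")

    def test_qualifying_congener_demotes_to_genus(self):
        r = assign_taxonomy(
            [_hit("Acer campestre", 100.0), _hit("Acer platanoides", 99.6)]
        )
        assert (r.call_level, r.call_name) == (CALL_GENUS, "Acer sp.")

    def test_sub_threshold_is_unidentifiable(self):
        r = assign_taxonomy([_hit("Xerolekia speciosissima", 98.5)])
        assert r.call_level == CALL_UNIDENTIFIABLE
        assert r.qualifying_hits == []

    def test_double_full_match_across_genera_is_ambiguous(self):
        r = assign_taxonomy(
            [_hit("Cyanus triumfettii", 100.0), _hit("Saussurea alpina", 100.0)]
        )
        assert r.call_level == CALL_AMBIGUOUS
        assert len(r.qualifying_hits) == 2

    def test_threshold_comparison_is_unrounded(self):
        # 621/627 = 99.043% qualifies; 620/627 = 98.88% does not
        r_in = assign_taxonomy([_hit("Alpha one", 100 * 621 / 627)])
        r_out = assign_taxonomy([_hit("Alpha one", 100 * 620 / 627)])
        assert r_in.call_level == CALL_SPECIES
        assert r_out.call_level == CALL_UNIDENTIFIABLE

    def test_top_hit_rule_keeps_species_when_congeners_trail(self):
        hits = [_hit("Acer campestre", 100.0), _hit("Acer platanoides", 99.6)]
        r = assign_taxonomy(hits, species_rule="top_hit")
        assert (r.call_level, r.call_name) == (CALL_SPECIES, "Acer campestre")

    def test_unsorted_hits_rejected(self):
        with pytest.raises(ValidationError, match="sorted"):
            assign_taxonomy([_hit("Beta two", 99.0), _hit("Alpha one", 100.0)])

    @given(
        pcts=st.lists(
            st.floats(min_value=90.0, max_value=100.0), min_size=1, max_size=6
        )
    )
    def test_threshold_monotonicity(self, pcts):
        """Raising the threshold never turns unidentifiable into identified."""
        hits = sorted(
            (_hit(f"Genus{i:02d} sp", p) for i, p in enumerate(pcts)),
            key=lambda h: (-h.identity_pct, h.species),
        )
        low = assign_taxonomy(hits, threshold_pct=97.0)
        high = assign_taxonomy(hits, threshold_pct=99.5)
        if low.call_level == CALL_UNIDENTIFIABLE:
            assert high.call_level == CALL_UNIDENTIFIABLE


class TestReconcileMarkers:
    def test_trnh_species_resolves_rbcl_congeneric_tie(self):
        r_rbcl = assign_taxonomy(
            [
                _hit("Prunella grandiflora", 100.0),
                _hit("Prunella vulgaris", 99.6),
            ]
        )
        r_trnh = assign_taxonomy(
            [_hit("Prunella grandiflora", 100.0, marker="trnH-psbA")]
        )
        final = reconcile_markers(r_rbcl, r_trnh)
        assert (final.call_level, final.call_name) == (
            CALL_SPECIES,
            "Prunella grandiflora",
        )

    def test_single_marker_detection_passes_through(self):
        r_trnh = assign_taxonomy(
            [_hit("Teucrium montanum", 100.0, marker="trnH-psbA")]
        )
        final = reconcile_markers(None, r_trnh)
        assert (final.call_level, final.call_name) == (
            CALL_SPECIES,
            "Teucrium montanum",
        )

    def test_matching_genus_calls_stay_genus(self):
        r_rbcl = assign_taxonomy(
            [_hit("Acer campestre", 100.0), _hit("Acer platanoides", 99.8)]
        )
        r_trnh = assign_taxonomy(
            [
                _hit("Acer campestre", 100.0, marker="trnH-psbA"),
                _hit("Acer platanoides", 99.6, marker="trnH-psbA"),
            ]
        )
        final = reconcile_markers(r_rbcl, r_trnh)
        assert (final.call_level, final.call_name) == (CALL_GENUS, "Acer sp.")

    def test_identical_species_calls_merge(self):
        r_rbcl = assign_taxonomy([_hit("Fagus sylvatica", 100.0)])
        r_trnh = assign_taxonomy([_hit("Fagus sylvatica", 100.0, marker="trnH-psbA")])
        final = reconcile_markers(r_rbcl, r_trnh)
        assert final.call_name == "Fagus sylvatica"
        assert not final.conflict

    def test_species_disagreement_is_flagged_not_merged(self):
        r_rbcl = assign_taxonomy([_hit("Alpha one", 100.0)])
        r_trnh = assign_taxonomy([_hit("Beta two", 100.0, marker="trnH-psbA")])
        final = reconcile_markers(r_rbcl, r_trnh)
        assert final.call_name == "Beta two"  # precedence marker wins
        assert final.conflict
        assert final.conflict_with == "Alpha one"

    def test_rbcl_precedence_config(self):
        r_rbcl = assign_taxonomy([_hit("Alpha one", 100.0)])
        r_trnh = assign_taxonomy([_hit("Beta two", 100.0, marker="trnH-psbA")])
        final = reconcile_markers(r_rbcl, r_trnh, precedence="rbcL")
        assert final.call_name == "Alpha one"

    def test_both_absent_rejected(self):
        with pytest.raises(ValidationError):
            reconcile_markers(None, None)


class TestExternalLookupFlag:
    @pytest.mark.parametrize(
        "hits,expected",
        [
            ([_hit("Alpha one", 98.0)], True),
            ([_hit("Alpha one", 100.0)], False),
            (
                [_hit("Alpha one", 100.0), _hit("Beta two", 100.0)],
                False,  # ambiguous calls are not escalated, only sub-threshold
            ),
        ],
    )
    def test_only_unidentifiable_escalates(self, hits, expected):
        assert flag_for_external_lookup(assign_taxonomy(hits)) is expected


class TestRecallOnSimulatedLibraries:
    def test_truth_species_always_among_qualifying_hits(self, study):
        """For every non-contaminant MOTU of a full simulated study, the true
        source species qualifies at the 99% threshold."""
        from pollenid.simulate import CONTAMINANT_PREFIX

        scenario, result = study
        checked = 0
        for sample in result.samples.values():
            for motu in sample.motus:
                truths = {
                    t.truth_species
                    for t in motu.members
                    if t.truth_species
                    and not t.truth_species.startswith(CONTAMINANT_PREFIX)
                }
                if not truths:
                    continue
                qualifying = {
                    h.species
                    for h in sample.assignments[motu.motu_id].qualifying_hits
                }
                assert truths <= qualifying
                checked += 1
        assert checked > 100

    def test_contaminant_motus_always_unidentifiable(self, study):
        from pollenid.simulate import CONTAMINANT_PREFIX

        scenario, result = study
        seen = 0
        for sample in result.samples.values():
            for motu in sample.motus:
                truths = {t.truth_species for t in motu.members}
                if all(
                    t and t.startswith(CONTAMINANT_PREFIX) for t in truths
                ):
                    seen += 1
                    assert (
                        sample.assignments[motu.motu_id].call_level
                        == CALL_UNIDENTIFIABLE
                    )
        assert seen > 10
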