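"""The identification loop: compatibility predicates, filtering, selection
edits, and the behavioural invariants of candidate elimination."""

import random

import pytest

from tachikey.engine import (
    Selection,
    deselect_state,
    filter_taxa,
    host_compatible,
    length_compatible,
    refresh_characters,
    refresh_hosts,
    state_compatible,
)
from tachikey.model import CodingEntry, KeyDataError, TaxonRecord

from conftest import oracle_filter, random_selection, random_small_matrix


class TestCompatibilityPredicates:
    @pytest.mark.parametrize(
        "entry,selected,expected",
        [
            (CodingEntry.coded({"a"}), {"a", "b"}, True),
            (CodingEntry.coded({"x"}), {"y"}, False),
            (CodingEntry("unknown"), {"y"}, True),
            (CodingEntry("inapplicable"), {"y"}, True),
            (CodingEntry.coded({"a", "b"}), {"b"}, True),
        ],
    )
    def test_state_compatible(self, entry, selected, expected):
        assert state_compatible(entry, selected) is expected

    @pytest.mark.parametrize(
        "length_range,L,expected",
        [((5.0, 9.0), 7, True), ((5.0, 9.0), 10, False), ((5.0, 9.0), 5, True),
         ((5.0, 9.0), 9, True), (None, 4, True)],
    )
    def test_length_compatible(self, length_range, L, expected):
        rec = TaxonRecord("T", body_length_mm=length_range)
        assert length_compatible(rec, L) is expected

    def test_length_tolerance_widens_both_ends(self):
        rec = TaxonRecord("T", body_length_mm=(5.0, 9.0))
        assert not length_compatible(rec, 10)
        assert length_compatible(rec, 10, tolerance=1.0)
        assert length_compatible(rec, 4, tolerance=1.0)

    @pytest.mark.parametrize(
        "hosts,groups,include_unknown,expected",
        [
            ({"Lepidoptera"}, {"Lepidoptera", "Coleoptera"}, True, True),
            ({"Lepidoptera"}, {"Lepidoptera", "Coleoptera"}, False, True),
            (set(), {"Coleoptera"}, True, True),
            (set(), {"Coleoptera"}, False, False),
            ({"Diptera"}, {"Coleoptera"}, True, False),
        ],
    )
    def test_host_compatible(self, hosts, groups, include_unknown, expected):
        rec = TaxonRecord("T", hosts=frozenset(hosts))
        assert host_compatible(rec, groups, include_unknown) is expected


class TestFilterTaxa:
    def test_empty_selection_keeps_everything(self, toy):
        assert filter_taxa(toy, Selection()).candidates == (0, 1, 2, 3)

    def test_single_state_selection(self, toy):
        result = filter_taxa(toy, Selection(char_states={"c1": frozenset("a")}))
        assert result.candidates == (0, 2)  # Alpha and polymorphic Gamma

    def test_two_characters_unknown_retained(self, toy):
        sel = Selection(char_states={"c1": frozenset("a"), "c2": frozenset("y")})
        result = filter_taxa(toy, sel)
        assert result.candidates == (2,)  # only Gamma: unknown at c2 survives
        assert result.resolved

    def test_strict_mode_discards_unknowns(self, toy):
        sel = Selection(char_states={"c2": frozenset("y")})
        assert filter_taxa(toy, sel).candidates == (1, 2)
        assert filter_taxa(toy, sel, strict_unknowns=True).candidates == (1,)

    def test_selection_outside_character_states_rejected(self, toy):
        with pytest.raises(KeyDataError) as err:
            filter_taxa(toy, Selection(char_states={"c1": frozenset("z")}))
        assert err.value.code == "BAD_SELECTION"

    def test_taxon_unknown_everywhere_always_survives(self, toy):
        toy.codings[(2, "c1")] = CodingEntry("unknown")
        toy.codings[(2, "c2")] = CodingEntry("unknown")
        sel = Selection(char_states={"c1": frozenset("a"), "c2": frozenset("z")})
        assert 2 in filter_taxa(toy, sel).candidates


class TestSelectionEdits:
    def _sel(self):
        return Selection(
            char_states={"c1": frozenset({"a"})},
            specimen_length_mm=6,
            subfamily="Tachininae",
            host_groups=frozenset({"Coleoptera"}),
            include_unknown_hosts=False,
        )

    def test_refresh_characters_keeps_other_filters(self):
        out = refresh_characters(self._sel())
        assert out.char_states == {}
        assert out.host_groups == frozenset({"Coleoptera"})
        assert out.subfamily == "Tachininae"
        assert out.specimen_length_mm == 6

    def test_refresh_hosts_keeps_characters(self):
        out = refresh_hosts(self._sel())
        assert out.host_groups is None
        assert out.include_unknown_hosts is True
        assert out.char_states == {"c1": frozenset({"a"})}
        assert out.subfamily == "Tachininae"

    def test_refreshes_are_idempotent_on_empty_selection(self):
        empty = Selection()
        assert refresh_characters(empty) == empty
        assert refresh_hosts(empty) == empty

    def test_deselect_narrows_then_drops_character(self):
        sel = Selection(char_states={"c1": frozenset({"a", "b"})})
        sel = deselect_state(sel, "c1", "b")
        assert sel.char_states == {"c1": frozenset({"a"})}
        sel = deselect_state(sel, "c1", "a")
        assert "c1" not in sel.char_states

    def test_deselect_unselected_state_rejected(self):
        with pytest.raises(KeyDataError) as err:
            deselect_state(Selection(), "c1", "a")
        assert err.value.code == "NOT_SELECTED"

    def test_select_all_then_deselect_two_states(self, toy):
        # narrowing by elimination: all of c2, then drop x and z
        sel = Selection(char_states={"c2": frozenset({"x", "y", "z"})})
        sel = deselect_state(sel, "c2", "x")
        sel = deselect_state(sel, "c2", "z")
        assert filter_taxa(toy, sel).candidates == (1, 2)


class TestBehaviouralInvariants:
    """Seeded-random properties of the elimination semantics."""

    def test_matches_brute_force_oracle(self):
        rng = random.Random(20120704)
        for _ in range(300):
            m = random_small_matrix(rng)
            sel = random_selection(rng, m)
            strict = rng.random() < 0.2
            got = filter_taxa(m, sel, strict_unknowns=strict).candidates
            assert list(got) == oracle_filter(m, sel, strict_unknowns=strict)

    def test_adding_constraints_never_enlarges_candidates(self):
        rng = random.Random(7)
        for _ in range(200):
            m = random_small_matrix(rng)
            sel = random_selection(rng, m)
            base = set(filter_taxa(m, sel).candidates)
            unconstrained = [c for c in m.characters if c.char_id not in sel.char_states]
            if unconstrained:
                ch = rng.choice(unconstrained)
                tightened = sel.with_states(ch.char_id, {rng.choice(ch.state_ids)})
                assert set(filter_taxa(m, tightened).candidates) <= base
            narrower = Selection(
                char_states=sel.char_states,
                specimen_length_mm=sel.specimen_length_mm or rng.randint(1, 14),
                subfamily=sel.subfamily or "S1",
                host_groups=sel.host_groups,
                include_unknown_hosts=sel.include_unknown_hosts,
            )
            assert set(filter_taxa(m, narrower).candidates) <= base

    def test_enlarging_a_state_set_never_shrinks_candidates(self):
        rng = random.Random(11)
        for _ in range(200):
            m = random_small_matrix(rng)
            sel = random_selection(rng, m)
            enlargeable = [
                cid for cid, states in sel.char_states.items()
                if states < set(m.character(cid).state_ids)
            ]
            if not enlargeable:
                continue
            cid = rng.choice(enlargeable)
            extra = rng.choice(sorted(set(m.character(cid).state_ids) - sel.char_states[cid]))
            enlarged = sel.with_states(cid, sel.char_states[cid] | {extra})
            assert set(filter_taxa(m, sel).candidates) <= set(filter_taxa(m, enlarged).candidates)

    def test_selecting_all_states_is_a_no_op(self):
        rng = random.Random(13)
        for _ in range(200):
            m = random_small_matrix(rng)
            sel = random_selection(rng, m)
            ch = rng.choice(m.characters)
            saturated = sel.with_states(ch.char_id, set(ch.state_ids))
            dropped = Selection(
                char_states={c: s for c, s in saturated.char_states.items() if c != ch.char_id},
                specimen_length_mm=sel.specimen_length_mm,
                subfamily=sel.subfamily,
                host_groups=sel.host_groups,
                include_unknown_hosts=sel.include_unknown_hosts,
            )
            assert filter_taxa(m, saturated).candidates == filter_taxa(m, dropped).candidates

    def test_result_independent_of_selection_insertion_order(self):
        rng = random.Random(17)
        for _ in range(200):
            m = random_small_matrix(rng)
            sel = random_selection(rng, m)
            items = list(sel.char_states.items())
            rng.shuffle(items)
            shuffled = Selection(
                char_states=dict(items),
                specimen_length_mm=sel.specimen_length_mm,
                subfamily=sel.subfamily,
                host_groups=sel.host_groups,
                include_unknown_hosts=sel.include_unknown_hosts,
            )
            assert filter_taxa(m, sel).candidates == filter_taxa(m, shuffled).candidates
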