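"""Deterministic candidate filtering — the identification loop.

The user selects one or more states per character (several states express
uncertainty), optionally an integer specimen length in mm, a subfamily and
a set of host groups.  A taxon survives when, for every constrained
character, its coding shares at least one selected state; unknown and
inapplicable codings are retained, so missing information never eliminates
a taxon.  Characters can be applied in any order and the result is
independent of that order; the loop is repeated until one candidate is
left.

A ``strict_unknowns`` switch makes unknown/inapplicable codings
eliminative instead, for users who want a matrix-completeness stress test
rather than an identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import CodingEntry, KeyDataError, KeyMatrix, TaxonRecord


@dataclass(frozen=True)
class Selection:
    """The user's current constraints.

    ``char_states`` maps char_id to the nonempty set of selected states;
    insertion order is remembered for display only and never affects the
    candidate set.  ``host_groups=None`` means the host filter is off
    (distinct from an empty set, which is not a legal filter).
    """

    char_states: dict[str, frozenset[str]] = field(default_factory=dict)
    specimen_length_mm: int | None = None
    subfamily: str | None = None
    host_groups: frozenset[str] | None = None
    include_unknown_hosts: bool = True

    def with_states(self, char_id: str, states) -> "Selection":
        new = dict(self.char_states)
        new[char_id] = frozenset(states)
        return replace(self, char_states=new)


@dataclass(frozen=True)
class IdentificationResult:
    candidates: tuple[int, ...]  # taxon indices, matrix order
    selection: Selection

    @property
    def resolved(self) -> bool:
        return len(self.candidates) == 1


def state_compatible(entry: CodingEntry, selected: frozenset[str] | set[str]) -> bool:
    """True iff the coding survives a selection on its character.

    Unknown and inapplicable codings always survive; a coded entry
    survives iff it shares at least one state with the selection.
    """
    if entry.kind != "coded":
        return True
    return bool(entry.states & frozenset(selected))


def length_compatible(record: TaxonRecord, length_mm: int, tolerance: float = 0.0) -> bool:
    """True iff the specimen length falls in the taxon's body-length range.

    Taxa with no recorded range are retained.  ``tolerance`` (mm) widens
    the interval at both ends for borderline measurements.
    """
    if record.body_length_mm is None:
        return True
    lo, hi = record.body_length_mm
    return lo - tolerance <= length_mm <= hi + tolerance


def host_compatible(record: TaxonRecord, host_groups, include_unknown: bool = True) -> bool:
    """True iff the taxon parasitizes one of the given host groups.

    A taxon with no recorded hosts (``hosts == ∅``) is retained only when
    ``include_unknown`` is set, mirroring the key's opt-in inclusion of
    genera whose host relationships are still unknown.
    """
    if not record.hosts:
        return include_unknown
    return bool(record.hosts & frozenset(host_groups))


def _check_selection(matrix: KeyMatrix, selection: Selection) -> None:
    for cid, states in selection.char_states.items():
        ch = matrix.character(cid)  # raises BAD_CHARACTER for foreign ids
        if not states:
            raise KeyDataError("BAD_SELECTION", f"empty state set for {cid!r}")
        bad = frozenset(states) - set(ch.state_ids)
        if bad:
            raise KeyDataError("BAD_SELECTION", f"states {sorted(bad)} are not states of {cid!r}")


def filter_taxa(
    matrix: KeyMatrix,
    selection: Selection,
    *,
    length_tolerance: float = 0.0,
    strict_unknowns: bool = False,
) -> IdentificationResult:
    """Apply every active constraint and return surviving taxa in matrix order."""
    _check_selection(matrix, selection)
    candidates = []
    for t, rec in enumerate(matrix.taxa):
        ok = True
        for cid, states in selection.char_states.items():
            entry = matrix.coding(t, cid)
            if strict_unknowns and entry.kind != "coded":
                ok = False
            elif not state_compatible(entry, states):
                ok = False
            if not ok:
                break
        if ok and selection.specimen_length_mm is not None:
            ok = length_compatible(rec, selection.specimen_length_mm, length_tolerance)
        if ok and selection.subfamily is not None:
            ok = rec.subfamily == selection.subfamily
        if ok and selection.host_groups is not None:
            if not selection.host_groups:
                raise KeyDataError("BAD_SELECTION", "host filter set but empty")
            ok = host_compatible(rec, selection.host_groups, selection.include_unknown_hosts)
        if ok:
            candidates.append(t)
    return IdentificationResult(candidates=tuple(candidates), selection=selection)


def refresh_characters(selection: Selection) -> Selection:
    """Clear all character checkboxes; length, subfamily and hosts stay."""
    return replace(selection, char_states={})


def refresh_hosts(selection: Selection) -> Selection:
    """Clear the host filter; characters, length and subfamily stay."""
    return replace(selection, host_groups=None, include_unknown_hosts=True)


def deselect_state(selection: Selection, char_id: str, state_id: str) -> Selection:
    """Remove one selected state; drop the character when none remain.

    This supports the narrowing-by-elimination style of use: select all
    states of a character, then deselect them one at a time.
    """
    current = selection.char_states.get(char_id, frozenset())
    if state_id not in current:
        raise KeyDataError("NOT_SELECTED", f"state {state_id!r} not selected for {char_id!r}")
    remaining = current - {state_id}
    new = dict(selection.char_states)
    if remaining:
        new[char_id] = remaining
    else:
        del new[char_id]
    return replace(selection, char_states=new)
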