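"""Domain model for a characters × taxa identification-key matrix.

A multi-access (polyclave) key is stored as a dense matrix: rows are
terminal taxa (genera, subgenera treated separately, or partitions of a
genus), columns are multi-state morphological characters, and each cell
codes the states observed across the taxon's species.  Polymorphism is
first-class: a cell may carry several states of one character.  Cells may
also be *unknown* (no information recorded) or *inapplicable* (the
structure does not exist on that taxon); both are non-eliminative during
identification.

Everything here is a plain in-memory value object; serialization lives in
:mod:`tachikey.io` and filtering in :mod:`tachikey.engine`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: The eight body-section headings of the character list, in window order.
SECTIONS = (
    "HEAD",
    "ANTENNAE",
    "MOUTHPARTS",
    "THORAX",
    "WING",
    "LEGS",
    "ABDOMEN",
    "COLOUR",
)

#: Permitted numbers of states per character.
MIN_STATES = 2
MAX_STATES = 9

#: Terminal-taxon ranks.  ``genus-partim`` marks a partition of a genus
#: (a "sensu stricto" or "except subgenus ..." terminal); ``species-group``
#: marks a species-group treated as its own terminal.
RANKS = ("genus", "subgenus", "species-group", "genus-partim")

CODING_KINDS = ("coded", "unknown", "inapplicable")


class KeyDataError(Exception):
    """Error with a stable machine-readable ``code`` attribute."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


_SLUG_RE = re.compile(r"[^a-z0-9]+")


def slugify(name: str, taken: set[str] | None = None) -> str:
    """Derive a stable slug identifier from a printed name.

    Lowercase, parentheses stripped, non-alphanumeric runs hyphenated.
    If *taken* is given, a deterministic ``-2``, ``-3`` ... suffix
    disambiguates collisions (and the result is added to *taken*).
    """
    base = name.lower().replace("(", "").replace(")", "")
    slug = _SLUG_RE.sub("-", base).strip("-") or "x"
    if taken is not None:
        candidate, n = slug, 1
        while candidate in taken:
            n += 1
            candidate = f"{slug}-{n}"
        taken.add(candidate)
        slug = candidate
    return slug


@dataclass(frozen=True)
class StateDef:
    """One discrete alternative of a character."""

    state_id: str
    label: str
    ordinal: int  # 1-based position within the character


@dataclass(frozen=True)
class CharacterDef:
    """A multi-state morphological character.

    ``highlighted`` is the editorial "green" flag for characters deemed
    easy to observe and strongly selective; a computed counterpart lives
    in :mod:`tachikey.analytics`.
    """

    char_id: str
    name: str
    section: str
    states: tuple[StateDef, ...] = ()
    highlighted: bool = False
    ordinal: int = 0  # 1-based position in the character window

    @property
    def state_ids(self) -> tuple[str, ...]:
        return tuple(s.state_id for s in self.states)

    def state(self, state_id: str) -> StateDef:
        for s in self.states:
            if s.state_id == state_id:
                return s
        raise KeyError(state_id)


@dataclass(frozen=True)
class TaxonRecord:
    """A terminal taxon of the key with its display metadata.

    ``hosts`` holds host-group labels of the insects the taxon
    parasitizes; an empty set means the host relationships are unknown.
    ``body_length_mm`` is a closed interval in millimetres.
    """

    terminal_name: str
    rank: str = "genus"
    parent_genus: str | None = None
    author: str | None = None
    year: int | None = None
    page: str | None = None
    subfamily: str | None = None
    hosts: frozenset[str] = frozenset()
    body_length_mm: tuple[float, float] | None = None
    distribution: str = ""
    remarks: str = ""
    image_refs: tuple[str, ...] = ()

    @property
    def genus(self) -> str:
        """The genus this terminal collapses to."""
        return self.parent_genus or self.terminal_name

    def display_name(self) -> str:
        """``"Name Author, Year"`` as shown in candidate listings."""
        if self.author and self.year:
            return f"{self.terminal_name} {self.author}, {self.year}"
        return self.terminal_name


_UNKNOWN_SENTINEL = object()


@dataclass(frozen=True)
class CodingEntry:
    """One matrix cell: the states recorded for (taxon, character)."""

    kind: str = "unknown"
    states: frozenset[str] = frozenset()

    @classmethod
    def coded(cls, states: Iterable[str]) -> "CodingEntry":
        return cls("coded", frozenset(states))


UNKNOWN = CodingEntry("unknown")
INAPPLICABLE = CodingEntry("inapplicable")


@dataclass(frozen=True)
class MatrixMeta:
    """Versioning metadata carried into the identification-code export."""

    app_version: str = "0"
    data_version: str = "0"
    last_modified: str = "1970-01-01"  # ISO-8601 date
    language: str = "English"


@dataclass
class KeyMatrix:
    """The whole key: characters, taxa, codings and version metadata.

    ``codings`` maps ``(taxon_index, char_id)`` to a :class:`CodingEntry`;
    pairs with no entry are implicitly unknown.
    """

    characters: list[CharacterDef] = field(default_factory=list)
    taxa: list[TaxonRecord] = field(default_factory=list)
    codings: dict[tuple[int, str], CodingEntry] = field(default_factory=dict)
    meta: MatrixMeta = field(default_factory=MatrixMeta)

    def coding(self, taxon_index: int, char_id: str) -> CodingEntry:
        return self.codings.get((taxon_index, char_id), UNKNOWN)

    def character(self, char_id: str) -> CharacterDef:
        for c in self.characters:
            if c.char_id == char_id:
                return c
        raise KeyDataError("BAD_CHARACTER", f"no character {char_id!r}")

    @property
    def char_ids(self) -> tuple[str, ...]:
        return tuple(c.char_id for c in self.characters)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_matrix`."""

    code: str
    location: str
    message: str


def _plausible_year(year: int | None) -> bool:
    return year is None or (isinstance(year, int) and 1000 <= year <= 9999)


def validate_matrix(matrix: KeyMatrix) -> list[Violation]:
    """Check every structural invariant; return violations, not exceptions.

    The report is deterministic: matrix-level and character-level findings
    first (in window order), then per-taxon findings ordered by
    (taxon ordinal, character ordinal).
    """
    out: list[Violation] = []

    seen_chars: set[str] = set()
    for i, ch in enumerate(matrix.characters):
        loc = f"character[{i}]:{ch.char_id}"
        if ch.char_id in seen_chars:
            out.append(Violation("DUP_CHAR_ID", loc, f"duplicate char_id {ch.char_id!r}"))
        seen_chars.add(ch.char_id)
        if ch.section not in SECTIONS:
            out.append(Violation("BAD_SECTION", loc, f"section {ch.section!r} not in {SECTIONS}"))
        if ch.ordinal != i + 1:
            out.append(Violation("BAD_ORDINAL", loc, f"ordinal {ch.ordinal} != {i + 1}"))
        k = len(ch.states)
        if not (MIN_STATES <= k <= MAX_STATES):
            out.append(
                Violation(
                    "STATE_COUNT",
                    loc,
                    f"{k} states; characters carry from {MIN_STATES} to {MAX_STATES} states",
                )
            )
        seen_states: set[str] = set()
        for j, s in enumerate(ch.states):
            if s.state_id in seen_states:
                out.append(Violation("DUP_STATE_ID", loc, f"duplicate state_id {s.state_id!r}"))
            seen_states.add(s.state_id)
            if s.ordinal != j + 1:
                out.append(Violation("BAD_STATE_ORDINAL", loc, f"state {s.state_id!r} ordinal {s.ordinal} != {j + 1}"))

    seen_taxa: set[str] = set()
    char_index = {c.char_id: c for c in matrix.characters}
    for t, rec in enumerate(matrix.taxa):
        loc = f"taxon[{t}]:{rec.terminal_name}"
        if rec.terminal_name in seen_taxa:
            out.append(Violation("DUP_TAXON", loc, f"duplicate terminal {rec.terminal_name!r}"))
        seen_taxa.add(rec.terminal_name)
        if rec.rank not in RANKS:
            out.append(Violation("BAD_RANK", loc, f"rank {rec.rank!r} not in {RANKS}"))
        if not _plausible_year(rec.year):
            out.append(Violation("BAD_YEAR", loc, f"implausible year {rec.year!r}"))
        if rec.body_length_mm is not None:
            lo, hi = rec.body_length_mm
            if not (0 < lo <= hi):
                out.append(Violation("BAD_LENGTH", loc, f"length range {rec.body_length_mm!r}"))
        if rec.rank != "genus" and rec.parent_genus is None:
            out.append(Violation("NO_PARENT", loc, f"rank {rec.rank!r} requires parent_genus"))

        for c_ord, ch in enumerate(matrix.characters):
            entry = matrix.coding(t, ch.char_id)
            cloc = f"coding[{t},{ch.char_id}]"
            if entry.kind not in CODING_KINDS:
                out.append(Violation("BAD_KIND", cloc, f"kind {entry.kind!r}"))
                continue
            if entry.kind == "coded":
                if not entry.states:
                    out.append(Violation("EMPTY_CODED", cloc, "coded entry with no states"))
                bad = entry.states - set(ch.state_ids)
                if bad:
                    out.append(
                        Violation("BAD_STATE_REF", cloc, f"states {sorted(bad)} not states of {ch.char_id!r}")
                    )
            elif entry.states:
                out.append(Violation("NONEMPTY_UNCODED", cloc, f"{entry.kind} entry carries states"))

    for (t, cid) in matrix.codings:
        if not (0 <= t < len(matrix.taxa)) or cid not in char_index:
            out.append(Violation("BAD_CODING_KEY", f"coding[{t},{cid}]", "key outside matrix"))

    return out


#: Metadata fields every encoded description must carry, mirroring what the
#: per-taxon information window displays.
MANDATORY_FIELDS = (
    "terminal_name",
    "rank",
    "author",
    "year",
    "subfamily",
    "distribution",
    "body_length_mm",
)


@dataclass(frozen=True)
class DescriptionReport:
    complete: bool
    missing: tuple[str, ...]


def validate_description_form(
    record: TaxonRecord,
    codings_for_record: Mapping[str, CodingEntry],
    characters: list[CharacterDef],
) -> DescriptionReport:
    """Check a taxon description against the full description protocol.

    A description is complete when every mandatory metadata field is
    present and *every* character of the key has an explicit coding entry
    — coded, unknown or inapplicable.  An explicit "unknown" is allowed;
    a silently absent character is not: the protocol's point is that the
    describer states what was not observed.

    Raises :class:`KeyDataError` ``FOREIGN_CHARACTER`` if the codings
    reference a character that is not part of the key.
    """
    known = {c.char_id for c in characters}
    foreign = set(codings_for_record) - known
    if foreign:
        raise KeyDataError("FOREIGN_CHARACTER", f"unknown characters {sorted(foreign)}")

    missing: list[str] = []
    for name in MANDATORY_FIELDS:
        value = getattr(record, name)
        if value is None or value == "":
            missing.append(name)
    for c in characters:
        if c.char_id not in codings_for_record:
            missing.append(c.char_id)
    return DescriptionReport(complete=not missing, missing=tuple(missing))
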