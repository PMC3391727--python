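"""Character-selectivity scoring and matrix summary statistics.

A good next character is one whose single-state selections split the
current candidates nearly evenly — choosing any one of its states then
discards a large, predictable fraction of taxa ("nearly linear
reduction").  We quantify this with a normalized-entropy score:

    score(c) = coded_fraction(c) × H(p) / log k

where ``k`` is the number of states of character *c*, ``r_s`` is the
number of current candidates a single-state selection of *s* would
retain (unknown-coded taxa survive every such what-if, so they count
toward every state), ``p_s = r_s / Σ r_s``, and ``coded_fraction`` is the
share of current candidates actually coded for *c*.  The score lives in
[0, 1]: 1 means every candidate is coded and the states split them into
equal parts; 0 means the character cannot discriminate at all (every
candidate in one state, or nothing coded).  The coded-fraction factor
down-weights characters that look balanced only because most codings are
missing.

The score is this package's computable counterpart of the editorial
"green" highlight stored on :class:`~tachikey.model.CharacterDef`; the
two are kept separate because ease of observation is an editorial
judgement the data cannot supply.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from typing import Iterable, Sequence

from .engine import state_compatible
from .model import KeyDataError, KeyMatrix


def retention_counts(matrix: KeyMatrix, candidates: Sequence[int], char_id: str) -> dict[str, int]:
    """For each state, how many candidates a single-state selection keeps.

    Each count is an actual what-if filter outcome, so polymorphic taxa
    count toward each of their states and unknown/inapplicable taxa count
    toward every state.
    """
    ch = matrix.character(char_id)  # raises BAD_CHARACTER
    counts = {sid: 0 for sid in ch.state_ids}
    for t in candidates:
        entry = matrix.coding(t, char_id)
        for sid in ch.state_ids:
            if state_compatible(entry, frozenset((sid,))):
                counts[sid] += 1
    return counts


def coded_fraction(matrix: KeyMatrix, candidates: Sequence[int], char_id: str) -> float:
    if not candidates:
        return 0.0
    coded = sum(1 for t in candidates if matrix.coding(t, char_id).kind == "coded")
    return coded / len(candidates)


def selectivity_score(matrix: KeyMatrix, candidates: Sequence[int], char_id: str) -> float:
    """Normalized-entropy selectivity of one character (see module docs)."""
    if len(candidates) < 2:
        raise KeyDataError("NOTHING_TO_SPLIT", f"{len(candidates)} candidate(s); need at least 2")
    counts = retention_counts(matrix, candidates, char_id)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    entropy = 0.0
    for r in counts.values():
        if r:
            p = r / total
            entropy -= p * math.log(p)
    k = len(counts)
    return coded_fraction(matrix, candidates, char_id) * entropy / math.log(k)


@dataclass(frozen=True)
class CharacterSelectivity:
    char_id: str
    retention_counts: dict[str, int]
    coded_fraction: float
    score: float
    rank: int  # 1-based, best first


@dataclass(frozen=True)
class SelectivityReport:
    entries: tuple[CharacterSelectivity, ...]  # in rank order
    green_threshold: float

    @property
    def highlighted(self) -> tuple[str, ...]:
        return tuple(e.char_id for e in self.entries if e.score >= self.green_threshold)


def rank_characters(
    matrix: KeyMatrix,
    candidates: Sequence[int],
    green_threshold: float = 0.8,
    exclude: Iterable[str] = (),
) -> SelectivityReport:
    """Rank unselected characters by selectivity, best first.

    Ties are broken by character-window ordinal, so the report is
    deterministic.  ``exclude`` removes characters the user has already
    selected — re-ranking them would be vacuous.
    """
    if len(candidates) < 2:
        raise KeyDataError("NOTHING_TO_SPLIT", f"{len(candidates)} candidate(s); need at least 2")
    excluded = set(exclude)
    scored = []
    for ch in matrix.characters:
        if ch.char_id in excluded:
            continue
        scored.append(
            (
                -selectivity_score(matrix, candidates, ch.char_id),
                ch.ordinal,
                ch.char_id,
            )
        )
    scored.sort()
    entries = tuple(
        CharacterSelectivity(
            char_id=cid,
            retention_counts=retention_counts(matrix, candidates, cid),
            coded_fraction=coded_fraction(matrix, candidates, cid),
            score=-neg,
            rank=i + 1,
        )
        for i, (neg, _ord, cid) in enumerate(scored)
    )
    return SelectivityReport(entries=entries, green_threshold=green_threshold)


@dataclass(frozen=True)
class MatrixSummary:
    n_taxa: int
    n_characters: int
    n_states_total: int
    state_count_min: int
    state_count_max: int
    section_counts: dict[str, int]
    n_genera: int
    n_subgenus_terminals: int
    subfamily_histogram: dict[str, int]


def summarize(matrix: KeyMatrix) -> MatrixSummary:
    """Exact structural census of a key matrix.

    Also works on fixture skeletons whose characters carry no state
    inventories (their state counts are simply zero).
    """
    state_counts = [len(c.states) for c in matrix.characters]
    sections = Counter(c.section for c in matrix.characters)
    subfamilies = Counter(t.subfamily for t in matrix.taxa if t.subfamily)
    return MatrixSummary(
        n_taxa=len(matrix.taxa),
        n_characters=len(matrix.characters),
        n_states_total=sum(state_counts),
        state_count_min=min(state_counts, default=0),
        state_count_max=max(state_counts, default=0),
        section_counts=dict(sections),
        n_genera=len({t.genus for t in matrix.taxa}),
        n_subgenus_terminals=sum(1 for t in matrix.taxa if t.rank == "subgenus"),
        subfamily_histogram=dict(subfamilies),
    )
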