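"""Shared fixtures: the toy matrix, a tiny random-matrix generator and an
independent brute-force filtering oracle.

The oracle re-states the retention predicate from scratch with raw set
operations so that engine tests compare two independently written
implementations, not one implementation with itself.
"""

from __future__ import annotations

import random

import pytest

from tachikey.engine import Selection
from tachikey.model import (
    CharacterDef,
    CodingEntry,
    KeyMatrix,
    MatrixMeta,
    StateDef,
    TaxonRecord,
)
from tachikey.synthetic import make_toy_matrix


@pytest.fixture
def toy():
    return make_toy_matrix()


def random_small_matrix(rng: random.Random, max_taxa: int = 12, max_chars: int = 5) -> KeyMatrix:
    """A small random but always-valid matrix, independent of the package's
    own synthetic generator."""
    n_chars = rng.randint(1, max_chars)
    n_taxa = rng.randint(1, max_taxa)
    characters = []
    for i in range(n_chars):
        k = rng.randint(2, 4)
        characters.append(
            CharacterDef(
                char_id=f"q{i}",
                name=f"character {i}",
                section="HEAD",
                states=tuple(StateDef(f"s{j}", f"state {j}", j + 1) for j in range(k)),
                ordinal=i + 1,
            )
        )
    taxa = []
    for t in range(n_taxa):
        length = None
        if rng.random() < 0.7:
            lo = rng.randint(1, 10)
            length = (float(lo), float(lo + rng.randint(0, 5)))
        hosts = frozenset(h for h in ("A", "B", "C") if rng.random() < 0.3)
        taxa.append(
            TaxonRecord(
                terminal_name=f"t{t}",
                subfamily=rng.choice(("S1", "S2", None)),
                hosts=hosts,
                body_length_mm=length,
            )
        )
    codings = {}
    for t in range(n_taxa):
        for ch in characters:
            u = rng.random()
            if u < 0.1:
                codings[(t, ch.char_id)] = CodingEntry("unknown")
            elif u < 0.15:
                codings[(t, ch.char_id)] = CodingEntry("inapplicable")
            else:
                size = rng.randint(1, len(ch.states))
                codings[(t, ch.char_id)] = CodingEntry.coded(rng.sample(ch.state_ids, size))
    return KeyMatrix(characters=characters, taxa=taxa, codings=codings, meta=MatrixMeta())


def random_selection(rng: random.Random, matrix: KeyMatrix) -> Selection:
    """A random valid selection over the matrix, possibly with filters."""
    char_states = {}
    for ch in matrix.characters:
        if rng.random() < 0.5:
            size = rng.randint(1, len(ch.states))
            char_states[ch.char_id] = frozenset(rng.sample(ch.state_ids, size))
    length = rng.randint(1, 14) if rng.random() < 0.3 else None
    subfamily = rng.choice(("S1", "S2")) if rng.random() < 0.2 else None
    hosts = None
    include_unknown = True
    if rng.random() < 0.3:
        hosts = frozenset(rng.sample(("A", "B", "C"), rng.randint(1, 3)))
        include_unknown = rng.random() < 0.5
    return Selection(
        char_states=char_states,
        specimen_length_mm=length,
        subfamily=subfamily,
        host_groups=hosts,
        include_unknown_hosts=include_unknown,
    )


def oracle_filter(matrix: KeyMatrix, selection: Selection, strict_unknowns: bool = False) -> list[int]:
    """Exhaustive per-taxon evaluation of the retention predicate."""
    survivors = []
    for t, rec in enumerate(matrix.taxa):
        keep = True
        for cid, wanted in selection.char_states.items():
            entry = matrix.codings.get((t, cid), CodingEntry("unknown"))
            if entry.kind == "coded":
                if len(entry.states.intersection(wanted)) == 0:
                    keep = False
            else:  # unknown or inapplicable
                if strict_unknowns:
                    keep = False
        if selection.specimen_length_mm is not None and rec.body_length_mm is not None:
            lo, hi = rec.body_length_mm
            if not (lo <= selection.specimen_length_mm <= hi):
                keep = False
        if selection.subfamily is not None and rec.subfamily != selection.subfamily:
            keep = False
        if selection.host_groups is not None:
            if len(rec.hosts) == 0:
                if not selection.include_unknown_hosts:
                    keep = False
            elif len(rec.hosts.intersection(selection.host_groups)) == 0:
                keep = False
        if keep:
            survivors.append(t)
    return survivors
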