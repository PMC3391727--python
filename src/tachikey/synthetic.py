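"""Seeded generator of structurally realistic key matrices.

The authors of a real multi-access key rarely publish their coded matrix,
so every operation in this package is exercised against generated
matrices that reproduce the published *shape* of the real one: 98
characters carrying 2–9 states each (374 states in total), 423 terminal
taxa across 4 subfamilies, polymorphic and unknown codings, per-taxon
body-length ranges and host-group sets.  The generator makes no attempt
to mimic correlations between real morphological characters — only the
marginal structure — so it is a test substrate, not a surrogate fauna.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; equal seeds give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    INAPPLICABLE,
    UNKNOWN,
    CharacterDef,
    CodingEntry,
    KeyDataError,
    KeyMatrix,
    MatrixMeta,
    SECTIONS,
    StateDef,
    TaxonRecord,
)

#: Default subfamily vocabulary: the four subfamilies of Tachinidae.
SUBFAMILIES = ("Dexiinae", "Exoristinae", "Phasiinae", "Tachininae")

#: Default host-group vocabulary (insect orders parasitized by tachinids).
HOST_POOL = ("Lepidoptera", "Coleoptera", "Heteroptera", "Hymenoptera", "Diptera", "other")

#: How the real character list distributes over body sections; used to give
#: synthetic characters a realistic sectioning.
_SECTION_WEIGHTS = {
    "HEAD": 26,
    "ANTENNAE": 8,
    "MOUTHPARTS": 4,
    "THORAX": 22,
    "WING": 18,
    "LEGS": 8,
    "ABDOMEN": 11,
    "COLOUR": 1,
}

_SYLLABLES = (
    "ta", "chi", "na", "my", "ia", "pha", "go", "ra", "ce", "lia",
    "dro", "me", "xo", "ris", "pe", "le", "si", "vo", "ri", "the",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; defaults reproduce the published shape."""

    n_taxa: int = 423
    n_chars: int = 98
    total_states: int = 374
    state_bounds: tuple[int, int] = (2, 9)
    p_polymorphic: float = 0.15  # P(a coded entry carries >= 2 states)
    p_unknown: float = 0.05
    p_inapplicable: float = 0.01
    n_subfamilies: int = 4
    host_pool: tuple[str, ...] = HOST_POOL
    p_host_group: float = 0.25  # per-label inclusion probability
    length_min_mm: tuple[float, float] = (2.0, 12.0)  # min ~ Uniform
    length_span_mm: tuple[float, float] = (1.0, 8.0)  # span ~ Uniform
    seed: int = 1

    def __post_init__(self):
        lo, hi = self.state_bounds
        if not (self.n_chars * lo <= self.total_states <= self.n_chars * hi):
            raise KeyDataError(
                "INFEASIBLE",
                f"{self.total_states} states cannot be spread over {self.n_chars} "
                f"characters of {lo}..{hi} states",
            )
        for p in (self.p_polymorphic, self.p_unknown, self.p_inapplicable):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.p_unknown + self.p_inapplicable > 1.0:
            raise ValueError("p_unknown + p_inapplicable exceeds 1")


def allocate_state_counts(
    n_chars: int,
    total_states: int,
    bounds: tuple[int, int] = (2, 9),
    seed: int = 0,
) -> list[int]:
    """Randomly spread a total state budget over characters within bounds.

    Every character starts at the lower bound; the remaining budget is
    handed out one state at a time to a character drawn uniformly among
    those still below the upper bound.  Deterministic for a given seed;
    raises ``INFEASIBLE`` when the budget cannot fit the bounds.
    """
    lo, hi = bounds
    if not (n_chars * lo <= total_states <= n_chars * hi):
        raise KeyDataError(
            "INFEASIBLE", f"{total_states} states over {n_chars} characters of {lo}..{hi}"
        )
    rng = np.random.default_rng(seed)
    counts = np.full(n_chars, lo, dtype=int)
    for _ in range(total_states - lo * n_chars):
        eligible = np.flatnonzero(counts < hi)
        counts[int(rng.choice(eligible))] += 1
    return counts.tolist()


def _section_allocation(n_chars: int) -> list[str]:
    """Assign sections in window order, proportional to the real list."""
    total = sum(_SECTION_WEIGHTS.values())
    quotas = {s: _SECTION_WEIGHTS[s] * n_chars / total for s in SECTIONS}
    counts = {s: int(quotas[s]) for s in SECTIONS}
    # largest-remainder rounding
    leftovers = sorted(SECTIONS, key=lambda s: quotas[s] - counts[s], reverse=True)
    i = 0
    while sum(counts.values()) < n_chars:
        counts[leftovers[i % len(leftovers)]] += 1
        i += 1
    out = []
    for s in SECTIONS:
        out.extend([s] * counts[s])
    return out[:n_chars]


def _taxon_name(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        k = int(rng.integers(3, 6))
        name = "".join(_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), k)).capitalize()
        if name not in taken:
            taken.add(name)
            return name


_AUTHORS = (
    "Alvarez", "Bergmann", "Costa", "Dubois", "Egorov", "Fontaine",
    "Gruber", "Hansen", "Ivanova", "Keller", "Larsson", "Moreau",
)


def generate_matrix(spec: SyntheticSpec | None = None) -> KeyMatrix:
    """Generate a complete, valid key matrix from a :class:`SyntheticSpec`."""
    spec = spec or SyntheticSpec()
    state_counts = allocate_state_counts(
        spec.n_chars, spec.total_states, spec.state_bounds, seed=spec.seed
    )
    rng = np.random.default_rng(spec.seed)
    sections = _section_allocation(spec.n_chars)

    characters = []
    for i, (k, section) in enumerate(zip(state_counts, sections)):
        cid = f"c{i + 1:03d}"
        characters.append(
            CharacterDef(
                char_id=cid,
                name=f"synthetic character {i + 1}",
                section=section,
                states=tuple(StateDef(f"s{j + 1}", f"state {j + 1}", j + 1) for j in range(k)),
                ordinal=i + 1,
            )
        )

    subfamilies = SUBFAMILIES[: spec.n_subfamilies]
    taken: set[str] = set()
    taxa = []
    for t in range(spec.n_taxa):
        lo = float(rng.uniform(*spec.length_min_mm))
        span = float(rng.uniform(*spec.length_span_mm))
        hosts = frozenset(h for h in spec.host_pool if rng.random() < spec.p_host_group)
        taxa.append(
            TaxonRecord(
                terminal_name=_taxon_name(rng, taken),
                rank="genus",
                author=str(rng.choice(_AUTHORS)),
                year=int(rng.integers(1758, 2013)),
                subfamily=str(rng.choice(subfamilies)),
                hosts=hosts,
                body_length_mm=(round(lo, 1), round(lo + span, 1)),
                distribution="synthetic",
            )
        )

    p_coded = 1.0 - spec.p_unknown - spec.p_inapplicable
    codings: dict[tuple[int, str], CodingEntry] = {}
    for t in range(spec.n_taxa):
        for ch in characters:
            u = rng.random()
            if u < spec.p_unknown:
                codings[(t, ch.char_id)] = UNKNOWN
            elif u < spec.p_unknown + spec.p_inapplicable:
                codings[(t, ch.char_id)] = INAPPLICABLE
            else:
                k = len(ch.states)
                if rng.random() < spec.p_polymorphic:
                    size = int(rng.integers(2, k + 1)) if k > 2 else 2
                else:
                    size = 1
                chosen = rng.choice(k, size=size, replace=False)
                codings[(t, ch.char_id)] = CodingEntry.coded(
                    ch.states[int(j)].state_id for j in chosen
                )

    return KeyMatrix(
        characters=characters,
        taxa=taxa,
        codings=codings,
        meta=MatrixMeta(
            app_version="tachikey-synthetic",
            data_version=f"seed-{spec.seed}",
            last_modified="2012-04-30",
        ),
    )


def make_toy_matrix() -> KeyMatrix:
    """The small worked example used throughout the documentation and tests.

    Two characters (C1: states a/b; C2: states x/y/z) and four taxa:
    Alpha a|x, Beta b|xy (polymorphic), Gamma ab|? (unknown at C2),
    Delta b|z.
    """
    c1 = CharacterDef(
        "c1",
        "eye pubescence",
        "HEAD",
        states=(StateDef("a", "bare", 1), StateDef("b", "hairy", 2)),
        ordinal=1,
    )
    c2 = CharacterDef(
        "c2",
        "costal spine",
        "WING",
        states=(StateDef("x", "absent", 1), StateDef("y", "short", 2), StateDef("z", "long", 3)),
        ordinal=2,
    )
    taxa = [
        TaxonRecord("Alpha", author="Smith", year=1900, subfamily="Tachininae",
                    hosts=frozenset({"Lepidoptera"}), body_length_mm=(5.0, 9.0)),
        TaxonRecord("Beta", author="Jones", year=1910, subfamily="Exoristinae",
                    body_length_mm=(3.0, 6.0)),
        TaxonRecord("Gamma", author="Brown", year=1920, subfamily="Tachininae",
                    hosts=frozenset({"Coleoptera"})),
        TaxonRecord("Delta", author="Weiss", year=1930, subfamily="Phasiinae",
                    body_length_mm=(7.0, 12.0)),
    ]
    codings = {
        (0, "c1"): CodingEntry.coded({"a"}),
        (0, "c2"): CodingEntry.coded({"x"}),
        (1, "c1"): CodingEntry.coded({"b"}),
        (1, "c2"): CodingEntry.coded({"x", "y"}),
        (2, "c1"): CodingEntry.coded({"a", "b"}),
        (2, "c2"): UNKNOWN,
        (3, "c1"): CodingEntry.coded({"b"}),
        (3, "c2"): CodingEntry.coded({"z"}),
    }
    return KeyMatrix(
        characters=[c1, c2],
        taxa=taxa,
        codings=codings,
        meta=MatrixMeta(app_version="0.1.0", data_version="toy-1.0", last_modified="2012-04-30"),
    )
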