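# Methods

## The identification model

A multi-access key is a total function from matrix cells to coding
entries. We keep three coding kinds: `coded` (a non-empty state set),
`unknown` (nothing recorded) and `inapplicable` (the structure does not
exist on that taxon). The published account of such keys does not
distinguish the latter two; we store both because they mean different
things to a describer, but the engine treats them identically.

**Retention rule.** A taxon survives a selection iff, for every
constrained character, its coding is non-coded or intersects the
selected state set, and it passes the length, subfamily and host
filters. The deliberate design choice here is that *missing data is not
eliminative*: the whole point of a highly redundant matrix is that an
incomplete specimen (or an incompletely coded taxon) can still be keyed
out. Discarding unknowns would turn every coding gap into a silent
misidentification. A `strict_unknowns` switch makes non-coded entries
eliminative for users who want to probe matrix completeness; it is off
by default and clearly not an identification mode.

Consequences the test suite enforces as properties:

- anti-monotone in constraints — adding a character constraint,
  tightening length, or narrowing subfamily/hosts never enlarges the
  candidate set;
- monotone in uncertainty — enlarging a selected state set never
  shrinks it;
- selecting *all* states of a character is a no-op;
- the result is independent of the order constraints were entered;
- a taxon unknown at every selected character always survives.

These are checked against an independently written brute-force oracle
on randomly generated matrices of at most 12 taxa × 5 characters (1,000
matrix/selection cases in the end-to-end suite, several hundred more in
the unit suite) — sizes at which exhaustive evaluation is obviously
correct by inspection.

**Filters.** Specimen length is an integer in mm compared against a
closed real interval per taxon; the default tolerance is 0 mm and a
non-negative tolerance widens both ends (for approximate measurements).
Taxa without a recorded range always pass. The host filter retains taxa
whose host set intersects the chosen groups; taxa with *no* recorded
hosts are retained by default (`include_unknown_hosts=True`), mirroring
the opt-in inclusion of genera whose biology is unknown; an empty host
set is "filter off", never "match nothing". Interval-coded morphometric
ratio characters get no special engine logic: a specimen at an interval
boundary is handled by the user selecting both contiguous states, and
the CLI `--select` help says so.

## Selectivity ("green") score

The key highlights characters that are easy to observe and split the
remaining taxa nearly evenly. Ease is an editorial judgement and stays a
stored flag (`CharacterDef.highlighted`); evenness is computable. For a
character with k states we first compute retention counts
`r_s = |{t ∈ candidates : t compatible with {s}}|` — each an actual
single-state what-if filter, so polymorphic taxa count toward each of
their states and unknown taxa toward every state (keeping `r_s` an
operationally meaningful number rather than a frequency estimate). Then

    score = coded_fraction × H(p) / log k,   p_s = r_s / Σ r_s

with `0·log 0 = 0`, score 0 when `Σ r_s = 0`, and natural logarithms
(the ratio is base-invariant, bounding the score in [0, 1] for any
k ∈ [2, 9]). The coded-fraction factor stops a character that is mostly
unknown — whose retention counts are flat by construction — from
looking like a perfect splitter. Ranking sorts by score descending with
ties broken by character-window ordinal, excludes already-selected
characters, and flags scores ≥ 0.8 (default, tunable) as green. Both
the formula and the threshold are this package's own definitions; the
original tool publishes neither.

## Serialization

A key bundle is one JSON document (metadata, ordered characters with
states, ordered taxa) plus one dense TSV of codings (rows = taxa,
columns = characters, cells `stateid(;stateid)* | ? | -`). Density is
deliberate: an absent cell cannot be told apart from a forgotten one, so
unknowns must be spelled out. Writing is canonical — sorted JSON keys,
`\n` endings, state sets serialized in character ordinal order — so
equal matrices give equal bytes and bundles diff cleanly under version
control; `read(write(m)) == m` is property-tested. The TXT
identification-code export (header with application/data versions and
modification date, `TAXON`, `STATE`, `FILTER` records; states in window
order regardless of selection order) is frozen by a hand-written golden
file, since its value is precisely bit-stability across time.

## Description protocol

`validate_description_form` checks an encoded taxon description against
the key: every mandatory metadata field (name, rank, author, year,
subfamily, distribution, body-length range — the fields the per-taxon
information window displays) and an *explicit* coding for every one of
the 98 characters, where an explicit `?` is acceptable and a silent
omission is not. The mandatory-field set is this package's reading of
"the minimum information needed to describe a new taxon into the key";
remarks, page and images stay optional.

## Packaged fixtures

The package ships the published structural lists: 98 character names
under 8 body-section headings (HEAD 26, ANTENNAE 8, MOUTHPARTS 4,
THORAX 22, WING 18, LEGS 8, ABDOMEN 11, COLOUR 1) and the April-2012
checklist of 423 terminal taxa. Spelling is preserved verbatim,
including evident typos ("lenght of second aristomere"; "Blepharella
Macquart, 1951"), because the fixtures are transcriptions, not
editions. Bracket annotations are parsed into ranks: `[subgenus of X]`
(8 terminals), `[partim]` (1 species-group), `[sensu stricto]` /
`[except ...]` (genus partitions); partitions share their parent genus
so collapsing terminals yields exactly 414 genera. The one duplicated
printed name (*Phytomyptera*, printed both as a genus partition and as
a species-group) is disambiguated as "Phytomyptera [partim]" to keep
terminal names unique. The character fixture carries no state
inventories — the per-character state lists were never published — so
it supports counting, naming and protocol validation, not filtering.
Character and state identifiers are slugs derived from printed names
(lowercase, parentheses stripped, hyphenated, deterministic `-2`/`-3`
suffixes on collision): stable and diff-friendly where the source
provides no identifiers.

## Synthetic matrices

Because the real coded matrix is not publicly distributable, everything
is exercised against generated matrices reproducing its published
*shape*. Defaults of `SyntheticSpec`: 423 taxa, 98 characters, 374
states within bounds [2, 9], 4 subfamilies, 6 host-group labels.
Unpublished quantities were fixed once at field-plausible values:
polymorphic coded entries 15 % (generic polymorphism is common but
minority), unknown 5 %, inapplicable 1 %, per-label host inclusion 25 %
(leaving ~18 % of taxa with unknown hosts), body-length minimum ~
U(2, 12) mm with span ~ U(1, 8) mm, matching small-to-midsize tachinids.
State totals are allocated by starting every character at the lower
bound and distributing the remaining budget one state at a time to a
uniformly drawn character still below the upper bound — exact totals by
construction, both bounds reachable. All randomness flows from one
integer seed through `numpy.random.default_rng`; equal seeds give
byte-identical bundles, and generated matrices always validate.

What the generator does **not** emulate: correlations between
morphological characters, phylogenetic signal, section-dependent state
counts, or realistic missingness structure (unknowns cluster in rarely
collected genera, not uniformly). Passing tests therefore demonstrate
the engine's logic and contracts, not identification performance on the
real fauna.

## Numerical and degenerate-case choices

- Entropy: natural log, `0·log 0 = 0`; score exactly 0.0 for
  all-unknown or constant characters; `NOTHING_TO_SPLIT` raised below 2
  candidates rather than returning a meaningless 0.
- Validation returns ordered violation records (matrix/character level
  first, then by taxon and character ordinal) instead of raising, so
  reports are deterministic and complete; writers refuse on the first
  violation.
- Deselecting a character's last state removes the character from the
  selection entirely — an empty constraint would otherwise eliminate
  every coded taxon.
- Year plausibility is a 4-digit check only; author-string parsing stops
  at "Author(s), year" (no nomenclatural authority parsing).
- Tests of the suite run in a few seconds; the largest object exercised
  is the full 423 × 98 default matrix.

## Known limitations

- The packaged character fixture cannot drive a real identification
  (no state inventories); only synthetic matrices can.
- Probabilistic/error-tolerant identification and automatic removal of
  redundant characters are deliberately out of scope, as they are in
  the original tool.
- No DELTA/SDD/Lucid interoperability; the JSON+TSV bundle is this
  package's own format.
- The selectivity score treats states as unordered; for interval-coded
  ratio characters an order-aware score could rank boundary-straddling
  selections better.
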