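# tachikey

A matrix-based **multi-access (polyclave) identification key engine**,
built around the generic key to Palaearctic Tachinidae — a family of
parasitoid flies with more than 400 genera in the region, notoriously
hard to key out dichotomously.

A multi-access key stores a *characters × taxa* matrix: 98 multi-state
morphological characters (2–9 states each, 374 states in total, grouped
into 8 body sections) against 423 terminal taxa (414 genera, 8 subgenera
treated separately, 1 species-group partition). Unlike a dichotomous
key, characters can be consulted in any order; damaged or ambiguous
specimens are handled by simply skipping characters or selecting several
states at once.

`tachikey` is for biodiversity informaticians and taxonomists who want
that engine as a reusable, scriptable library: deterministic filtering,
character ranking, auditable identification codes, a description-protocol
validator, and a seeded generator of structurally realistic matrices.

## The model

Each matrix cell is a coding: a non-empty set of states (polymorphism is
legitimate — a genus varies across its species), *unknown* (`?`), or
*inapplicable* (`-`). A selection maps characters to chosen state sets
and may add a specimen length (integer mm), a subfamily, and host
groups. Taxon *t* survives iff for every constrained character *c*

```
coding(t, c) is unknown/inapplicable,  or  coding(t, c) ∩ selected(c) ≠ ∅
```

plus the length/subfamily/host filters. Missing data never eliminates a
taxon (a `--strict-unknowns` mode inverts that), so adding constraints
only ever shrinks the candidate set, and widening a state set only ever
grows it.

Characters are ranked by a normalized-entropy **selectivity score**

```
score(c) = coded_fraction(c) · H(p) / log k,    p_s = r_s / Σ r_s
```

where `r_s` is the number of current candidates a single-state selection
of state *s* would retain and *k* is the number of states. A score of 1
means a fully coded, perfectly even split — the "green" characters that
give near-linear reduction of candidates.

## Worked example

```python
import tachikey as tk

toy = tk.make_toy_matrix()   # 2 characters, 4 taxa
sel = tk.Selection(char_states={"c1": frozenset({"a"}),   # eye pubescence: bare
                                "c2": frozenset({"y"})})  # costal spine: short
res = tk.filter_taxa(toy, sel)
print([toy.taxa[t].display_name() for t in res.candidates], res.resolved)
print(round(tk.selectivity_score(toy, (0, 1, 2, 3), "c1"), 3))
```

prints

```
['Gamma Brown, 1920'] True
0.971
```

Only *Gamma* survives: the two taxa coded `b` at `c1` are discarded, and
*Gamma*, unknown at `c2`, is retained — missing data is not eliminative —
so the search is resolved. The score 0.971 is the normalized binary
entropy of the 2-vs-3 split `c1` induces on the four candidates, damped
by nothing since all four are coded.

The same workflow from the shell:

```
$ tachikey simulate --taxa 423 --chars 98 --states 374 --seed 1 --out key
$ tachikey summary key.json key.tsv | head -4
taxa	423
characters	98
states_total	374
states_per_character	2..7
$ tachikey rank key.json key.tsv --top 3
rank	score	green	char_id	name
1	0.964	green	c022	synthetic character 22
2	0.961	green	c027	synthetic character 27
3	0.960	green	c057	synthetic character 57
$ tachikey identify key.json key.tsv --select c001=s1 --select c002=s2 --length 6 | tail -1
31 candidate(s) remain
```

`identify --export code.txt` writes the identification code — the
remaining taxa plus every selected state in character-window order — as
a TXT audit trail for the determination.

The packaged reference fixtures load without any external data:

```python
chars = tk.load_packaged_characters()   # 98 characters, 8 sections
taxa  = tk.load_packaged_taxa()         # 423 terminals, 414 genera
```

## Layout

| module | contents |
| --- | --- |
| `tachikey.model` | domain types, matrix validation, description-protocol validator |
| `tachikey.io` | JSON+TSV bundle reader/writer, packaged fixtures, TXT export |
| `tachikey.engine` | selections, compatibility predicates, `filter_taxa` |
| `tachikey.analytics` | retention counts, selectivity score, ranking, summaries |
| `tachikey.synthetic` | seeded matrix generator and the toy worked example |
| `tachikey.cli` | `tachikey` console script |

See `docs/methods.md` for the modelling choices and their rationale.
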