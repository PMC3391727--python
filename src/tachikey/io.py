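"""Readers and writers for the key-matrix bundle and related documents.

On disk a key is a two-file bundle:

* a JSON document holding the version metadata, the ordered character
  list (with states) and the ordered taxon list;
* a dense TSV table of codings — one row per taxon in matrix order, one
  column per character in window order.  A cell is a ``;``-joined list of
  state ids for a coded entry, ``?`` for unknown and ``-`` for
  inapplicable, so missing data is always explicit.

Both writers are canonical (sorted JSON keys, ``\\n`` endings, state sets
listed in character ordinal order), which makes serialized matrices
byte-comparable and diffable.

The module also ships two packaged reference fixtures — the 98-character
list (8 body sections) and the 423-terminal checklist of Palaearctic
tachinid genera (April 2012) — and the TXT exporter for identification
codes.
"""

from __future__ import annotations

import json
import re
from importlib import resources

from .model import (
    INAPPLICABLE,
    UNKNOWN,
    CharacterDef,
    CodingEntry,
    KeyDataError,
    KeyMatrix,
    MatrixMeta,
    StateDef,
    TaxonRecord,
    slugify,
    validate_matrix,
)

_CELL_RE = re.compile(r"^(\?|-|[^\s;]+(?:;[^\s;]+)*)$")


def parse_cell(cell: str) -> CodingEntry:
    """Parse one TSV cell: ``stateid(;stateid)*``, ``?`` or ``-``."""
    if not _CELL_RE.match(cell):
        raise KeyDataError("CELL_SYNTAX", f"bad cell {cell!r}")
    if cell == "?":
        return UNKNOWN
    if cell == "-":
        return INAPPLICABLE
    return CodingEntry.coded(cell.split(";"))


def format_cell(entry: CodingEntry, character: CharacterDef) -> str:
    """Canonical cell text: states in the character's ordinal order."""
    if entry.kind == "unknown":
        return "?"
    if entry.kind == "inapplicable":
        return "-"
    return ";".join(sid for sid in character.state_ids if sid in entry.states)


def _taxon_to_json(rec: TaxonRecord) -> dict:
    return {
        "terminal_name": rec.terminal_name,
        "rank": rec.rank,
        "parent_genus": rec.parent_genus,
        "author": rec.author,
        "year": rec.year,
        "page": rec.page,
        "subfamily": rec.subfamily,
        "hosts": sorted(rec.hosts),
        "body_length_mm": list(rec.body_length_mm) if rec.body_length_mm else None,
        "distribution": rec.distribution,
        "remarks": rec.remarks,
        "image_refs": list(rec.image_refs),
    }


def _taxon_from_json(obj: dict) -> TaxonRecord:
    length = obj.get("body_length_mm")
    return TaxonRecord(
        terminal_name=obj["terminal_name"],
        rank=obj.get("rank", "genus"),
        parent_genus=obj.get("parent_genus"),
        author=obj.get("author"),
        year=obj.get("year"),
        page=obj.get("page"),
        subfamily=obj.get("subfamily"),
        hosts=frozenset(obj.get("hosts", ())),
        body_length_mm=tuple(length) if length else None,
        distribution=obj.get("distribution", ""),
        remarks=obj.get("remarks", ""),
        image_refs=tuple(obj.get("image_refs", ())),
    )


def write_matrix(matrix: KeyMatrix) -> tuple[str, str]:
    """Serialize a valid matrix to canonical ``(json_text, tsv_text)``.

    Refuses an invalid matrix, quoting its first violation, so no
    structurally broken bundle can reach disk.
    """
    violations = validate_matrix(matrix)
    if violations:
        v = violations[0]
        raise ValueError(f"refusing to write invalid matrix: {v.code} at {v.location}: {v.message}")

    doc = {
        "meta": {
            "app_version": matrix.meta.app_version,
            "data_version": matrix.meta.data_version,
            "last_modified": matrix.meta.last_modified,
            "language": matrix.meta.language,
        },
        "characters": [
            {
                "char_id": c.char_id,
                "name": c.name,
                "section": c.section,
                "highlighted": c.highlighted,
                "states": [{"state_id": s.state_id, "label": s.label} for s in c.states],
            }
            for c in matrix.characters
        ],
        "taxa": [_taxon_to_json(t) for t in matrix.taxa],
    }
    json_text = json.dumps(doc, sort_keys=True, indent=1, ensure_ascii=False) + "\n"

    lines = ["\t".join(matrix.char_ids)]
    for t in range(len(matrix.taxa)):
        lines.append("\t".join(format_cell(matrix.coding(t, c.char_id), c) for c in matrix.characters))
    tsv_text = "\n".join(lines) + "\n"
    return json_text, tsv_text


def read_characters(json_text: str) -> list[CharacterDef]:
    """Parse just the ordered character list out of a bundle's JSON half."""
    doc = json.loads(json_text)
    return [
        CharacterDef(
            char_id=c["char_id"],
            name=c["name"],
            section=c["section"],
            highlighted=c.get("highlighted", False),
            ordinal=i + 1,
            states=tuple(
                StateDef(s["state_id"], s["label"], j + 1) for j, s in enumerate(c.get("states", ()))
            ),
        )
        for i, c in enumerate(doc.get("characters", ()))
    ]


def read_matrix(json_text: str, tsv_text: str) -> KeyMatrix:
    """Parse a bundle back into a :class:`KeyMatrix`.

    Raises :class:`KeyDataError` ``ORDER_MISMATCH`` when the TSV header
    does not equal the JSON character order (or the row count does not
    match the taxon list), and ``CELL_SYNTAX`` with row/column
    coordinates for a malformed cell.
    """
    doc = json.loads(json_text)
    meta = MatrixMeta(**doc.get("meta", {}))
    characters = read_characters(json_text)
    taxa = [_taxon_from_json(t) for t in doc.get("taxa", ())]

    rows = tsv_text.rstrip("\n").split("\n") if tsv_text.strip() else []
    if not rows:
        raise KeyDataError("ORDER_MISMATCH", "TSV has no header row")
    header = rows[0].split("\t")
    char_ids = [c.char_id for c in characters]
    if header != char_ids:
        raise KeyDataError("ORDER_MISMATCH", f"TSV header {header!r} != character order {char_ids!r}")
    if len(rows) - 1 != len(taxa):
        raise KeyDataError("ORDER_MISMATCH", f"{len(rows) - 1} coding rows for {len(taxa)} taxa")

    codings: dict[tuple[int, str], CodingEntry] = {}
    for t, row in enumerate(rows[1:]):
        cells = row.split("\t")
        if len(cells) != len(characters):
            raise KeyDataError("CELL_SYNTAX", f"row {t}: {len(cells)} cells for {len(characters)} characters")
        for cid, cell in zip(char_ids, cells):
            try:
                codings[(t, cid)] = parse_cell(cell)
            except KeyDataError:
                raise KeyDataError("CELL_SYNTAX", f"row {t}, column {cid}: bad cell {cell!r}") from None
    return KeyMatrix(characters=characters, taxa=taxa, codings=codings, meta=meta)


# ---------------------------------------------------------------------------
# Packaged fixtures


def _read_fixture(name: str) -> str:
    ref = resources.files("tachikey.data").joinpath(name)
    return ref.read_text(encoding="utf-8")


def load_packaged_characters() -> list[CharacterDef]:
    """The packaged 98-character list (names and sections only).

    State inventories are not part of the published list, so the returned
    characters are structural skeletons with empty ``states``; they are
    meant for counting, naming and protocol validation, not filtering.
    """
    text = _read_fixture("characters.txt")
    characters: list[CharacterDef] = []
    taken: set[str] = set()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        section, _, items = line.partition(":")
        section = section.strip()
        for item in items.rstrip(".").split(";"):
            name = item.strip()
            if not name:
                raise ValueError(f"empty character name under section {section!r}")
            characters.append(
                CharacterDef(
                    char_id=slugify(name, taken),
                    name=name,
                    section=section,
                    ordinal=len(characters) + 1,
                )
            )
    return characters


_ENTRY_RE = re.compile(r"^(?P<name>[A-Z][a-zA-Z']+)\s*(?P<rest>.*)$")
_AUTHOR_YEAR_RE = re.compile(r"^(?P<author>.+?),?\s+(?P<year>1[5-9]\d{2}|20\d{2})$")
_SUBGENUS_RE = re.compile(r"^subgenus of (?P<parent>[A-Z][a-zA-Z']+)$")


def _parse_taxon_line(line: str) -> TaxonRecord:
    m = _ENTRY_RE.match(line)
    if not m:
        raise ValueError(f"unparseable terminal-taxon entry: {line!r}")
    name = m.group("name")
    rest = m.group("rest")

    annotations = re.findall(r"\[([^\]]*)\]", rest)
    pre = rest.split("[", 1)[0].strip()

    author = year = None
    if pre:
        ay = _AUTHOR_YEAR_RE.match(pre)
        if not ay:
            raise ValueError(f"cannot parse author/year in entry: {line!r}")
        author = ay.group("author")
        year = int(ay.group("year"))

    rank, parent, remarks = "genus", name, []
    for ann in annotations:
        ann = ann.strip()
        sg = _SUBGENUS_RE.match(ann)
        if sg:
            rank, parent = "subgenus", sg.group("parent")
        elif ann == "partim":
            rank = "species-group"
        elif ann == "sensu stricto" or ann.startswith("except"):
            rank = "genus-partim"
            remarks.append(ann)
        else:
            remarks.append(ann)
    return TaxonRecord(
        terminal_name=name,
        rank=rank,
        parent_genus=parent,
        author=author,
        year=year,
        remarks="; ".join(remarks),
    )


def load_packaged_taxa() -> list[TaxonRecord]:
    """The packaged checklist of 423 terminal taxa, in printed order.

    Bracket annotations are parsed: ``[subgenus of X]`` yields a
    subgenus-rank terminal under genus *X*; ``[partim]`` a species-group
    partition; ``[sensu stricto]`` / ``[except ...]`` a genus partition.
    Partitions keep their own terminal but share the parent genus, so
    collapsing terminals by genus reproduces the genus-level census.
    Spelling (including printed typos) is preserved verbatim.
    """
    text = _read_fixture("taxa.txt")
    taxa = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            taxa.append(_parse_taxon_line(line))
    names = [t.terminal_name for t in taxa]
    dup_partitions = {n for n in names if names.count(n) > 1}
    # genus partitions printed under the same name are disambiguated by rank
    out = []
    for t in taxa:
        if t.terminal_name in dup_partitions and t.rank == "species-group":
            out.append(
                TaxonRecord(
                    terminal_name=f"{t.terminal_name} [partim]",
                    rank=t.rank,
                    parent_genus=t.parent_genus,
                    author=t.author,
                    year=t.year,
                    remarks=t.remarks,
                )
            )
        else:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# Identification-code export


def export_identification_code(matrix: KeyMatrix, result) -> str:
    """Render an identification result as the TXT audit code.

    The code records, against the key's version metadata, the remaining
    candidate taxa and the exact character states (plus length, subfamily
    and host filters) that produced them — a durable record that lets a
    determination be re-checked after nomenclatural changes or matrix
    updates.  Dialect: ``#`` header lines, then ``TAXON``, ``STATE`` and
    ``FILTER`` records, tab-separated, ``\\n`` endings.  States appear in
    character-window order regardless of selection order.
    """
    meta = matrix.meta
    sel = result.selection
    lines = [
        f"# application={meta.app_version} data={meta.data_version} modified={meta.last_modified}",
        f"# taxa_remaining={len(result.candidates)}",
    ]
    for t in result.candidates:
        lines.append(f"TAXON\t{matrix.taxa[t].display_name()}")
    for ch in matrix.characters:
        selected = sel.char_states.get(ch.char_id)
        if not selected:
            continue
        labels = [s.label for s in ch.states if s.state_id in selected]
        lines.append(f"STATE\t{ch.section}\t{ch.name}\t{'; '.join(labels)}")
    if sel.specimen_length_mm is not None:
        lines.append(f"FILTER\tlength_mm={sel.specimen_length_mm}")
    if sel.subfamily is not None:
        lines.append(f"FILTER\tsubfamily={sel.subfamily}")
    if sel.host_groups:
        lines.append(f"FILTER\thosts={';'.join(sorted(sel.host_groups))}")
        lines.append(f"FILTER\tinclude_unknown_hosts={'true' if sel.include_unknown_hosts else 'false'}")
    return "\n".join(lines) + "\n"
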