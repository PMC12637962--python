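"""BioC-flavoured document model with structure-preserving table encoding.

A converted supplementary file becomes one :class:`BioCDocument`. Tables are
stored as passages whose text is the row-major linearization of the grid
(cells joined by TAB, rows by NEWLINE) and whose cell values are recoverable
exactly from per-cell annotations carrying ``row``/``col`` infons — so the
passage text stays minable as free text while the grid survives losslessly,
including cells that themselves contain tabs or newlines.

Offsets are 0-based *character* offsets with half-open spans. Annotation
locations serialize at document scope (passage offset + span start), the
convention used by BioC collections in the wild.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Iterator
from xml.sax.saxutils import escape, quoteattr

PASSAGE_TYPES = ("title", "paragraph", "table", "table_caption")

#: infon keys used by the table encoding (documented convention, see README)
K_TYPE = "type"
K_TABLE_ID = "table_id"
K_N_ROWS = "n_rows"
K_N_COLS = "n_cols"
K_SHEET = "source_sheet"
K_CAPTION_FOR = "caption_for"
K_ROW = "row"
K_COL = "col"


class BioCValidationError(ValueError):
    """A document, passage or annotation violates a model invariant."""


class BioCParseError(ValueError):
    """Input text is not well-formed BioC-XML / BioC-JSON."""


@dataclass
class Table:
    """A rectangular grid of text cells; the atomic unit of categorization.

    ``cells`` is row-major with length exactly ``n_rows * n_cols``; empty
    cells are empty strings, never absent.
    """

    table_id: str
    n_rows: int
    n_cols: int
    cells: list[str]
    caption: str | None = None
    source_sheet: str | None = None

    @classmethod
    def from_rows(
        cls,
        table_id: str,
        rows: Iterable[Iterable[str]],
        caption: str | None = None,
        source_sheet: str | None = None,
    ) -> "Table":
        grid = [[str(c) for c in r] for r in rows]
        n_rows = len(grid)
        n_cols = max((len(r) for r in grid), default=0)
        cells = [r[j] if j < len(r) else "" for r in grid for j in range(n_cols)]
        if n_rows and not n_cols:
            n_rows = 0
        return cls(table_id, n_rows, n_cols, cells, caption, source_sheet)

    def rows(self) -> list[list[str]]:
        return [
            self.cells[i * self.n_cols : (i + 1) * self.n_cols]
            for i in range(self.n_rows)
        ]

    def validate(self) -> None:
        if len(self.cells) != self.n_rows * self.n_cols:
            raise BioCValidationError(
                f"table {self.table_id!r}: {len(self.cells)} cells, "
                f"expected {self.n_rows}x{self.n_cols}"
            )
        if (self.n_rows == 0) != (self.n_cols == 0):
            raise BioCValidationError(
                f"table {self.table_id!r}: n_rows=0 iff n_cols=0 violated "
                f"({self.n_rows}x{self.n_cols})"
            )


@dataclass
class CellAnnotation:
    """Half-open character span of one cell within its passage text."""

    row: int
    col: int
    start: int
    end: int
    text: str


@dataclass
class BioCPassage:
    offset: int
    text: str
    passage_type: str
    annotations: list[CellAnnotation] = field(default_factory=list)
    infons: dict[str, str] = field(default_factory=dict)

    def validate(self, where: str = "") -> None:
        if self.passage_type not in PASSAGE_TYPES:
            raise BioCValidationError(f"{where}: unknown passage type {self.passage_type!r}")
        seen: set[tuple[int, int]] = set()
        for a in self.annotations:
            if not (0 <= a.start <= a.end <= len(self.text)):
                raise BioCValidationError(
                    f"{where}: annotation span [{a.start},{a.end}) outside "
                    f"passage text of length {len(self.text)}"
                )
            if self.text[a.start : a.end] != a.text:
                raise BioCValidationError(
                    f"{where}: annotation text mismatch at ({a.row},{a.col})"
                )
            if (a.row, a.col) in seen:
                raise BioCValidationError(f"{where}: duplicate cell ({a.row},{a.col})")
            seen.add((a.row, a.col))
        if self.passage_type == "table":
            n_rows = int(self.infons.get(K_N_ROWS, "0"))
            n_cols = int(self.infons.get(K_N_COLS, "0"))
            if len(self.annotations) != n_rows * n_cols:
                raise BioCValidationError(
                    f"{where}: table passage has {len(self.annotations)} cell "
                    f"annotations, expected {n_rows * n_cols}"
                )


@dataclass
class BioCDocument:
    doc_id: str
    media_class: str
    passages: list[BioCPassage] = field(default_factory=list)
    infons: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        expected = 0
        for i, p in enumerate(self.passages):
            if p.offset != expected:
                raise BioCValidationError(
                    f"document {self.doc_id!r} passage {i}: offset {p.offset}, "
                    f"expected {expected}"
                )
            p.validate(where=f"document {self.doc_id!r} passage {i}")
            expected = p.offset + len(p.text) + 1  # single-newline separator

    def text(self) -> str:
        return "\n".join(p.text for p in self.passages)


# ---------------------------------------------------------------------------
# table <-> passage bridge


def linearize_grid(rows: list[list[str]]) -> tuple[str, list[CellAnnotation]]:
    """Row-major linearization with TAB/NEWLINE separators + cell spans."""
    parts: list[str] = []
    anns: list[CellAnnotation] = []
    pos = 0
    for i, row in enumerate(rows):
        if i:
            parts.append("\n")
            pos += 1
        for j, cell in enumerate(row):
            if j:
                parts.append("\t")
                pos += 1
            anns.append(CellAnnotation(i, j, pos, pos + len(cell), cell))
            parts.append(cell)
            pos += len(cell)
    return "".join(parts), anns


def table_passages(table: Table, offset: int) -> list[BioCPassage]:
    """Encode a table (plus optional caption passage) starting at ``offset``."""
    table.validate()
    out: list[BioCPassage] = []
    if table.caption is not None:
        out.append(
            BioCPassage(
                offset=offset,
                text=table.caption,
                passage_type="table_caption",
                infons={K_CAPTION_FOR: table.table_id},
            )
        )
        offset += len(table.caption) + 1
    text, anns = linearize_grid(table.rows())
    infons = {
        K_TABLE_ID: table.table_id,
        K_N_ROWS: str(table.n_rows),
        K_N_COLS: str(table.n_cols),
    }
    if table.source_sheet is not None:
        infons[K_SHEET] = table.source_sheet
    out.append(BioCPassage(offset=offset, text=text, passage_type="table", annotations=anns, infons=infons))
    return out


def tables_of(document: BioCDocument) -> list[Table]:
    """Reconstruct :class:`Table` objects from a document's table passages."""
    captions = {
        p.infons[K_CAPTION_FOR]: p.text
        for p in document.passages
        if p.passage_type == "table_caption" and K_CAPTION_FOR in p.infons
    }
    out: list[Table] = []
    for p in document.passages:
        if p.passage_type != "table":
            continue
        n_rows = int(p.infons[K_N_ROWS])
        n_cols = int(p.infons[K_N_COLS])
        cells = [""] * (n_rows * n_cols)
        for a in p.annotations:
            cells[a.row * n_cols + a.col] = a.text
        tid = p.infons[K_TABLE_ID]
        out.append(
            Table(
                table_id=tid,
                n_rows=n_rows,
                n_cols=n_cols,
                cells=cells,
                caption=captions.get(tid),
                source_sheet=p.infons.get(K_SHEET),
            )
        )
    return out


def document_from_parts(
    doc_id: str,
    media_class: str,
    parts: Iterable[tuple[str, object]],
    infons: dict[str, str] | None = None,
) -> BioCDocument:
    """Assemble a document from ('paragraph'|'title', text) and ('table', Table) parts."""
    passages: list[BioCPassage] = []
    offset = 0
    for kind, payload in parts:
        if kind == "table":
            for p in table_passages(payload, offset):  # type: ignore[arg-type]
                passages.append(p)
                offset = p.offset + len(p.text) + 1
        else:
            text = str(payload)
            passages.append(BioCPassage(offset=offset, text=text, passage_type=kind))
            offset += len(text) + 1
    return BioCDocument(doc_id, media_class, passages, dict(infons or {}))


# ---------------------------------------------------------------------------
# XML codec

_XML_HEADER = "<?xml version='1.0' encoding='UTF-8'?>\n<!DOCTYPE collection SYSTEM 'BioC.dtd'>\n"


def _infon_xml(infons: dict[str, str], indent: str) -> str:
    return "".join(
        f"{indent}<infon key={quoteattr(k)}>{escape(infons[k])}</infon>\n"
        for k in sorted(infons)
    )


def write_bioc_xml(collection: list[BioCDocument]) -> str:
    """Serialize to BioC-XML. Deterministic: sorted infon keys, fixed header."""
    for doc in collection:
        doc.validate()
    buf = [_XML_HEADER, "<collection>\n  <source>suppmat</source>\n  <date></date>\n  <key>suppmat.key</key>\n"]
    for doc in collection:
        buf.append("  <document>\n")
        buf.append(f"    <id>{escape(doc.doc_id)}</id>\n")
        infons = dict(doc.infons)
        infons["media_class"] = doc.media_class
        buf.append(_infon_xml(infons, "    "))
        for p in doc.passages:
            buf.append("    <passage>\n")
            pinfons = dict(p.infons)
            pinfons[K_TYPE] = p.passage_type
            buf.append(_infon_xml(pinfons, "      "))
            buf.append(f"      <offset>{p.offset}</offset>\n")
            buf.append(f"      <text>{escape(p.text)}</text>\n")
            for a in p.annotations:
                buf.append(
                    f'      <annotation id="{a.row}.{a.col}">\n'
                    f"        <infon key=\"col\">{a.col}</infon>\n"
                    f"        <infon key=\"row\">{a.row}</infon>\n"
                    f'        <location offset="{p.offset + a.start}" length="{a.end - a.start}"/>\n'
                    f"        <text>{escape(a.text)}</text>\n"
                    f"      </annotation>\n"
                )
            buf.append("    </passage>\n")
        buf.append("  </document>\n")
    buf.append("</collection>\n")
    return "".join(buf)


def _elem_infons(elem: ET.Element) -> dict[str, str]:
    return {e.attrib["key"]: e.text or "" for e in elem.findall("infon")}


def read_bioc_xml(text: str) -> list[BioCDocument]:
    """Parse BioC-XML back into documents; unknown infons preserved verbatim."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:  # exc carries (line, column)
        raise BioCParseError(f"malformed XML: {exc}") from exc
    if root.tag != "collection":
        raise BioCParseError(f"expected <collection> root, got <{root.tag}>")
    docs: list[BioCDocument] = []
    for d in root.findall("document"):
        doc_id = d.findtext("id") or ""
        infons = _elem_infons(d)
        media_class = infons.pop("media_class", "plain_text")
        passages: list[BioCPassage] = []
        for pe in d.findall("passage"):
            pinfons = _elem_infons(pe)
            ptype = pinfons.pop(K_TYPE, "paragraph")
            offset = int(pe.findtext("offset") or "0")
            ptext = pe.findtext("text") or ""
            anns: list[CellAnnotation] = []
            for ae in pe.findall("annotation"):
                ainfons = _elem_infons(ae)
                loc = ae.find("location")
                if loc is None:
                    raise BioCParseError("annotation without <location>")
                start = int(loc.attrib["offset"]) - offset
                length = int(loc.attrib["length"])
                anns.append(
                    CellAnnotation(
                        row=int(ainfons[K_ROW]),
                        col=int(ainfons[K_COL]),
                        start=start,
                        end=start + length,
                        text=ae.findtext("text") or "",
                    )
                )
            passages.append(BioCPassage(offset, ptext, ptype, anns, pinfons))
        doc = BioCDocument(doc_id, media_class, passages, infons)
        doc.validate()
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# JSON codec (same data model; mutually convertible with the XML codec)


def _doc_to_obj(doc: BioCDocument) -> dict:
    infons = dict(doc.infons)
    infons["media_class"] = doc.media_class
    return {
        "id": doc.doc_id,
        "infons": infons,
        "passages": [
            {
                "infons": {**p.infons, K_TYPE: p.passage_type},
                "offset": p.offset,
                "text": p.text,
                "annotations": [
                    {
                        "id": f"{a.row}.{a.col}",
                        "infons": {"row": str(a.row), "col": str(a.col)},
                        "locations": [{"offset": p.offset + a.start, "length": a.end - a.start}],
                        "text": a.text,
                    }
                    for a in p.annotations
                ],
            }
            for p in doc.passages
        ],
    }


def write_bioc_json(collection: list[BioCDocument]) -> str:
    for doc in collection:
        doc.validate()
    obj = {
        "source": "suppmat",
        "date": "",
        "key": "suppmat.key",
        "infons": {},
        "documents": [_doc_to_obj(d) for d in collection],
    }
    return json.dumps(obj, ensure_ascii=False, sort_keys=True, indent=1)


def read_bioc_json(text: str) -> list[BioCDocument]:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise BioCParseError(f"malformed JSON: {exc}") from exc
    docs: list[BioCDocument] = []
    for d in obj.get("documents", []):
        infons = dict(d.get("infons", {}))
        media_class = infons.pop("media_class", "plain_text")
        passages: list[BioCPassage] = []
        for p in d.get("passages", []):
            pinfons = dict(p.get("infons", {}))
            ptype = pinfons.pop(K_TYPE, "paragraph")
            offset = int(p.get("offset", 0))
            anns = []
            for a in p.get("annotations", []):
                loc = a["locations"][0]
                start = int(loc["offset"]) - offset
                anns.append(
                    CellAnnotation(
                        row=int(a["infons"]["row"]),
                        col=int(a["infons"]["col"]),
                        start=start,
                        end=start + int(loc["length"]),
                        text=a.get("text", ""),
                    )
                )
            passages.append(BioCPassage(offset, p.get("text", ""), ptype, anns, pinfons))
        doc = BioCDocument(d.get("id", ""), media_class, passages, infons)
        doc.validate()
        docs.append(doc)
    return docs


def iter_tables(collection: Iterable[BioCDocument]) -> Iterator[tuple[BioCDocument, Table]]:
    for doc in collection:
        for t in tables_of(doc):
            yield doc, t
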