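"""Minimal OOXML (.docx/.pptx) reading and writing over zipfile + ElementTree.

Only the subset of WordprocessingML / PresentationML needed for the pipeline:
paragraph text, tables (with horizontally/vertically merged cells expanded by
value duplication), and slide text frames. Writers exist so the synthetic
corpus can emit real containers without external dependencies; all zip
members carry a fixed timestamp so regeneration is byte-identical.
"""

from __future__ import annotations

import io
import re
import zipfile
import xml.etree.ElementTree as ET
from xml.sax.saxutils import escape

W = "{http://schemas.openxmlformats.org/wordprocessingml/2006/main}"
A = "{http://schemas.openxmlformats.org/drawingml/2006/main}"

_FIXED_DATE = (2000, 1, 1, 0, 0, 0)


class OOXMLError(ValueError):
    """Corrupt or unsupported OOXML container."""


def _zwrite(zf: zipfile.ZipFile, name: str, data: str) -> None:
    info = zipfile.ZipInfo(name, date_time=_FIXED_DATE)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, data)


# ---------------------------------------------------------------------------
# docx


def _para_text(p: ET.Element) -> str:
    return "".join(t.text or "" for t in p.iter(f"{W}t"))


def _cell_text(tc: ET.Element) -> str:
    return " ".join(_para_text(p) for p in tc.findall(f"{W}p"))


def read_docx(payload: bytes) -> tuple[list[str], list[tuple[str, list[list[str]]]]]:
    """Return (body items as ('p', text)/('tbl', grid) flattened) — see below.

    Returns (items,) where items is an ordered list of ("p", text) and
    ("tbl", grid) tuples; merged cells are expanded by duplicating values.
    """
    try:
        with zipfile.ZipFile(io.BytesIO(payload)) as zf:
            xml = zf.read("word/document.xml")
        root = ET.fromstring(xml)
    except (zipfile.BadZipFile, KeyError, ET.ParseError) as exc:
        raise OOXMLError(f"unreadable docx: {exc}") from exc
    body = root.find(f"{W}body")
    if body is None:
        raise OOXMLError("docx without body")
    items: list[tuple[str, object]] = []
    for child in body:
        if child.tag == f"{W}p":
            items.append(("p", _para_text(child)))
        elif child.tag == f"{W}tbl":
            items.append(("tbl", _read_docx_table(child)))
    return items  # type: ignore[return-value]


def _read_docx_table(tbl: ET.Element) -> list[list[str]]:
    rows: list[list[str]] = []
    for tr in tbl.findall(f"{W}tr"):
        row: list[str] = []
        for tc in tr.findall(f"{W}tc"):
            pr = tc.find(f"{W}tcPr")
            span = 1
            vmerge_cont = False
            if pr is not None:
                gs = pr.find(f"{W}gridSpan")
                if gs is not None:
                    span = int(gs.attrib.get(f"{W}val", "1"))
                vm = pr.find(f"{W}vMerge")
                if vm is not None and vm.attrib.get(f"{W}val", "continue") == "continue":
                    vmerge_cont = True
            text = _cell_text(tc)
            if vmerge_cont and rows:
                # duplicate the value from the cell above
                col = len(row)
                text = rows[-1][col] if col < len(rows[-1]) else ""
            row.extend([text] * span)
        rows.append(row)
    width = max((len(r) for r in rows), default=0)
    return [r + [""] * (width - len(r)) for r in rows]


_DOCX_CT = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Types xmlns="http://schemas.openxmlformats.org/package/2006/content-types">
<Default Extension="rels" ContentType="application/vnd.openxmlformats-package.relationships+xml"/>
<Default Extension="xml" ContentType="application/xml"/>
<Override PartName="/word/document.xml" ContentType="application/vnd.openxmlformats-officedocument.wordprocessingml.document.main+xml"/>
</Types>"""

_DOCX_RELS = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="http://schemas.openxmlformats.org/package/2006/relationships">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/officeDocument" Target="word/document.xml"/>
</Relationships>"""


def write_docx(items: list[tuple[str, object]]) -> bytes:
    """items: ordered ('p', text) and ('tbl', grid-or-(grid, merges)) tuples.

    A table item may be ``('tbl', grid)`` or ``('tbl', (grid, merges))`` where
    merges is a list of (row, col, span) horizontal merges: the cell at
    (row, col) is written once with gridSpan=span and the grid's duplicated
    values at (row, col+1..col+span-1) are omitted from the markup.
    """
    ns = 'xmlns:w="http://schemas.openxmlformats.org/wordprocessingml/2006/main"'
    buf = [f'<?xml version="1.0" encoding="UTF-8" standalone="yes"?>\n<w:document {ns}><w:body>']
    for kind, payload in items:
        if kind == "p":
            buf.append(f"<w:p><w:r><w:t xml:space=\"preserve\">{escape(str(payload))}</w:t></w:r></w:p>")
        else:
            if isinstance(payload, tuple):
                grid, merges = payload
            else:
                grid, merges = payload, []
            mergemap = {(r, c): s for r, c, s in merges}
            buf.append("<w:tbl>")
            for i, row in enumerate(grid):
                buf.append("<w:tr>")
                j = 0
                while j < len(row):
                    span = mergemap.get((i, j), 1)
                    pr = f"<w:tcPr><w:gridSpan w:val=\"{span}\"/></w:tcPr>" if span > 1 else ""
                    buf.append(
                        f"<w:tc>{pr}<w:p><w:r><w:t xml:space=\"preserve\">{escape(row[j])}</w:t></w:r></w:p></w:tc>"
                    )
                    j += span
                buf.append("</w:tr>")
            buf.append("</w:tbl>")
    buf.append("</w:body></w:document>")
    out = io.BytesIO()
    with zipfile.ZipFile(out, "w") as zf:
        _zwrite(zf, "[Content_Types].xml", _DOCX_CT)
        _zwrite(zf, "_rels/.rels", _DOCX_RELS)
        _zwrite(zf, "word/document.xml", "".join(buf))
    return out.getvalue()


# ---------------------------------------------------------------------------
# pptx


def read_pptx(payload: bytes) -> tuple[list[str], list[list[list[str]]]]:
    """Return (paragraphs from text frames, table grids) across slides in order."""
    try:
        with zipfile.ZipFile(io.BytesIO(payload)) as zf:
            slide_names = sorted(
                (n for n in zf.namelist() if re.fullmatch(r"ppt/slides/slide\d+\.xml", n)),
                key=lambda n: int(re.search(r"(\d+)", n).group(1)),  # type: ignore[union-attr]
            )
            paragraphs: list[str] = []
            grids: list[list[list[str]]] = []
            for name in slide_names:
                root = ET.fromstring(zf.read(name))
                _walk_slide(root, paragraphs, grids)
    except (zipfile.BadZipFile, KeyError, ET.ParseError) as exc:
        raise OOXMLError(f"unreadable pptx: {exc}") from exc
    return paragraphs, grids


def _walk_slide(root: ET.Element, paragraphs: list[str], grids: list[list[list[str]]]) -> None:
    for tbl in root.iter(f"{A}tbl"):
        grid = []
        for tr in tbl.findall(f"{A}tr"):
            grid.append(["".join(t.text or "" for t in tc.iter(f"{A}t")) for tc in tr.findall(f"{A}tc")])
        width = max((len(r) for r in grid), default=0)
        grids.append([r + [""] * (width - len(r)) for r in grid])
    in_tables = {id(t) for tbl in root.iter(f"{A}tbl") for t in tbl.iter(f"{A}t")}
    for p in root.iter(f"{A}p"):
        texts = [t for t in p.iter(f"{A}t") if id(t) not in in_tables]
        joined = "".join(t.text or "" for t in texts)
        if joined:
            paragraphs.append(joined)


_PPTX_CT = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Types xmlns="http://schemas.openxmlformats.org/package/2006/content-types">
<Default Extension="rels" ContentType="application/vnd.openxmlformats-package.relationships+xml"/>
<Default Extension="xml" ContentType="application/xml"/>
<Override PartName="/ppt/presentation.xml" ContentType="application/vnd.openxmlformats-officedocument.presentationml.presentation.main+xml"/>
<Override PartName="/ppt/slides/slide1.xml" ContentType="application/vnd.openxmlformats-officedocument.presentationml.slide+xml"/>
</Types>"""

_PPTX_RELS = """<?xml version="1.0" encoding="UTF-8" standalone="yes"?>
<Relationships xmlns="http://schemas.openxmlformats.org/package/2006/relationships">
<Relationship Id="rId1" Type="http://schemas.openxmlformats.org/officeDocument/2006/relationships/officeDocument" Target="ppt/presentation.xml"/>
</Relationships>"""


def write_pptx(paragraphs: list[str], grids: list[list[list[str]]] | None = None) -> bytes:
    a = 'xmlns:a="http://schemas.openxmlformats.org/drawingml/2006/main"'
    body = [f'<?xml version="1.0" encoding="UTF-8" standalone="yes"?>\n<slide {a}>']
    for text in paragraphs:
        body.append(f"<sp><a:p><a:r><a:t>{escape(text)}</a:t></a:r></a:p></sp>")
    for grid in grids or []:
        body.append("<graphicFrame><a:tbl>")
        for row in grid:
            body.append("<a:tr>")
            for cell in row:
                body.append(f"<a:tc><a:txBody><a:p><a:r><a:t>{escape(cell)}</a:t></a:r></a:p></a:txBody></a:tc>")
            body.append("</a:tr>")
        body.append("</a:tbl></graphicFrame>")
    body.append("</slide>")
    out = io.BytesIO()
    with zipfile.ZipFile(out, "w") as zf:
        _zwrite(zf, "[Content_Types].xml", _PPTX_CT)
        _zwrite(zf, "_rels/.rels", _PPTX_RELS)
        _zwrite(zf, "ppt/presentation.xml", '<?xml version="1.0"?><presentation/>')
        _zwrite(zf, "ppt/slides/slide1.xml", "".join(body))
    return out.getvalue()
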