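"""Media-class detection, per-format extraction, archive expansion, and the
corpus conversion driver with success accounting.

Media class is decided by file extension first; magic bytes act as a
tiebreak for text-like extensions whose payload is actually a container,
and as the fallback for unknown extensions. PDF input is deliberately
converted to raw text only — no Table object is ever produced from a PDF.
"""

from __future__ import annotations

import csv
import gzip
import io
import tarfile
import zipfile
from collections import Counter
from dataclasses import dataclass, field

from . import _ooxml, _pdf
from .bioc import BioCDocument, Table, document_from_parts

MEDIA_CLASSES = (
    "delimited_text",
    "plain_text",
    "spreadsheet",
    "word_processor",
    "slides",
    "pdf",
    "archive",
    "non_textual",
)

_EXT_MAP = {
    ".csv": "delimited_text",
    ".tsv": "delimited_text",
    ".tab": "delimited_text",
    ".txt": "plain_text",
    ".text": "plain_text",
    ".xlsx": "spreadsheet",
    ".xlsm": "spreadsheet",
    ".xls": "spreadsheet",
    ".docx": "word_processor",
    ".doc": "word_processor",
    ".pptx": "slides",
    ".ppt": "slides",
    ".pdf": "pdf",
    ".zip": "archive",
    ".tar": "archive",
    ".gz": "archive",
    ".tgz": "archive",
}

_TEXTY = {"delimited_text", "plain_text"}

# known-binary formats routed straight to non_textual (e.g. IBM SPSS .sav)
_BINARY_EXTS = {
    ".sav", ".rdata", ".rds", ".mat", ".h5", ".hdf5", ".npy",
    ".jpg", ".jpeg", ".png", ".gif", ".tif", ".tiff", ".bmp",
    ".mp4", ".avi", ".mov", ".wav", ".mp3", ".exe", ".dll", ".so",
}


class ExtractionError(ValueError):
    """Payload could not be extracted for its media class."""


class ArchiveBombError(ExtractionError):
    """Archive expansion exceeded the configured total-bytes ceiling."""


@dataclass
class SMFile:
    """One supplementary-material file attached to an article."""

    article_id: str
    filename: str
    payload: bytes
    media_class: str = ""

    def __post_init__(self) -> None:
        if not self.media_class:
            self.media_class = detect_media_class(self.filename, self.payload)

    @property
    def size_bytes(self) -> int:
        return len(self.payload)


@dataclass
class ConversionReport:
    n_total: int = 0
    n_converted: int = 0
    n_failed: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        # empty corpus reports 1.0 by convention
        return self.n_converted / self.n_total if self.n_total else 1.0

    def record_success(self) -> None:
        self.n_total += 1
        self.n_converted += 1

    def record_failure(self, filename: str, reason: str) -> None:
        self.n_total += 1
        self.n_failed += 1
        self.failures.append((filename, reason))


# ---------------------------------------------------------------------------
# detection


def _magic_class(payload: bytes) -> str | None:
    if payload.startswith(b"%PDF"):
        return "pdf"
    if payload.startswith(b"PK\x03\x04"):
        return _classify_zip(payload)
    if payload.startswith(b"\x1f\x8b"):
        return "archive"
    if len(payload) > 265 and payload[257:262] == b"ustar":
        return "archive"
    return None


def _classify_zip(payload: bytes) -> str:
    """A PK container may be an OOXML document; peek at member names."""
    try:
        with zipfile.ZipFile(io.BytesIO(payload)) as zf:
            names = set(zf.namelist())
    except zipfile.BadZipFile:
        return "archive"
    if "word/document.xml" in names:
        return "word_processor"
    if "xl/workbook.xml" in names:
        return "spreadsheet"
    if "ppt/presentation.xml" in names:
        return "slides"
    return "archive"


def _decodable(payload: bytes) -> bool:
    if b"\x00" in payload:
        return False
    try:
        payload.decode("utf-8")
        return True
    except UnicodeDecodeError:
        # latin-1 always succeeds; require mostly-printable bytes
        bad = sum(1 for b in payload if b < 9 or (13 < b < 32))
        return bad <= len(payload) // 100


def detect_media_class(filename: str, payload: bytes) -> str:
    """Total function: extension first, magic bytes as tiebreak/fallback."""
    name = filename.lower()
    ext = "." + name.rsplit(".", 1)[-1] if "." in name else ""
    if ext in _BINARY_EXTS:
        return "non_textual"
    by_ext = _EXT_MAP.get(ext)
    magic = _magic_class(payload)
    if by_ext in _TEXTY and magic is not None:
        return magic  # e.g. "notes.txt" that is really a ZIP
    if by_ext is not None:
        return by_ext
    if magic is not None:
        return magic
    return "plain_text" if payload and _decodable(payload) else "non_textual"


# ---------------------------------------------------------------------------
# decoding


def decode_text(payload: bytes, encoding_hint: str | None = None) -> tuple[str, str]:
    """UTF-8 -> hinted/BOM charset -> Latin-1 cascade; NUL bytes mean binary."""
    if b"\x00" in payload and not payload.startswith((b"\xff\xfe", b"\xfe\xff")):
        raise ExtractionError("binary payload (NUL bytes) is not decodable text")
    if payload.startswith(b"\xff\xfe") or payload.startswith(b"\xfe\xff"):
        return payload.decode("utf-16"), "utf-16"
    if encoding_hint:
        try:
            return payload.decode(encoding_hint), encoding_hint
        except (UnicodeDecodeError, LookupError):
            pass
    try:
        return payload.decode("utf-8"), "utf-8"
    except UnicodeDecodeError:
        return payload.decode("latin-1"), "latin-1"


# ---------------------------------------------------------------------------
# delimited text

_DELIMS = (",", "\t", ";")


def sniff_delimiter(text: str, n_rows: int = 20) -> tuple[str, int]:
    """Delimiter over {comma, tab, semicolon} maximizing the consistent
    column count across the first ``n_rows`` rows. Returns (delimiter,
    consistent column count); count 1 means no delimiter structure."""
    lines = text.splitlines()[:n_rows]
    best = (",", 1)
    best_key = (-1, -1)
    for d in _DELIMS:
        counts = [len(row) for row in csv.reader(lines, delimiter=d)]
        if not counts:
            continue
        modal, freq = Counter(counts).most_common(1)[0]
        consistent = freq == len(counts)
        # prefer fully consistent multi-column, then modal frequency, then width
        key = (int(consistent and modal > 1) * 2 + int(modal > 1), modal)
        if key > best_key:
            best_key = key
            best = (d, modal)
    return best


def extract_delimited(
    payload: bytes, encoding_hint: str | None = None, table_id: str = "T1"
) -> Table:
    """Parse delimited text into a grid; ragged rows are right-padded."""
    text, _enc = decode_text(payload, encoding_hint)
    delim, _ = sniff_delimiter(text)
    rows = [row for row in csv.reader(io.StringIO(text), delimiter=delim)]
    rows = [r for r in rows if r]  # drop fully empty trailing lines
    return Table.from_rows(table_id, rows)


# ---------------------------------------------------------------------------
# spreadsheets


def _render_cell(value: object) -> str:
    import datetime

    if value is None:
        return ""
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):
        if value.is_integer():
            return str(int(value))
        return repr(value)  # shortest round-trip decimal
    if isinstance(value, (datetime.datetime, datetime.date, datetime.time)):
        return value.isoformat()
    return str(value)


def extract_spreadsheet(payload: bytes) -> list[Table]:
    """One Table per non-empty sheet, bounded by the minimal rectangle
    covering all non-empty cells; merged ranges duplicated."""
    import openpyxl

    try:
        wb = openpyxl.load_workbook(io.BytesIO(payload), data_only=True)
    except Exception as exc:  # openpyxl raises a zoo of exceptions
        raise ExtractionError(f"unreadable workbook: {exc}") from exc
    tables: list[Table] = []
    for si, ws in enumerate(wb.worksheets, start=1):
        grid = [[_render_cell(c) for c in row] for row in ws.iter_rows(values_only=True)]
        # duplicate merged values before bounding
        for rng in list(getattr(ws, "merged_cells", None).ranges if ws.merged_cells else []):
            top = grid[rng.min_row - 1][rng.min_col - 1] if rng.min_row - 1 < len(grid) else ""
            for r in range(rng.min_row - 1, rng.max_row):
                for c in range(rng.min_col - 1, rng.max_col):
                    if r < len(grid) and c < len(grid[r]):
                        grid[r][c] = top
        occupied = [
            (i, j) for i, row in enumerate(grid) for j, v in enumerate(row) if v != ""
        ]
        if not occupied:
            continue
        r0 = min(i for i, _ in occupied)
        r1 = max(i for i, _ in occupied)
        c0 = min(j for _, j in occupied)
        c1 = max(j for _, j in occupied)
        rect = [row[c0 : c1 + 1] for row in grid[r0 : r1 + 1]]
        tables.append(Table.from_rows(f"T{si}", rect, source_sheet=ws.title))
    return tables


# ---------------------------------------------------------------------------
# word processor / slides / pdf


def extract_wordproc(payload: bytes) -> tuple[list[str], list[Table]]:
    try:
        items = _ooxml.read_docx(payload)
    except _ooxml.OOXMLError as exc:
        raise ExtractionError(str(exc)) from exc
    paragraphs = [t for kind, t in items if kind == "p"]
    tables = [
        Table.from_rows(f"T{i}", grid)
        for i, (kind, grid) in enumerate(
            ((k, g) for k, g in items if k == "tbl"), start=1
        )
    ]
    return paragraphs, tables


def extract_slides(payload: bytes) -> tuple[list[str], list[Table]]:
    try:
        paragraphs, grids = _ooxml.read_pptx(payload)
    except _ooxml.OOXMLError as exc:
        raise ExtractionError(str(exc)) from exc
    return paragraphs, [Table.from_rows(f"T{i}", g) for i, g in enumerate(grids, start=1)]


def extract_pdf_text(payload: bytes) -> list[str]:
    """Raw text only; table structure is never reconstructed from PDF."""
    try:
        return _pdf.extract_text(payload)
    except _pdf.PDFError as exc:
        raise ExtractionError(str(exc)) from exc


# ---------------------------------------------------------------------------
# archives


def expand_archive(
    sm_file: SMFile, max_depth: int = 3, ceiling_bytes: int = 1 << 30
) -> list[SMFile]:
    """Recursively expand ZIP/TAR/GZ members up to ``max_depth``; member names
    are prefixed by the archive path. Aborts past ``ceiling_bytes`` total."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    budget = [ceiling_bytes]
    return _expand(sm_file, max_depth, budget)


def _expand(sm_file: SMFile, depth: int, budget: list[int]) -> list[SMFile]:
    members = _list_members(sm_file)
    out: list[SMFile] = []
    for name, data in members:
        budget[0] -= len(data)
        if budget[0] < 0:
            raise ArchiveBombError(
                f"archive expansion exceeded ceiling at {sm_file.filename}/{name}"
            )
        member = SMFile(sm_file.article_id, f"{sm_file.filename}/{name}", data)
        if member.media_class == "archive" and depth > 1:
            out.extend(_expand(member, depth - 1, budget))
        else:
            out.append(member)
    return out


def _list_members(sm_file: SMFile) -> list[tuple[str, bytes]]:
    payload = sm_file.payload
    bio = io.BytesIO(payload)
    if payload.startswith(b"PK\x03\x04"):
        try:
            with zipfile.ZipFile(bio) as zf:
                return [
                    (i.filename, zf.read(i.filename))
                    for i in zf.infolist()
                    if not i.is_dir()
                ]
        except zipfile.BadZipFile as exc:
            raise ExtractionError(f"bad zip: {exc}") from exc
    if payload.startswith(b"\x1f\x8b"):
        name = sm_file.filename.rsplit("/", 1)[-1]
        inner = name[:-3] if name.lower().endswith(".gz") else name + ".out"
        if inner.lower().endswith(".tgz"):
            inner = inner[:-4] + ".tar"
        try:
            data = gzip.decompress(payload)
        except (OSError, EOFError) as exc:
            raise ExtractionError(f"bad gzip: {exc}") from exc
        if data[257:262] == b"ustar" or inner.lower().endswith(".tar"):
            return _tar_members(data)
        return [(inner, data)]
    try:
        with tarfile.open(fileobj=bio) as tf:
            return [
                (m.name, tf.extractfile(m).read())  # type: ignore[union-attr]
                for m in tf.getmembers()
                if m.isfile()
            ]
    except tarfile.TarError as exc:
        raise ExtractionError(f"bad archive: {exc}") from exc


def _tar_members(data: bytes) -> list[tuple[str, bytes]]:
    try:
        with tarfile.open(fileobj=io.BytesIO(data)) as tf:
            return [
                (m.name, tf.extractfile(m).read())  # type: ignore[union-attr]
                for m in tf.getmembers()
                if m.isfile()
            ]
    except tarfile.TarError as exc:
        raise ExtractionError(f"bad tar: {exc}") from exc


# ---------------------------------------------------------------------------
# conversion driver


def convert_file(sm_file: SMFile) -> BioCDocument:
    """Convert one textual file to a BioC document. Raises
    :class:`ExtractionError` on failure; ValueError for archives or
    non-textual input (expand archives first — see convert_corpus)."""
    mc = sm_file.media_class
    if mc == "archive":
        raise ValueError("archives must be expanded before conversion")
    if mc == "non_textual":
        raise ValueError("non-textual files are never passed to extractors")
    doc_id = f"{sm_file.article_id}/{sm_file.filename}"
    infons = {"source_filename": sm_file.filename, "conversion_status": "ok"}

    parts: list[tuple[str, object]]
    if mc == "delimited_text":
        parts = [("table", extract_delimited(sm_file.payload))]
        _, enc = decode_text(sm_file.payload)
        infons["encoding"] = enc
    elif mc == "plain_text":
        text, enc = decode_text(sm_file.payload)
        infons["encoding"] = enc
        _, ncols = sniff_delimiter(text)
        if ncols > 1:
            parts = [("table", extract_delimited(sm_file.payload))]
        else:
            parts = [("paragraph", ln) for ln in text.splitlines() if ln.strip()]
    elif mc == "spreadsheet":
        parts = [("table", t) for t in extract_spreadsheet(sm_file.payload)]
    elif mc == "word_processor":
        items = _ooxml_items_in_order(sm_file.payload)
        parts = items
    elif mc == "slides":
        paragraphs, tables = extract_slides(sm_file.payload)
        parts = [("paragraph", p) for p in paragraphs] + [("table", t) for t in tables]
    elif mc == "pdf":
        parts = [("paragraph", p) for p in extract_pdf_text(sm_file.payload)]
    else:  # pragma: no cover - MEDIA_CLASSES is closed
        raise ValueError(f"unknown media class {mc!r}")

    doc = document_from_parts(doc_id, mc, parts, infons)
    doc.validate()
    return doc


def _ooxml_items_in_order(payload: bytes) -> list[tuple[str, object]]:
    """Word content in source order: paragraphs and tables interleaved."""
    try:
        items = _ooxml.read_docx(payload)
    except _ooxml.OOXMLError as exc:
        raise ExtractionError(str(exc)) from exc
    parts: list[tuple[str, object]] = []
    ti = 0
    for kind, payload_item in items:
        if kind == "p":
            if str(payload_item).strip():
                parts.append(("paragraph", payload_item))
        else:
            ti += 1
            parts.append(("table", Table.from_rows(f"T{ti}", payload_item)))
    return parts


def _failed_document(sm_file: SMFile, reason: str) -> BioCDocument:
    return BioCDocument(
        doc_id=f"{sm_file.article_id}/{sm_file.filename}",
        media_class=sm_file.media_class,
        passages=[],
        infons={
            "source_filename": sm_file.filename,
            "conversion_status": "failed",
            "failure_reason": reason,
        },
    )


def convert_corpus(
    files: list[SMFile], max_depth: int = 3, ceiling_bytes: int = 1 << 30
) -> tuple[list[BioCDocument], ConversionReport]:
    """Convert every textual file (expanding archives) in deterministic order.

    Archive members replace their container in the accounting; a container
    that fails to expand counts as one failed file; non-textual leaves are
    skipped and not counted.
    """
    report = ConversionReport()
    docs: list[BioCDocument] = []
    for f in sorted(files, key=lambda s: (s.article_id, s.filename)):
        if f.media_class == "non_textual":
            continue
        if f.media_class == "archive":
            try:
                members = expand_archive(f, max_depth=max_depth, ceiling_bytes=ceiling_bytes)
            except ExtractionError as exc:
                report.record_failure(f"{f.article_id}/{f.filename}", str(exc))
                docs.append(_failed_document(f, str(exc)))
                continue
            leaves = sorted(members, key=lambda s: s.filename)
        else:
            leaves = [f]
        for leaf in leaves:
            if leaf.media_class in ("non_textual", "archive"):
                continue  # unexpanded inner archives past max_depth are skipped
            try:
                docs.append(convert_file(leaf))
                report.record_success()
            except ExtractionError as exc:
                report.record_failure(f"{leaf.article_id}/{leaf.filename}", str(exc))
                docs.append(_failed_document(leaf, str(exc)))
    return docs, report
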