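"""Minimal single-page-per-stream text PDF writer and raw-text extractor.

The extractor handles uncompressed content streams only (Tj / TJ / ' show
operators), which covers every PDF the synthetic corpus emits and simple
text PDFs generally. Compressed or encrypted streams raise
:class:`PDFError` so the conversion pipeline records a failure instead of
silently emitting garbage. Tables are never reconstructed from PDFs.
"""

from __future__ import annotations

import re


class PDFError(ValueError):
    """Corrupt, encrypted, or unsupported PDF payload."""


_ESCAPES = {"n": "\n", "r": "\r", "t": "\t", "b": "\b", "f": "\f", "(": "(", ")": ")", "\\": "\\"}


def _unescape(s: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(s):
        c = s[i]
        if c == "\\" and i + 1 < len(s):
            nxt = s[i + 1]
            if nxt in _ESCAPES:
                out.append(_ESCAPES[nxt])
                i += 2
                continue
            if nxt.isdigit():  # octal escape, up to 3 digits
                j = i + 1
                while j < len(s) and j < i + 4 and s[j].isdigit():
                    j += 1
                out.append(chr(int(s[i + 1 : j], 8)))
                i = j
                continue
            i += 1
            continue
        out.append(c)
        i += 1
    return "".join(out)


_STRING_RE = re.compile(rb"\((?:\\.|[^\\()])*\)")


def extract_text(payload: bytes) -> list[str]:
    """Extract shown text strings, one list item per text-showing operator line."""
    if not payload.startswith(b"%PDF"):
        raise PDFError("missing %PDF header")
    if b"%%EOF" not in payload:
        raise PDFError("truncated PDF (no %%EOF)")
    if b"/Encrypt" in payload:
        raise PDFError("encrypted PDF")
    lines: list[str] = []
    for m in re.finditer(rb"stream\r?\n(.*?)endstream", payload, re.S):
        body = m.group(1)
        if b"BT" not in body:
            continue
        if b"\x00" in body:
            raise PDFError("compressed/binary content stream not supported")
        for sm in _STRING_RE.finditer(body):
            s = _unescape(sm.group(0)[1:-1].decode("latin-1"))
            if s:
                lines.append(s)
    return lines


def write_pdf(lines: list[str]) -> bytes:
    """Emit a minimal valid one-page PDF showing each line of text."""

    def esc(s: str) -> str:
        return s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")

    ops = ["BT", "/F1 10 Tf", "50 750 Td"]
    for i, line in enumerate(lines):
        if i:
            ops.append("0 -14 Td")
        ops.append(f"({esc(line)}) Tj")
    ops.append("ET")
    content = "\n".join(ops).encode("latin-1", "replace")

    objs = [
        b"<< /Type /Catalog /Pages 2 0 R >>",
        b"<< /Type /Pages /Kids [3 0 R] /Count 1 >>",
        b"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 612 792] "
        b"/Resources << /Font << /F1 4 0 R >> >> /Contents 5 0 R >>",
        b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>",
        b"<< /Length %d >>\nstream\n%s\nendstream" % (len(content), content),
    ]
    out = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, obj in enumerate(objs, start=1):
        offsets.append(len(out))
        out += b"%d 0 obj\n%s\nendobj\n" % (i, obj)
    xref_pos = len(out)
    out += b"xref\n0 %d\n" % (len(objs) + 1)
    out += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        out += b"%010d 00000 n \n" % off
    out += b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n" % (
        len(objs) + 1,
        xref_pos,
    )
    return bytes(out)


def write_empty_pdf() -> bytes:
    """A valid PDF with zero pages (edge-case fixture)."""
    objs = [
        b"<< /Type /Catalog /Pages 2 0 R >>",
        b"<< /Type /Pages /Kids [] /Count 0 >>",
    ]
    out = bytearray(b"%PDF-1.4\n")
    offsets = []
    for i, obj in enumerate(objs, start=1):
        offsets.append(len(out))
        out += b"%d 0 obj\n%s\nendobj\n" % (i, obj)
    xref_pos = len(out)
    out += b"xref\n0 %d\n0000000000 65535 f \n" % (len(objs) + 1)
    for off in offsets:
        out += b"%010d 00000 n \n" % off
    out += b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n" % (len(objs) + 1, xref_pos)
    return bytes(out)
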