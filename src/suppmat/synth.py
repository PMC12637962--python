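"""Seeded, ground-truthed synthetic supplementary-material corpora.

Stands in for a real open-access corpus so every pipeline stage is testable
offline: emits genuine CSV/TSV, minimal OOXML spreadsheet/word/slide
containers, plain text, single-page text PDFs, and ZIP archives, with
per-file ground truth (media class, grids, category label) and exact
planted-failure counts. Fully deterministic per seed, including bytes on
disk.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _ooxml, _pdf
from .bioc import BioCDocument, BioCPassage, CellAnnotation, Table, document_from_parts
from .categorize import LabeledTableSet
from .embedding import DEFAULT_DIM, HashingEncoder, encode, linearize_table
from .extraction import SMFile

_FIXED_ZIP_DATE = (2000, 1, 1, 0, 0, 0)


@dataclass
class Category:
    label: str
    vocabulary: list[str]
    mean_shape: tuple[int, int] = (6, 4)


@dataclass
class CorpusSpec:
    n_articles: int = 20
    categories: list[Category] = field(default_factory=list)
    files_per_article: int | tuple[int, int] = 2
    failure_rate: float = 0.0
    archive_rate: float = 0.0
    pdf_rate: float = 0.15
    overlap_fraction: float = 0.0  # shared-vocabulary stress knob
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.categories:
            self.categories = default_categories(3, seed=self.seed)
        for rate in (self.failure_rate, self.archive_rate, self.pdf_rate, self.overlap_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0,1]")
        vocabs = [set(c.vocabulary) for c in self.categories]
        for i in range(len(vocabs)):
            for j in range(i + 1, len(vocabs)):
                inter = vocabs[i] & vocabs[j]
                if inter and self.overlap_fraction == 0.0:
                    raise ValueError(f"category vocabularies overlap: {sorted(inter)[:3]}...")


_DEFAULT_LABELS = [
    "Gene Expression Data",
    "Cohort and Patient Characteristics",
    "Functional Annotation and Pathway Analysis",
    "Genomic Mutation and Variant Data",
    "Metabolomics and Lipidomic Data",
    "Immune Response Data",
    "Survival Analysis",
    "Ecotoxicology Data",
    "Clinical Diagnostics Data",
    "Animal Model Phenotyping",
]


def default_categories(
    c: int, seed: int = 0, vocab_size: int = 60, overlap_fraction: float = 0.0
) -> list[Category]:
    """c categories with pairwise-disjoint pseudo-word vocabularies; an
    optional shared-token fraction for stress testing."""
    rng = np.random.default_rng(seed)
    shared = [f"shared{j:03d}" for j in range(int(vocab_size * overlap_fraction))]
    cats = []
    for i in range(c):
        own = [f"c{i}w{j:03d}" for j in range(vocab_size - len(shared))]
        label = _DEFAULT_LABELS[i % len(_DEFAULT_LABELS)]
        if i >= len(_DEFAULT_LABELS):
            label = f"{label} Series {i // len(_DEFAULT_LABELS) + 1}"
        shape = (int(rng.integers(4, 9)), int(rng.integers(3, 6)))
        cats.append(Category(label=label, vocabulary=own + shared, mean_shape=shape))
    return cats


@dataclass
class FileTruth:
    article_id: str
    filename: str
    media_class: str
    label: str
    corrupted: bool
    grids: list[list[list[str]]]
    n_paragraphs: int = 0


@dataclass
class GroundTruth:
    files: list[FileTruth] = field(default_factory=list)
    expected_converted: int = 0
    expected_failed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "expected_converted": self.expected_converted,
                "expected_failed": self.expected_failed,
                "files": [
                    {
                        "article_id": f.article_id,
                        "filename": f.filename,
                        "media_class": f.media_class,
                        "label": f.label,
                        "corrupted": f.corrupted,
                        "grids": f.grids,
                        "n_paragraphs": f.n_paragraphs,
                    }
                    for f in self.files
                ],
            },
            indent=1,
        )


def _random_grid(rng: np.random.Generator, vocab: list[str], shape: tuple[int, int]) -> list[list[str]]:
    n_rows = max(1, int(rng.integers(max(1, shape[0] - 2), shape[0] + 3)))
    n_cols = max(1, int(rng.integers(max(1, shape[1] - 1), shape[1] + 2)))
    return [
        [vocab[int(rng.integers(0, len(vocab)))] for _ in range(n_cols)]
        for _ in range(n_rows)
    ]


def _csv_bytes(grid: list[list[str]], delim: str) -> bytes:
    return ("\n".join(delim.join(row) for row in grid) + "\n").encode("utf-8")


def _xlsx_bytes(grid: list[list[str]]) -> bytes:
    import datetime

    import openpyxl

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "Sheet1"
    for row in grid:
        ws.append(row)
    fixed = datetime.datetime(2000, 1, 1)
    wb.properties.created = fixed
    wb.properties.modified = fixed
    buf = io.BytesIO()
    wb.save(buf)
    return buf.getvalue()


def _zip_bytes(members: list[tuple[str, bytes]]) -> bytes:
    out = io.BytesIO()
    with zipfile.ZipFile(out, "w") as zf:
        for name, data in members:
            info = zipfile.ZipInfo(name, date_time=_FIXED_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)
    return out.getvalue()


# file kinds cycled per article; corruptible kinds use zip/pdf containers
_KINDS = ("csv", "xlsx", "docx", "tsv", "txt", "pdf")


def generate_smfiles(spec: CorpusSpec) -> tuple[list[SMFile], GroundTruth]:
    """Generate the corpus in memory. Deterministic per spec.seed."""
    rng = np.random.default_rng(spec.seed)
    files: list[SMFile] = []
    truth = GroundTruth()
    c = len(spec.categories)

    plan: list[tuple[str, str, Category, str]] = []  # (article, filename, cat, kind)
    for a in range(spec.n_articles):
        article_id = f"PMC{9000000 + a}"
        cat = spec.categories[a % c]
        fpa = spec.files_per_article
        n_files = fpa if isinstance(fpa, int) else int(rng.integers(fpa[0], fpa[1] + 1))
        for fi in range(n_files):
            kind = _KINDS[(a + fi) % len(_KINDS)]
            if kind == "pdf" and rng.random() > spec.pdf_rate:
                kind = "csv"
            if spec.archive_rate > 0 and rng.random() < spec.archive_rate and kind in ("csv", "tsv"):
                kind = "zip"
            plan.append((article_id, f"supp_{fi + 1}.{kind}", cat, kind))

    n_corrupt = round(spec.failure_rate * len(plan))
    corruptible = [i for i, p in enumerate(plan) if p[3] in ("xlsx", "docx", "zip", "pdf")]
    # force enough container files to host the planted corruptions
    i = 0
    while len(corruptible) < n_corrupt and i < len(plan):
        if i not in corruptible:
            art, fn, cat, _ = plan[i]
            stem = fn.rsplit(".", 1)[0]
            plan[i] = (art, f"{stem}.xlsx", cat, "xlsx")
            corruptible.append(i)
        i += 1
    corrupt_idx = set(
        rng.choice(corruptible, size=n_corrupt, replace=False).tolist() if n_corrupt else []
    )

    for i, (article_id, filename, cat, kind) in enumerate(plan):
        corrupted = i in corrupt_idx
        grids: list[list[list[str]]] = []
        n_paragraphs = 0
        if kind in ("csv", "tsv"):
            grid = _random_grid(rng, cat.vocabulary, cat.mean_shape)
            payload = _csv_bytes(grid, "," if kind == "csv" else "\t")
            media = "delimited_text"
            grids = [grid]
        elif kind == "xlsx":
            grid = _random_grid(rng, cat.vocabulary, cat.mean_shape)
            payload = _xlsx_bytes(grid)
            media = "spreadsheet"
            grids = [grid]
        elif kind == "docx":
            paras = [
                " ".join(
                    cat.vocabulary[int(rng.integers(0, len(cat.vocabulary)))]
                    for _ in range(8)
                )
                for _ in range(2)
            ]
            grid = _random_grid(rng, cat.vocabulary, cat.mean_shape)
            payload = _ooxml.write_docx([("p", paras[0]), ("p", paras[1]), ("tbl", grid)])
            media = "word_processor"
            grids = [grid]
            n_paragraphs = 2
        elif kind == "txt":
            lines = [
                " ".join(
                    cat.vocabulary[int(rng.integers(0, len(cat.vocabulary)))]
                    for _ in range(6)
                )
                for _ in range(4)
            ]
            payload = ("\n".join(lines) + "\n").encode("utf-8")
            media = "plain_text"
            n_paragraphs = 4
        elif kind == "pdf":
            lines = [
                " ".join(
                    cat.vocabulary[int(rng.integers(0, len(cat.vocabulary)))]
                    for _ in range(5)
                )
                for _ in range(3)
            ]
            payload = _pdf.write_pdf(lines)
            media = "pdf"
            n_paragraphs = 3
        else:  # zip wrapping one CSV
            grid = _random_grid(rng, cat.vocabulary, cat.mean_shape)
            payload = _zip_bytes([("inner.csv", _csv_bytes(grid, ","))])
            media = "archive"
            grids = [grid]

        if corrupted:
            payload = payload[: min(len(payload), 20)]
        files.append(SMFile(article_id, filename, payload, media))
        truth.files.append(
            FileTruth(article_id, filename, media, cat.label, corrupted, grids, n_paragraphs)
        )
        if corrupted:
            truth.expected_failed += 1
        else:
            truth.expected_converted += 1
    return files, truth


def generate_corpus(spec: CorpusSpec, out_dir: str | Path) -> GroundTruth:
    """Write the corpus tree ``out_dir/article_id/filename`` + ground truth
    JSON. Byte-identical regeneration for a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files, truth = generate_smfiles(spec)
    for f in files:
        target = out / f.article_id
        target.mkdir(exist_ok=True)
        (target / f.filename).write_bytes(f.payload)
    (out / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    return truth


def load_corpus(corpus_dir: str | Path) -> list[SMFile]:
    root = Path(corpus_dir)
    out = []
    for article_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for fp in sorted(article_dir.iterdir()):
            out.append(SMFile(article_dir.name, fp.name, fp.read_bytes()))
    return out


def truth_tables(truth: GroundTruth) -> list[tuple[str, Table, str]]:
    """(table_key, Table, label) for every uncorrupted ground-truth grid."""
    out = []
    for f in truth.files:
        if f.corrupted:
            continue
        for gi, grid in enumerate(f.grids, start=1):
            key = f"{f.article_id}/{f.filename}#T{gi}"
            out.append((key, Table.from_rows(f"T{gi}", grid), f.label))
    return out


def make_labeled_seed(
    truth: GroundTruth,
    fraction: float,
    seed: int = 0,
    encoder=None,
    max_chars: int | None = 4000,
) -> LabeledTableSet:
    """Stratified per-category sample of ground-truth tables with their true
    labels, embedded with the given encoder (default hashing fixture)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    encoder = encoder or HashingEncoder(DEFAULT_DIM)
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[tuple[str, Table]]] = {}
    for key, table, label in truth_tables(truth):
        by_label.setdefault(label, []).append((key, table))
    ids: list[str] = []
    vecs: list[np.ndarray] = []
    labels: list[str] = []
    for label in sorted(by_label):
        pool = by_label[label]
        n_take = round(fraction * len(pool))
        if n_take == 0:
            raise ValueError(f"fraction {fraction} yields 0 tables for {label!r}")
        chosen = rng.choice(len(pool), size=n_take, replace=False)
        for idx in sorted(chosen.tolist()):
            key, table = pool[idx]
            ids.append(key)
            vecs.append(encode(encoder, linearize_table(table, max_chars=max_chars)))
            labels.append(label)
    return LabeledTableSet(ids, np.vstack(vecs), labels)


# ---------------------------------------------------------------------------
# randomized BioC collections (codec round-trip fixtures)

_CELL_ALPHABET = ["gene", "p=0.01", "7.5", "", "fold\tchange", "multi\nline", "α-value", "x|y"]


def make_random_collection(seed: int, n_docs: int = 50) -> list[BioCDocument]:
    """Randomized valid documents exercising captions, empty cells, unicode,
    embedded tabs/newlines, and unknown infons."""
    rng = np.random.default_rng(seed)
    docs = []
    for di in range(n_docs):
        parts: list[tuple[str, object]] = []
        n_parts = int(rng.integers(1, 5))
        ti = 0
        for pi in range(n_parts):
            if rng.random() < 0.55:
                ti += 1
                n_rows = int(rng.integers(0, 5))
                n_cols = int(rng.integers(1, 5)) if n_rows else 0
                cells = [
                    _CELL_ALPHABET[int(rng.integers(0, len(_CELL_ALPHABET)))]
                    for _ in range(n_rows * n_cols)
                ]
                caption = f"Caption {di}.{ti}" if rng.random() < 0.5 else None
                sheet = f"Sheet{ti}" if rng.random() < 0.3 else None
                parts.append(
                    ("table", Table(f"T{ti}", n_rows, n_cols, cells, caption, sheet))
                )
            else:
                parts.append(("paragraph", f"paragraph {di}.{pi} of text"))
        doc = document_from_parts(
            f"PMC{1000 + di}/file_{di}.xlsx",
            "spreadsheet",
            parts,
            infons={"custom_key": f"value-{di}", "conversion_status": "ok"},
        )
        docs.append(doc)
    return docs
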