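"""Searchable index over categorized table embeddings.

All rankings are exact brute-force cosine — no approximate shortcuts — and
deterministic: ties break on the lexicographic entry key
(article_id, filename, table_id).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .bioc import BioCDocument, tables_of, write_bioc_json
from .categorize import CategorizedSet, ClusterModel, assign_category, load_code_registry
from .embedding import Encoder, encode, linearize_table

EntryKey = tuple[str, str, str]  # (article_id, filename, table_id)

INDEX_FORMAT_VERSION = "1"
MAX_FETCH_IDS = 50
ATTACHMENT_THRESHOLD_BYTES = 5 * 1024 * 1024
DEFAULT_NEIGHBORS = 1000


class UnknownCodeError(ValueError):
    pass


class NotFoundError(KeyError):
    pass


@dataclass
class IndexEntry:
    article_id: str
    filename: str
    table_id: str
    vector: np.ndarray
    code: str
    n_rows: int
    n_cols: int

    @property
    def key(self) -> EntryKey:
        return (self.article_id, self.filename, self.table_id)


@dataclass
class NeighborList:
    owner: EntryKey
    neighbors: list[tuple[EntryKey, float]]  # similarity-descending


@dataclass
class RankedResult:
    article_id: str
    best_table: EntryKey
    score: float


def _split_doc_id(doc_id: str) -> tuple[str, str]:
    article_id, _, filename = doc_id.partition("/")
    return article_id, filename


def build_index(
    corpus: list[BioCDocument],
    encoder: Encoder,
    model: ClusterModel,
    categorized: CategorizedSet,
    max_chars: int | None = 4000,
) -> list[IndexEntry]:
    """One entry per table passage, categorized by 1-NN against the seed set;
    deterministic (article_id, filename, table_id) order."""
    if categorized.vectors.shape[1] != encoder.d:
        raise ValueError(
            f"encoder dimension {encoder.d} != model dimension {categorized.vectors.shape[1]}"
        )
    entries: list[IndexEntry] = []
    for doc in corpus:
        article_id, filename = _split_doc_id(doc.doc_id)
        for table in tables_of(doc):
            vec = encode(encoder, linearize_table(table, max_chars=max_chars))
            code, _sim = assign_category(vec, categorized, tau=model.tau)
            entries.append(
                IndexEntry(article_id, filename, table.table_id, vec, code, table.n_rows, table.n_cols)
            )
    entries.sort(key=lambda e: e.key)
    return entries


def _similarity_matrix(entries: list[IndexEntry]) -> np.ndarray:
    M = np.vstack([e.vector for e in entries])
    norms = np.linalg.norm(M, axis=1)
    norms[norms == 0] = 1.0
    U = M / norms[:, None]
    return U @ U.T


def precompute_neighbors(
    entries: list[IndexEntry], N: int = DEFAULT_NEIGHBORS
) -> dict[EntryKey, NeighborList]:
    """Exact top-min(N, total-1) cosine neighbors per entry; self excluded;
    ties broken by entry key."""
    if not entries:
        raise ValueError("index is empty")
    sims = _similarity_matrix(entries)
    keys = [e.key for e in entries]
    out: dict[EntryKey, NeighborList] = {}
    for i, e in enumerate(entries):
        order = sorted(
            (j for j in range(len(entries)) if j != i),
            key=lambda j: (-sims[i, j], keys[j]),
        )[:N]
        out[e.key] = NeighborList(e.key, [(keys[j], float(sims[i, j])) for j in order])
    return out


def valid_codes(entries: list[IndexEntry]) -> set[str]:
    return set(load_code_registry().values()) | {e.code for e in entries} | {"OTHR"}


def search_by_query(
    entries: list[IndexEntry],
    encoder: Encoder,
    query_text: str,
    code: str,
    top_n: int = 10,
) -> list[RankedResult]:
    """Type-filtered cosine ranking: keep entries of the requested code,
    score each article by the max cosine over its matching tables."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    codes = valid_codes(entries)
    if code not in codes:
        raise UnknownCodeError(f"unknown code {code!r}; valid codes: {sorted(codes)}")
    qv = encode(encoder, query_text)
    nq = np.linalg.norm(qv)
    best: dict[str, tuple[float, EntryKey]] = {}
    for e in entries:
        if e.code != code:
            continue
        ne = np.linalg.norm(e.vector)
        sim = float(e.vector @ qv / (ne * nq)) if ne > 0 and nq > 0 else 0.0
        cur = best.get(e.article_id)
        if cur is None or sim > cur[0] or (sim == cur[0] and e.key < cur[1]):
            best[e.article_id] = (sim, e.key)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [RankedResult(a, key, s) for a, (s, key) in ranked[:top_n]]


def search_by_table(
    entries: list[IndexEntry],
    neighbors: dict[EntryKey, NeighborList],
    article_id: str,
    filename: str,
    limit: int = DEFAULT_NEIGHBORS,
) -> list[tuple[EntryKey, float]]:
    """Union of the file's tables' neighbor lists, deduplicated by max
    similarity, similarity-descending, truncated to ``limit``."""
    own = [e for e in entries if e.article_id == article_id and e.filename == filename]
    if not own:
        raise NotFoundError(f"no indexed tables for {article_id}/{filename}")
    merged: dict[EntryKey, float] = {}
    for e in own:
        for key, sim in neighbors[e.key].neighbors:
            if key not in merged or sim > merged[key]:
                merged[key] = sim
    ranked = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:limit]


# ---------------------------------------------------------------------------
# BioC fetch


@dataclass
class FetchResult:
    found: dict[str, list[BioCDocument]]
    missing: list[str]
    body: str  # serialized BioC-JSON of all found documents
    attachment: bool = False

    @property
    def size_bytes(self) -> int:
        return len(self.body.encode("utf-8"))


def fetch_sm(corpus_store: dict[str, list[BioCDocument]], ids: list[str]) -> FetchResult:
    """All converted documents for up to 50 article ids; oversize responses
    are flagged as attachments; unknown ids yield per-id markers."""
    if not 1 <= len(ids) <= MAX_FETCH_IDS:
        raise ValueError(f"between 1 and {MAX_FETCH_IDS} ids per request (got {len(ids)})")
    found: dict[str, list[BioCDocument]] = {}
    missing: list[str] = []
    for aid in ids:
        if aid in corpus_store:
            found[aid] = corpus_store[aid]
        else:
            missing.append(aid)
    docs = [d for aid in sorted(found) for d in found[aid]]
    body = write_bioc_json(docs)
    result = FetchResult(found=found, missing=missing, body=body)
    result.attachment = result.size_bytes > ATTACHMENT_THRESHOLD_BYTES
    return result


# ---------------------------------------------------------------------------
# persistence (JSON, versioned; rebuild-from-corpus always possible)


def save_index(
    path: str,
    entries: list[IndexEntry],
    neighbors: dict[EntryKey, NeighborList] | None = None,
) -> None:
    obj = {
        "format_version": INDEX_FORMAT_VERSION,
        "d": int(entries[0].vector.shape[0]) if entries else 0,
        "entries": [
            {
                "article_id": e.article_id,
                "filename": e.filename,
                "table_id": e.table_id,
                "code": e.code,
                "n_rows": e.n_rows,
                "n_cols": e.n_cols,
                "vector": [float(x) for x in e.vector],
            }
            for e in entries
        ],
        "neighbors": {
            "|".join(k): [["|".join(nk), s] for nk, s in nl.neighbors]
            for k, nl in (neighbors or {}).items()
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh)


def load_index(path: str) -> tuple[list[IndexEntry], dict[EntryKey, NeighborList]]:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(f"unsupported index format {obj.get('format_version')!r}")
    entries = [
        IndexEntry(
            e["article_id"],
            e["filename"],
            e["table_id"],
            np.asarray(e["vector"], dtype=np.float64),
            e["code"],
            e["n_rows"],
            e["n_cols"],
        )
        for e in obj["entries"]
    ]
    neighbors: dict[EntryKey, NeighborList] = {}
    for k, lst in obj.get("neighbors", {}).items():
        key: EntryKey = tuple(k.split("|"))  # type: ignore[assignment]
        neighbors[key] = NeighborList(key, [(tuple(nk.split("|")), float(s)) for nk, s in lst])  # type: ignore[misc]
    return entries, neighbors
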