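"""Pluggable text encoders, table linearization, and cosine geometry.

The default :class:`HashingEncoder` is a deterministic bag-of-tokens
feature hasher (stable across sessions — it hashes with BLAKE2, not
Python's randomized ``hash``). A production biomedical sentence encoder can
be plugged in through the same protocol; nothing in the package requires
one.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .bioc import Table

DEFAULT_DIM = 768

_TOKEN_RE = re.compile(r"[^0-9a-zA-Z]+")


class Encoder(Protocol):
    name: str
    d: int

    def encode(self, text: str) -> np.ndarray: ...


@dataclass
class HashingEncoder:
    """Deterministic fixture encoder: lowercase tokens hashed into ``d``
    signed buckets, L2-normalized. Order-free by construction."""

    d: int = DEFAULT_DIM
    name: str = "hashing"

    def encode(self, text: str) -> np.ndarray:
        vec = np.zeros(self.d, dtype=np.float64)
        for token in _TOKEN_RE.split(text.lower()):
            if not token:
                continue
            digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
            h = int.from_bytes(digest, "big")
            bucket = (h >> 1) % self.d
            sign = 1.0 if h & 1 else -1.0
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


@dataclass
class EncoderPair:
    """Separate query/table encoder slots; defaults to one shared encoder."""

    table_encoder: Encoder
    query_encoder: Encoder

    @classmethod
    def shared(cls, encoder: Encoder) -> "EncoderPair":
        return cls(encoder, encoder)


_REGISTRY: dict[str, type] = {"hashing": HashingEncoder}


def register_encoder(name: str, factory: type) -> None:
    _REGISTRY[name] = factory


def get_encoder(name: str, d: int = DEFAULT_DIM) -> Encoder:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown encoder {name!r}; registered: {sorted(_REGISTRY)}")
    return factory(d=d)


def linearize_table(table: Table, max_chars: int | None = None) -> str:
    """Caption + row-major cells joined by single spaces, rows joined by
    " | ", truncated at a cell boundary at ``max_chars``."""
    pieces: list[str] = []
    length = 0

    def try_append(sep: str, token: str) -> bool:
        nonlocal length
        add = (len(sep) if pieces else 0) + len(token)
        if max_chars is not None and length + add > max_chars:
            return False
        if pieces:
            pieces.append(sep)
        pieces.append(token)
        length += add
        return True

    if table.caption:
        if not try_append(" ", table.caption):
            return ""
    for i, row in enumerate(table.rows()):
        for j, cell in enumerate(row):
            sep = " | " if (j == 0 and i > 0) else " "
            if not try_append(sep, cell):
                return "".join(pieces)
    return "".join(pieces)


def encode(encoder: Encoder, text: str) -> np.ndarray:
    """Encode whitespace-normalized text; empty text gives the zero vector."""
    normalized = " ".join(text.split())
    if not normalized:
        return np.zeros(encoder.d, dtype=np.float64)
    vec = np.asarray(encoder.encode(normalized), dtype=np.float64)
    if vec.shape != (encoder.d,):
        raise ValueError(f"encoder {encoder.name!r} returned shape {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite embedding values")
    return vec


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u,v)/(|u||v|); 0 by convention when either norm is zero."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))
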