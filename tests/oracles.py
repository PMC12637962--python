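"""Independent brute-force oracles kept deliberately separate from the
implementations they check."""

from __future__ import annotations

import itertools
import math

import numpy as np


def exhaustive_kmeans_wcss(X: np.ndarray, k: int) -> float:
    """Optimal WCSS by enumerating every partition of n points into exactly
    k non-empty clusters. Feasible for n <= 8."""
    n = len(X)
    best = math.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) != k:
            continue
        total = 0.0
        for c in range(k):
            members = X[[i for i in range(n) if assignment[i] == c]]
            centroid = members.mean(axis=0)
            total += float(((members - centroid) ** 2).sum())
        best = min(best, total)
    return best


def brute_cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = math.sqrt(float(sum(x * x for x in u)))
    nv = math.sqrt(float(sum(x * x for x in v)))
    if nu == 0 or nv == 0:
        return 0.0
    return float(sum(a * b for a, b in zip(u, v))) / (nu * nv)


def brute_assign(query: np.ndarray, ids: list[str], vectors: np.ndarray, codes: list[str], tau: float):
    """Double-loop 1-NN with smallest-id tie-breaking."""
    best_sim = -2.0
    best_id = None
    best_code = None
    for tid, vec, code in sorted(zip(ids, vectors, codes), key=lambda t: t[0]):
        sim = brute_cosine(query, vec)
        if sim > best_sim:
            best_sim, best_id, best_code = sim, tid, code
    if best_sim < tau:
        return "OTHR", best_sim
    return best_code, best_sim


def brute_neighbors(keys: list, vectors: np.ndarray, i: int, N: int):
    """Exact top-N cosine neighbors of entry i, ties by key, self excluded."""
    sims = [
        (-brute_cosine(vectors[i], vectors[j]), keys[j], j)
        for j in range(len(keys))
        if j != i
    ]
    sims.sort()
    return [(key, -negsim) for negsim, key, _ in sims[:N]]


def brute_query_rank(entries, qv: np.ndarray, code: str, top_n: int):
    """Filter to code, max-cosine per article, rank descending (ties by id)."""
    per_article: dict[str, tuple[float, tuple]] = {}
    for e in entries:
        if e.code != code:
            continue
        sim = brute_cosine(e.vector, qv)
        cur = per_article.get(e.article_id)
        if cur is None or sim > cur[0] or (sim == cur[0] and e.key < cur[1]):
            per_article[e.article_id] = (sim, e.key)
    ranked = sorted(per_article.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [(a, key, s) for a, (s, key) in ranked[:top_n]]
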