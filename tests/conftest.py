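import numpy as np
import pytest

from suppmat.embedding import HashingEncoder
from suppmat.synth import Category, CorpusSpec, default_categories, generate_smfiles


@pytest.fixture(scope="session")
def encoder():
    return HashingEncoder(768)


@pytest.fixture(scope="session")
def small_encoder():
    return HashingEncoder(64)


def tight_categories(c: int, seed: int) -> list[Category]:
    """Disjoint-vocabulary categories with large tables (tight clusters)."""
    return [Category(b.label, b.vocabulary, (12, 6)) for b in default_categories(c, seed=seed)]


@pytest.fixture(scope="session")
def corpus_100():
    """100 files, 5 planted corruptions, mixed formats incl. archives."""
    spec = CorpusSpec(
        n_articles=25,
        categories=default_categories(5, seed=3),
        files_per_article=4,
        failure_rate=0.05,
        archive_rate=0.2,
        seed=3,
    )
    return generate_smfiles(spec)


def gaussian_blobs(k: int, n_per: int = 30, d: int = 8, sigma: float = 0.05, seed: int = 0):
    """Well-separated Gaussian blobs: centers are random unit directions with
    pairwise distance >= 0.9 (near-unit separation, sigma=0.05 noise)."""
    rng = np.random.default_rng(seed)
    while True:
        centers = rng.normal(size=(k, d))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        if k == 1:
            break
        dm = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(dm, np.inf)
        if dm.min() >= 0.9:
            break
    return np.vstack([c + sigma * rng.normal(size=(n_per, d)) for c in centers])


def truth_key_for_doc(doc_id: str, table_id: str) -> str:
    """Ground-truth table keys name the on-disk file; archive members fold
    back onto their container."""
    key = f"{doc_id}#{table_id}"
    return key.replace("/inner.csv", "")
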