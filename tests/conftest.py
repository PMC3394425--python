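import numpy as np
import pytest

from ldarank.corpus import corpus_from_token_ids, load_stopwords


@pytest.fixture(scope="session")
def stopwords():
    return load_stopwords()


@pytest.fixture
def tiny_corpus():
    """Three short passages over a 4-word vocabulary (9 tokens total)."""
    token_ids = [[0, 1, 0, 2], [2, 3, 3], [1, 0, 2]]
    words = [f"w{i}" for i in range(4)]
    return corpus_from_token_ids("q1", token_ids, words), token_ids


def random_importance_rows(rng, n, T):
    """Random passage-id -> importance-row mapping for rerank tests."""
    pids = [f"p{i}" for i in range(n)]
    return pids, {p: rng.random(T) for p in pids}
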