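"""Passage preprocessing: tokenization, filtering, and corpus construction.

A corpus holds the retrieved passages of a single query.  Preprocessing
follows simple IR conventions: lower-case everything, split on any
non-alphanumeric character (hyphens, slashes, parentheses, ...), drop
stop words, and drop words that occur exactly once within a passage.
Passages emptied by filtering are kept: they still participate in
re-ranking, they just contribute no tokens to the topic model.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field

import numpy as np

_SPLIT = re.compile(r"[^0-9a-z]+")


class CorpusError(ValueError):
    """Raised for malformed passage collections (duplicate ids or ranks)."""


@dataclass
class Passage:
    """One retrieved text unit of a query's ranked list.

    ``tokens`` holds word ids into the parent corpus vocabulary and is
    filled by :func:`build_corpus`.
    """

    query_id: str
    passage_id: str
    rank: int
    score: float
    text: str
    tokens: list[int] = field(default_factory=list)

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """Tokenized passage collection for one query.

    ``vocabulary`` maps word string -> word id; ``words`` is the inverse.
    Passage order equals baseline rank order.
    """

    query_id: str
    passages: list[Passage]
    vocabulary: dict[str, int]
    words: list[str]

    @property
    def D(self) -> int:
        return len(self.passages)

    @property
    def V(self) -> int:
        return len(self.words)

    @property
    def n_tokens(self) -> int:
        return sum(p.n_tokens for p in self.passages)

    def flat_tokens(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (doc_of, word_of) int32 arrays, one entry per token."""
        doc_of = np.empty(self.n_tokens, dtype=np.int32)
        word_of = np.empty(self.n_tokens, dtype=np.int32)
        i = 0
        for d, p in enumerate(self.passages):
            for w in p.tokens:
                doc_of[i] = d
                word_of[i] = w
                i += 1
        return doc_of, word_of

    def doc_lengths(self) -> np.ndarray:
        return np.array([p.n_tokens for p in self.passages], dtype=np.int64)


def tokenize(text: str) -> list[str]:
    """Lower-case ``text`` and split it on every non-alphanumeric character.

    Empty fragments are discarded; token order is preserved.
    """
    return [t for t in _SPLIT.split(text.lower()) if t]


def filter_tokens(tokens: list[str], stopwords: set[str]) -> list[str]:
    """Drop stop words, then drop per-passage singletons.

    A singleton is a token whose frequency *within this passage* (after
    stop-word removal) is exactly 1.  Relative order of survivors is kept.
    """
    kept = [t for t in tokens if t not in stopwords]
    counts: dict[str, int] = {}
    for t in kept:
        counts[t] = counts.get(t, 0) + 1
    return [t for t in kept if counts[t] >= 2]


def load_stopwords(path: str | None = None) -> set[str]:
    """Load a stop-word file (one lower-case token per line).

    With no path, the bundled general-English list is used.
    """
    if path is None:
        ref = importlib.resources.files("ldarank.data") / "stopwords.txt"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return {line.strip() for line in text.splitlines() if line.strip()}


def build_corpus(
    raw_passages: list[tuple[str, str, int, float, str]],
    stopwords: set[str],
) -> Corpus:
    """Tokenize and filter raw passages and assemble the corpus.

    ``raw_passages`` rows are (query_id, passage_id, rank, score, text),
    all sharing one query id.  The vocabulary covers surviving tokens
    only, so no entry is unused.
    """
    if not raw_passages:
        raise CorpusError("empty passage list")
    qid = raw_passages[0][0]
    seen_ids: set[str] = set()
    seen_ranks: set[int] = set()
    vocabulary: dict[str, int] = {}
    words: list[str] = []
    passages: list[Passage] = []
    for query_id, pid, rank, score, text in raw_passages:
        if query_id != qid:
            raise CorpusError(f"mixed query ids: {qid!r} vs {query_id!r}")
        if pid in seen_ids:
            raise CorpusError(f"duplicate passage id {pid!r} in query {qid!r}")
        if rank in seen_ranks:
            raise CorpusError(f"duplicate rank {rank} in query {qid!r}")
        seen_ids.add(pid)
        seen_ranks.add(rank)
        surviving = filter_tokens(tokenize(text), stopwords)
        ids = []
        for w in surviving:
            if w not in vocabulary:
                vocabulary[w] = len(words)
                words.append(w)
            ids.append(vocabulary[w])
        passages.append(Passage(qid, pid, rank, float(score), text, ids))
    passages.sort(key=lambda p: p.rank)
    ranks = [p.rank for p in passages]
    if ranks != list(range(1, len(ranks) + 1)):
        raise CorpusError(f"ranks not contiguous from 1 in query {qid!r}: {ranks}")
    return Corpus(qid, passages, vocabulary, words)


def corpus_from_token_ids(
    query_id: str,
    token_ids: list[list[int]],
    words: list[str],
    scores: list[float] | None = None,
    passage_ids: list[str] | None = None,
) -> Corpus:
    """Assemble a corpus directly from pre-tokenized word-id sequences.

    Used by the synthetic generator, where tokens come from a known
    topic model rather than from raw text.  Vocabulary entries may be
    unused here (the generative vocabulary is fixed a priori).
    """
    D = len(token_ids)
    if passage_ids is None:
        passage_ids = [f"p{i + 1:04d}" for i in range(D)]
    if scores is None:
        scores = [float(D - i) for i in range(D)]
    vocabulary = {w: i for i, w in enumerate(words)}
    passages = [
        Passage(query_id, passage_ids[i], i + 1, scores[i],
                " ".join(words[t] for t in token_ids[i]), list(token_ids[i]))
        for i in range(D)
    ]
    return Corpus(query_id, passages, vocabulary, list(words))
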