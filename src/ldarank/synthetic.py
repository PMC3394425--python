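"""Synthetic corpora and retrieval scenarios with known ground truth.

Two generators make the whole pipeline testable without any external
collection.  ``generate_lda_corpus`` draws a corpus from the LDA
generative process itself (φ* rows from a symmetric Dirichlet(β*),
θ* rows from a symmetric Dirichlet(α*), then the topic-then-word draw
per token) and returns the ground-truth parameters alongside, so
parameter recovery and model selection can be checked directly.

``generate_retrieval_scenario`` builds the redundancy situation that
diversity re-ranking targets: groups of passages sharing one dominant
generating topic sit adjacently at the top of the baseline ranking
(the worst case for aspect coverage), followed by topically mixed
passages.  Because the fixture is generated from topics, "aspect =
latent topic" is literally true: the gold aspect set of a passage is
the set of topics holding at least ``label_threshold`` of its θ* mass.
All passages are relevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, corpus_from_token_ids
from .evaluation import GoldAspects
from .rerank import Ranking

DOMINANT_MASS = 0.8       # minimum θ* mass on a redundancy group's shared topic
LABEL_THRESHOLD = 0.2     # θ* mass for a topic to count as a gold aspect


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generative process.

    ``doc_length`` is the token count per passage, exact by default or
    a Poisson mean with ``poisson_lengths``.  ``redundancy_groups`` is
    a list of (group size, shared dominant topic) pairs; group members
    are placed adjacently at the head of the baseline ranking.
    """

    T_true: int
    V: int
    D: int
    doc_length: int = 60
    alpha_true: float = 2.0
    beta_true: float = 0.05
    redundancy_groups: tuple[tuple[int, int], ...] = ()
    poisson_lengths: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_true > self.V:
            raise ValueError("need T_true <= V")
        if sum(s for s, _ in self.redundancy_groups) > self.D:
            raise ValueError("redundancy groups exceed D")
        for _, t in self.redundancy_groups:
            if not 0 <= t < self.T_true:
                raise ValueError(f"group topic {t} outside [0, T_true)")


def _word_strings(V: int) -> list[str]:
    return [f"w{i:04d}" for i in range(V)]


def _draw_tokens(rng, theta_row, phi, length: int) -> list[int]:
    topics = rng.choice(len(theta_row), size=length, p=theta_row)
    return [int(rng.choice(phi.shape[1], p=phi[t])) for t in topics]


def _lengths(rng, spec: SyntheticSpec) -> np.ndarray:
    if spec.poisson_lengths:
        return np.maximum(1, rng.poisson(spec.doc_length, size=spec.D))
    return np.full(spec.D, spec.doc_length, dtype=np.int64)


def generate_lda_corpus(spec: SyntheticSpec) -> tuple[Corpus, np.ndarray, np.ndarray]:
    """Draw (corpus, θ*, φ*) from the LDA generative process, seeded."""
    rng = np.random.default_rng(spec.seed)
    phi = rng.dirichlet([spec.beta_true] * spec.V, size=spec.T_true)
    theta = rng.dirichlet([spec.alpha_true] * spec.T_true, size=spec.D)
    lengths = _lengths(rng, spec)
    token_ids = [_draw_tokens(rng, theta[d], phi, int(lengths[d])) for d in range(spec.D)]
    corpus = corpus_from_token_ids(f"synth{spec.seed}", token_ids, _word_strings(spec.V))
    return corpus, theta, phi


def _group_theta_row(rng, T: int, topic: int, alpha: float) -> np.ndarray:
    """θ* row with mass >= DOMINANT_MASS concentrated on ``topic``."""
    mass = rng.uniform(DOMINANT_MASS, 0.95)
    row = np.empty(T)
    if T == 1:
        row[:] = 1.0
        return row
    rest = rng.dirichlet([alpha] * (T - 1)) * (1.0 - mass)
    row[:topic] = rest[:topic]
    row[topic] = mass
    row[topic + 1 :] = rest[topic:]
    return row


def generate_retrieval_scenario(
    spec: SyntheticSpec,
) -> tuple[Ranking, Corpus, GoldAspects, np.ndarray, np.ndarray]:
    """Build (baseline ranking, corpus, gold aspects, θ*, φ*).

    Redundancy-group members occupy the top ranks adjacently, in group
    order; the remaining passages follow with Dirichlet-mixed topics.
    """
    if not spec.redundancy_groups:
        raise ValueError("scenario needs at least one redundancy group")
    rng = np.random.default_rng(spec.seed)
    phi = rng.dirichlet([spec.beta_true] * spec.V, size=spec.T_true)
    theta = np.empty((spec.D, spec.T_true))
    d = 0
    for size, topic in spec.redundancy_groups:
        for _ in range(size):
            theta[d] = _group_theta_row(rng, spec.T_true, topic, spec.alpha_true)
            d += 1
    while d < spec.D:
        theta[d] = rng.dirichlet([spec.alpha_true] * spec.T_true)
        d += 1
    lengths = _lengths(rng, spec)
    token_ids = [_draw_tokens(rng, theta[i], phi, int(lengths[i])) for i in range(spec.D)]
    qid = f"scen{spec.seed}"
    corpus = corpus_from_token_ids(qid, token_ids, _word_strings(spec.V))
    pids = [p.passage_id for p in corpus.passages]
    relevant: dict[str, set[str]] = {}
    for i, pid in enumerate(pids):
        labels = {f"t{t}" for t in range(spec.T_true) if theta[i, t] >= LABEL_THRESHOLD}
        if not labels:  # every passage is relevant; fall back to the dominant topic
            labels = {f"t{int(theta[i].argmax())}"}
        relevant[pid] = labels
    universe = set().union(*relevant.values())
    gold = GoldAspects(qid, relevant, universe)
    return Ranking(qid, pids), corpus, gold, theta, phi
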