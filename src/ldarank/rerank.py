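"""Slide-window re-ranking of a baseline ranked list in importance space.

Both algorithms work on a window of the top N not-yet-placed passages
of the baseline ranking R, so a passage can never jump far ahead of its
relevance-based position.  The first output passage is the window
member with the largest aspect coverage.  After that:

``nwin``
    greedy global selection — repeatedly score every window member by
    its mean distance to all passages already placed in S and move the
    farthest one to S.  The window slides down R as passages leave it.

``nwin_group``
    local reordering — split the remaining R into consecutive N-size
    groups; within each group, sort members by mean distance to the
    current S (S frozen for the whole group) in descending order and
    append the whole group.  Each group keeps its block of positions,
    so the output stays close to the baseline order.

Distances between passages are Euclidean distances between their rows
of the importance matrix Θ, optionally weighted per aspect by the mean
topic weight μ_t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class Ranking:
    """Ordered passage ids for one query (baseline R or re-ranked S)."""

    query_id: str
    order: list[str]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError(f"duplicate passage ids in ranking for {self.query_id!r}")


@dataclass(frozen=True)
class RerankConfig:
    N: int = 5
    algorithm: str = "nwin_group"
    metric: str = "plain"
    top_k: int = 100

    def __post_init__(self) -> None:
        if self.N < 1 or self.top_k < 1:
            raise ValueError("N and top_k must be positive")
        if self.algorithm not in ("nwin", "nwin_group"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.metric not in ("plain", "weighted"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.top_k < self.N:
            log.warning("top_k=%d < window size N=%d", self.top_k, self.N)


def distance_plain(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance between two importance vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(((u - v) ** 2).sum()))


def distance_weighted(u: np.ndarray, v: np.ndarray, mu: np.ndarray) -> float:
    """Euclidean distance with per-aspect weights μ_t.

    Aspects that carry more of the collection's topic mass count more
    toward the distinction between two passages.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    if u.shape != v.shape or u.shape != mu.shape:
        raise ValueError(f"length mismatch: {u.shape}, {v.shape}, {mu.shape}")
    return float(np.sqrt((mu * (u - v) ** 2).sum()))


def _make_distance(config: RerankConfig, mu: np.ndarray | None):
    if config.metric == "weighted":
        if mu is None:
            raise ValueError("weighted metric requires mu")
        return lambda u, v: distance_weighted(u, v, mu)
    return distance_plain


def select_first(order: list[str], N: int, rows: dict[str, np.ndarray]) -> str:
    """Passage with the largest aspect coverage among the top min(N, |R|).

    Ties break toward the smaller baseline rank (earlier position).
    """
    if not order:
        raise ValueError("empty ranking")
    window = order[: min(N, len(order))]
    best = window[0]
    best_cov = float(np.sum(rows[best]))
    for pid in window[1:]:
        cov = float(np.sum(rows[pid]))
        if cov > best_cov:
            best, best_cov = pid, cov
    return best


def rank_nwin(
    order: list[str],
    rows: dict[str, np.ndarray],
    config: RerankConfig,
    mu: np.ndarray | None = None,
) -> list[str]:
    """Greedy slide-window re-ranking (global selection)."""
    dist = _make_distance(config, mu)
    R = list(order)
    first = select_first(R, config.N, rows)
    R.remove(first)
    S = [first]
    while R:
        window = R[: min(config.N, len(R))]
        best_i = 0
        best_d = -np.inf
        for i, pid in enumerate(window):
            d = sum(dist(rows[pid], rows[s]) for s in S) / len(S)
            if d > best_d:
                best_i, best_d = i, d
        S.append(window[best_i])
        R.remove(window[best_i])
    return S


def rank_nwin_group(
    order: list[str],
    rows: dict[str, np.ndarray],
    config: RerankConfig,
    mu: np.ndarray | None = None,
) -> list[str]:
    """Group-wise slide-window re-ranking (local reordering).

    Group boundaries are laid down after the seed passage is removed;
    each group is sorted by mean distance to the S accumulated so far,
    descending, with ties keeping baseline order.
    """
    dist = _make_distance(config, mu)
    R = list(order)
    first = select_first(R, config.N, rows)
    R.remove(first)
    S = [first]
    for start in range(0, len(R), config.N):
        group = R[start : start + config.N]
        scored = [
            (-sum(dist(rows[pid], rows[s]) for s in S) / len(S), i, pid)
            for i, pid in enumerate(group)
        ]
        scored.sort()
        S.extend(pid for _, _, pid in scored)
    return S


_ALGORITHMS = {"nwin": rank_nwin, "nwin_group": rank_nwin_group}


def rerank(
    ranking: Ranking,
    rows: dict[str, np.ndarray],
    config: RerankConfig,
    mu: np.ndarray | None = None,
) -> Ranking:
    """Re-rank the top ``top_k`` passages of one query; the tail keeps
    its baseline order and is appended unchanged."""
    head = ranking.order[: config.top_k]
    tail = ranking.order[config.top_k :]
    algorithm = _ALGORITHMS[config.algorithm]
    new_head = algorithm(head, rows, config, mu)
    return Ranking(ranking.query_id, new_head + tail)


def rerank_run(
    rankings: dict[str, Ranking],
    models: dict[str, tuple[dict[str, np.ndarray], np.ndarray]],
    config: RerankConfig,
) -> dict[str, Ranking]:
    """Re-rank every query of a run.

    ``models`` maps query_id -> (importance rows by passage id, μ).  A
    query without a model is passed through unchanged with a warning.
    """
    out: dict[str, Ranking] = {}
    for qid, ranking in rankings.items():
        if qid not in models:
            log.warning("query %s: no importance model; passed through unchanged", qid)
            out[qid] = ranking
            continue
        rows, mu = models[qid]
        out[qid] = rerank(ranking, rows, config, mu)
    return out
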