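"""End-to-end per-query chain: preprocess → fit → transform → rerank → evaluate.

Per-query seeds are derived from the master seed and a stable hash of
the query id, so results do not depend on query order and the whole
run is reproducible under one seed.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import Corpus, build_corpus
from .evaluation import GoldAspects, evaluate_run, mean_over_queries
from .importance import ImportanceModel, fit_importance
from .lda import LdaConfig, TopicModel, ZeroTokenCorpusError, fit_lda, select_T, uniform_topic_model
from .rerank import Ranking, RerankConfig, rerank_run

log = logging.getLogger(__name__)


def query_seed(master_seed: int, query_id: str) -> int:
    """Stable per-query seed below 2**31."""
    return (master_seed + zlib.crc32(query_id.encode("utf-8"))) % (2**31)


@dataclass
class PipelineConfig:
    lda: LdaConfig
    rerank: RerankConfig
    T_grid: tuple[int, ...] = ()   # empty: use lda.T as a fixed topic count
    seed: int = 0


@dataclass
class QueryResult:
    query_id: str
    model: TopicModel
    importance: ImportanceModel
    reranked: Ranking
    evidence_curve: list[tuple[int, float]] = field(default_factory=list)


def fit_query(corpus: Corpus, config: PipelineConfig) -> tuple[TopicModel, list[tuple[int, float]]]:
    """Fit one query's topic model, selecting T on the grid if given."""
    seed = query_seed(config.seed, corpus.query_id)
    base = replace(config.lda, seed=seed)
    try:
        if config.T_grid:
            best_T, curve = select_T(corpus, list(config.T_grid), base)
            model = fit_lda(corpus, replace(base, T=best_T))
            return model, curve
        return fit_lda(corpus, base), []
    except ZeroTokenCorpusError:
        log.warning("query %s: empty after preprocessing; uniform topic model", corpus.query_id)
        return uniform_topic_model(corpus.D, base), []


def run_pipeline(
    corpora: dict[str, Corpus],
    rankings: dict[str, Ranking],
    config: PipelineConfig,
    gold: dict[str, GoldAspects] | None = None,
) -> dict:
    """Run the whole chain for every query; returns models, rankings and
    (when gold is supplied) a per-query evaluation of baseline vs re-ranked."""
    results: dict[str, QueryResult] = {}
    models: dict[str, tuple[dict[str, np.ndarray], np.ndarray]] = {}
    for qid, corpus in corpora.items():
        model, curve = fit_query(corpus, config)
        imp = fit_importance(model.theta)
        rows = {p.passage_id: imp.Theta[i] for i, p in enumerate(corpus.passages)}
        models[qid] = (rows, imp.mu)
        results[qid] = QueryResult(qid, model, imp, Ranking(qid, []), curve)
        log.info(
            "query %s: T=%d alpha=%.4f beta=%g log_evidence=%.2f",
            qid, model.config.T, model.config.alpha, model.config.beta, model.log_evidence,
        )
    reranked = rerank_run(rankings, models, config.rerank)
    for qid, r in reranked.items():
        if qid in results:
            results[qid].reranked = r
    out = {"queries": results, "reranked": reranked}
    if gold:
        base_eval = evaluate_run({q: r.order for q, r in rankings.items()}, gold)
        new_eval = evaluate_run({q: r.order for q, r in reranked.items()}, gold)
        gq = set(gold)
        out["evaluation"] = {
            "baseline": base_eval,
            "reranked": new_eval,
            "baseline_mean_aspect_ap": mean_over_queries(
                {q: v["aspect_ap"] for q, v in base_eval.items()}, gq),
            "reranked_mean_aspect_ap": mean_over_queries(
                {q: v["aspect_ap"] for q, v in new_eval.items()}, gq),
        }
    return out


def corpora_from_records(
    records: dict[str, list[tuple[str, str, int, float, str]]],
    stopwords: set[str],
) -> dict[str, Corpus]:
    return {qid: build_corpus(recs, stopwords) for qid, recs in records.items()}
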