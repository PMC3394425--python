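"""Aspect-level and document-level ranking evaluation.

Aspect AP implemented here is an operational variant of the genomics
aspect-retrieval measure: walking down the ranking, a passage is
*aspect-novel* iff it is relevant and carries at least one gold aspect
label not yet seen at an earlier rank; at each aspect-novel rank r the
precision (number of aspect-novel passages so far) / r is accumulated,
and the sum is normalized by the number of gold aspects for the query.
Relevant passages contributing no new aspect accumulate nothing, which
is what makes the measure reward diversity.  The value is not bounded
by 1 in general (a passage can introduce several aspects at once while
the normalizer counts aspects); it equals 1 exactly when ranks
1..|aspects| each introduce exactly one new aspect.

An alternative normalization — by the number of aspect-novel passages
instead of the number of aspects — is noted in the literature; the
aspect-count normalizer is the default here and every report records
the definition string so scores are never confused with official
trec-genomics numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

ASPECT_AP_DEFINITION = (
    "variant aspect AP: sum over aspect-novel ranks r of "
    "(#aspect-novel passages at <= r)/r, divided by |gold aspect set|; "
    "not the official trec-genomics character-level measure"
)


@dataclass
class GoldAspects:
    """Gold annotations for one query.

    ``relevant`` maps passage id -> non-empty set of aspect labels;
    passages absent from the mapping are non-relevant.
    """

    query_id: str
    relevant: dict[str, set[str]]
    aspect_universe: set[str]

    def __post_init__(self) -> None:
        for pid, labels in self.relevant.items():
            extra = labels - self.aspect_universe
            if extra:
                raise ValueError(
                    f"passage {pid!r} carries labels outside the aspect universe: {extra}"
                )


def aspect_average_precision(order: list[str], gold: GoldAspects) -> float:
    """Aspect-novelty average precision of one ranking (see module doc)."""
    if not gold.aspect_universe:
        raise ValueError(f"query {gold.query_id!r}: empty aspect universe")
    seen: set[str] = set()
    novel_count = 0
    acc = 0.0
    for r, pid in enumerate(order, start=1):
        labels = gold.relevant.get(pid)
        if labels and not labels <= seen:
            novel_count += 1
            acc += novel_count / r
            seen |= labels
    return acc / len(gold.aspect_universe)


def document_average_precision(order: list[str], relevant: set[str]) -> float:
    """Standard average precision over binary relevance; empty set → 0."""
    if not relevant:
        return 0.0
    hits = 0
    acc = 0.0
    for r, pid in enumerate(order, start=1):
        if pid in relevant:
            hits += 1
            acc += hits / r
    return acc / len(relevant)


def mean_over_queries(per_query: dict[str, float], gold_queries: set[str]) -> float:
    """Arithmetic mean over the gold queries; a query missing from the
    run contributes 0."""
    if not gold_queries:
        raise ValueError("no gold queries")
    return sum(per_query.get(q, 0.0) for q in gold_queries) / len(gold_queries)


def evaluate_run(
    rankings: dict[str, list[str]],
    gold: dict[str, GoldAspects],
) -> dict[str, dict[str, float]]:
    """Per-query aspect AP and document AP for every gold query."""
    report: dict[str, dict[str, float]] = {}
    for qid, g in gold.items():
        order = rankings.get(qid, [])
        report[qid] = {
            "aspect_ap": aspect_average_precision(order, g) if order else 0.0,
            "document_ap": document_average_precision(order, set(g.relevant)),
        }
    return report


def format_report(report: dict[str, dict[str, float]]) -> str:
    """Tab-separated report mirroring the genomics-track column order
    (Aspect, Passage2, Passage, Document); the character-level passage
    measures are out of scope and printed as n/a."""
    lines = [f"# {ASPECT_AP_DEFINITION}"]
    lines.append("query\tAspect\tPassage2\tPassage\tDocument")
    for qid in sorted(report):
        row = report[qid]
        lines.append(f"{qid}\t{row['aspect_ap']:.8f}\tn/a\tn/a\t{row['document_ap']:.8f}")
    n = len(report)
    if n:
        mean_a = sum(r["aspect_ap"] for r in report.values()) / n
        mean_d = sum(r["document_ap"] for r in report.values()) / n
        lines.append(f"mean\t{mean_a:.8f}\tn/a\tn/a\t{mean_d:.8f}")
    return "\n".join(lines) + "\n"
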