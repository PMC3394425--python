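"""Independent oracles used by the test suite.

Everything here is deliberately naive and written directly from the
method's printed definitions, independent of the package's own code
paths: straight-line transcriptions of the two re-ranking listings,
exact enumeration of the LDA marginal likelihood, and a literal walk
of the aspect-AP definition.
"""

import itertools
import math

import numpy as np
from scipy.special import gammaln, logsumexp


def naive_distance(u, v, mu=None):
    if mu is None:
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))
    return math.sqrt(sum(m * (a - b) ** 2 for m, a, b in zip(mu, u, v)))


def naive_select_first(R, N, rows):
    window = R[: min(N, len(R))]
    coverages = [sum(rows[p]) for p in window]
    best = max(coverages)
    return window[coverages.index(best)]


def naive_rank_nwin(R, rows, N, mu=None):
    """Literal transcription of the greedy slide-window listing."""
    R = list(R)
    pass1 = naive_select_first(R, N, rows)
    R.remove(pass1)
    S = [pass1]
    while len(R) != 0:
        if len(R) >= N:
            candidates = R[:N]
        else:
            candidates = list(R)
        dist = []
        for p in candidates:
            d = 0.0
            for s in S:
                d = d + naive_distance(rows[p], rows[s], mu)
            d = d / len(S)
            dist.append(d)
        best = max(dist)
        pass_rest = candidates[dist.index(best)]
        R.remove(pass_rest)
        S.append(pass_rest)
    return S


def naive_rank_nwin_group(R, rows, N, mu=None):
    """Literal transcription of the grouped slide-window listing."""
    R = list(R)
    pass1 = naive_select_first(R, N, rows)
    R.remove(pass1)
    S = [pass1]
    n_groups = math.ceil(len(R) / N)
    for g in range(n_groups):
        group = R[g * N : (g + 1) * N]
        dist = []
        for p in group:
            d = 0.0
            for s in S:
                d = d + naive_distance(rows[p], rows[s], mu)
            d = d / len(S)
            dist.append(d)
        # descending by distance; stable sort keeps baseline order on ties
        order = sorted(range(len(group)), key=lambda i: -dist[i])
        S.extend(group[i] for i in order)
    return S


def collapsed_log_likelihood(n_tw, n_t, beta):
    T, V = n_tw.shape
    return float(
        T * (gammaln(V * beta) - V * gammaln(beta))
        + gammaln(np.asarray(n_tw) + beta).sum()
        - gammaln(np.asarray(n_t) + V * beta).sum()
    )


def exact_log_evidence(token_ids, V, T, alpha, beta):
    """log p(w|T) by summing over all T^n topic assignments.

    p(w|T) = Σ_z p(z|α) p(w|z,β), with both factors in collapsed
    (Polya) form.  Only feasible for a handful of tokens.
    """
    docs = [d for d, toks in enumerate(token_ids) for _ in toks]
    words = [w for toks in token_ids for w in toks]
    n = len(words)
    D = len(token_ids)
    terms = []
    for z in itertools.product(range(T), repeat=n):
        n_dt = np.zeros((D, T))
        n_tw = np.zeros((T, V))
        for d, w, t in zip(docs, words, z):
            n_dt[d, t] += 1
            n_tw[t, w] += 1
        lp_w = collapsed_log_likelihood(n_tw, n_tw.sum(axis=1), beta)
        lp_z = sum(
            gammaln(T * alpha) - T * gammaln(alpha)
            + gammaln(n_dt[d] + alpha).sum()
            - gammaln(n_dt[d].sum() + T * alpha)
            for d in range(D)
        )
        terms.append(lp_w + lp_z)
    return float(logsumexp(terms))


def naive_aspect_ap(order, relevant, universe):
    """Literal walk of the aspect-AP variant definition."""
    seen = set()
    novel = 0
    total = 0.0
    for r, pid in enumerate(order, start=1):
        labels = relevant.get(pid, set())
        if labels and (labels - seen):
            novel += 1
            total += novel / r
            seen.update(labels)
    return total / len(universe)


def greedy_topic_l1(phi_hat, phi_true):
    """Greedy matching of estimated to true topics; mean L1 per topic."""
    avail = set(range(phi_hat.shape[0]))
    total = 0.0
    for t in range(phi_true.shape[0]):
        best = min(avail, key=lambda k: np.abs(phi_hat[k] - phi_true[t]).sum())
        total += np.abs(phi_hat[best] - phi_true[t]).sum()
        avail.remove(best)
    return total / phi_true.shape[0]
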