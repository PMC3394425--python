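"""Collapsed Gibbs sampling for LDA, per-query model fitting and selection.

Each query's retrieved passages form one small document collection; an
LDA model is fitted to it so that the latent topics play the role of the
query's *aspects*.  Inference integrates out the topic mixtures θ and
topic-word distributions φ and resamples each token's topic assignment
z_i from its conditional

    p(z_i = t | z_-i, w)  ∝  (n_tw[t, w_i] + β) / (n_t[t] + Vβ) · (n_dt[d, t] + α)

with all counts excluding token i.  Point estimates use the usual
smoothed forms θ_dt = (n_dt + α)/(N_d + Tα) and
φ_tw = (n_tw + β)/(n_t + Vβ).

The number of topics T is selected per query by the harmonic-mean
estimate of the marginal likelihood p(w|T): the harmonic mean of
p(w|z, T) over post-burn-in samples of z.  The Dirichlet hyperparameter
α is tied to T through αT = constant (default 10), keeping the total
prior mass on θ fixed while T varies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.special import gammaln, logsumexp

from .corpus import Corpus

log = logging.getLogger(__name__)

DEFAULT_ALPHA_T_CONSTANT = 10.0


class ZeroTokenCorpusError(ValueError):
    """No tokens survive preprocessing; skip LDA and fall back to uniform θ."""


def alpha_from_T(T: int, constant: float = DEFAULT_ALPHA_T_CONSTANT) -> float:
    """Symmetric Dirichlet α for a topic count T under αT = constant.

    With the default constant 10 and T ≥ 10, α stays at or below 1.
    Smaller T is allowed but pushes α above 1 (a warning is logged).
    """
    if T < 1:
        raise ValueError("T must be positive")
    alpha = constant / T
    if alpha > 1.0:
        log.warning("alpha = %.3f > 1 for T = %d (constant = %g)", alpha, T, constant)
    return alpha


@dataclass(frozen=True)
class LdaConfig:
    """Sampler configuration for one fit.

    ``alpha`` is derived, not set: alpha = alpha_T_constant / T.
    """

    T: int
    beta: float
    alpha_T_constant: float = DEFAULT_ALPHA_T_CONSTANT
    n_sweeps: int = 1000
    burn_in: int = 500
    sample_lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.beta <= 0 or self.alpha_T_constant <= 0:
            raise ValueError("T, beta and alpha_T_constant must be positive")
        if not (0 <= self.burn_in < self.n_sweeps):
            raise ValueError("need burn_in < n_sweeps (at least one retained sample)")
        if self.sample_lag < 1:
            raise ValueError("sample_lag must be >= 1")

    @property
    def alpha(self) -> float:
        return self.alpha_T_constant / self.T


@dataclass
class GibbsState:
    """Mutable sampler state: assignments z plus the three count tables."""

    z: np.ndarray          # per-token topic, int32
    doc_of: np.ndarray     # per-token document index
    word_of: np.ndarray    # per-token word id
    n_dt: np.ndarray       # D x T
    n_tw: np.ndarray       # T x V
    n_t: np.ndarray        # T
    rng: np.random.Generator

    def check_consistency(self) -> None:
        D, T = self.n_dt.shape
        assert self.n_tw.shape[0] == T
        n_dt = np.zeros_like(self.n_dt)
        n_tw = np.zeros_like(self.n_tw)
        for d, w, t in zip(self.doc_of, self.word_of, self.z):
            n_dt[d, t] += 1
            n_tw[t, w] += 1
        assert np.array_equal(n_dt, self.n_dt)
        assert np.array_equal(n_tw, self.n_tw)
        assert np.array_equal(self.n_tw.sum(axis=1), self.n_t)
        assert self.n_t.sum() == len(self.z)


@dataclass
class TopicModel:
    """Fitted model: θ (D×T), φ (T×V), config, and the evidence estimate."""

    theta: np.ndarray
    phi: np.ndarray
    config: LdaConfig
    log_evidence: float
    retained_log_likelihoods: list[float] = field(default_factory=list)

    @property
    def T(self) -> int:
        return self.theta.shape[1]


@njit(cache=True)
def _sweep_kernel(z, doc_of, word_of, n_dt, n_tw, n_t, alpha, beta, uniforms, cum):
    V = n_tw.shape[1]
    T = n_t.shape[0]
    vbeta = V * beta
    for i in range(z.shape[0]):
        d = doc_of[i]
        w = word_of[i]
        t = z[i]
        n_dt[d, t] -= 1
        n_tw[t, w] -= 1
        n_t[t] -= 1
        total = 0.0
        for k in range(T):
            total += (n_tw[k, w] + beta) / (n_t[k] + vbeta) * (n_dt[d, k] + alpha)
            cum[k] = total
        r = uniforms[i] * total
        t = 0
        while t < T - 1 and cum[t] < r:
            t += 1
        z[i] = t
        n_dt[d, t] += 1
        n_tw[t, w] += 1
        n_t[t] += 1


def gibbs_init(corpus: Corpus, config: LdaConfig) -> GibbsState:
    """Assign every token a uniformly random topic and build count tables."""
    doc_of, word_of = corpus.flat_tokens()
    n = len(doc_of)
    if n == 0:
        raise ZeroTokenCorpusError(
            f"query {corpus.query_id!r}: no tokens survive preprocessing; "
            "skip LDA and use a uniform topic distribution"
        )
    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, config.T, size=n).astype(np.int32)
    n_dt = np.zeros((corpus.D, config.T), dtype=np.int64)
    n_tw = np.zeros((config.T, corpus.V), dtype=np.int64)
    for d, w, t in zip(doc_of, word_of, z):
        n_dt[d, t] += 1
        n_tw[t, w] += 1
    return GibbsState(z, doc_of, word_of, n_dt, n_tw, n_tw.sum(axis=1), rng)


def gibbs_sweep(state: GibbsState, corpus: Corpus, config: LdaConfig) -> GibbsState:
    """Resample every token once, in corpus order, updating counts in place."""
    uniforms = state.rng.random(len(state.z))
    cum = np.empty(config.T, dtype=np.float64)
    _sweep_kernel(
        state.z, state.doc_of, state.word_of,
        state.n_dt, state.n_tw, state.n_t,
        config.alpha, config.beta, uniforms, cum,
    )
    return state


def estimate_theta(state: GibbsState, config: LdaConfig) -> np.ndarray:
    """Smoothed passage-topic weights; zero-token passages get uniform rows."""
    alpha = config.alpha
    n_d = state.n_dt.sum(axis=1, keepdims=True)
    return (state.n_dt + alpha) / (n_d + config.T * alpha)


def estimate_phi(state: GibbsState, config: LdaConfig) -> np.ndarray:
    """Smoothed topic-word distributions; empty topics get uniform rows."""
    beta = config.beta
    V = state.n_tw.shape[1]
    return (state.n_tw + beta) / (state.n_t[:, None] + V * beta)


def sample_log_likelihood(n_tw: np.ndarray, n_t: np.ndarray, beta: float) -> float:
    """log p(w | z, T): collapsed word likelihood given the assignments.

    Closed form per topic: log Γ(Vβ) − V log Γ(β) + Σ_w log Γ(n_tw + β)
    − log Γ(n_t + Vβ).
    """
    T, V = n_tw.shape
    return float(
        T * (gammaln(V * beta) - V * gammaln(beta))
        + gammaln(n_tw + beta).sum()
        - gammaln(n_t + V * beta).sum()
    )


def log_evidence_harmonic(retained_log_likelihoods: list[float]) -> float:
    """log of the harmonic mean of p(w|z,T) over retained samples.

    Computed stably in log space: log S − logsumexp(−ll).
    """
    lls = np.asarray(retained_log_likelihoods, dtype=np.float64)
    if lls.size == 0:
        raise ValueError("need at least one retained log-likelihood")
    return float(np.log(lls.size) - logsumexp(-lls))


def fit_lda(corpus: Corpus, config: LdaConfig) -> TopicModel:
    """Run the collapsed Gibbs chain and estimate θ, φ and log p(w|T).

    Samples are retained every ``sample_lag`` sweeps after ``burn_in``
    for the evidence estimate; θ and φ come from the final sweep only
    (averaging across sweeps would mix topic labelings).
    """
    state = gibbs_init(corpus, config)
    retained: list[float] = []
    for sweep in range(config.n_sweeps):
        gibbs_sweep(state, corpus, config)
        if sweep >= config.burn_in and (sweep - config.burn_in) % config.sample_lag == 0:
            retained.append(sample_log_likelihood(state.n_tw, state.n_t, config.beta))
    return TopicModel(
        theta=estimate_theta(state, config),
        phi=estimate_phi(state, config),
        config=config,
        log_evidence=log_evidence_harmonic(retained),
        retained_log_likelihoods=retained,
    )


def _derived_seed(seed: int, T: int) -> int:
    return (seed * 100003 + 7919 * T) % (2**31)


def select_T(
    corpus: Corpus,
    T_grid: list[int],
    base_config: LdaConfig,
) -> tuple[int, list[tuple[int, float]]]:
    """Fit at each T on the grid and pick the argmax of log p(w|T).

    α is re-derived for each T through αT = constant; each fit gets its
    own seed derived from the base seed.  Ties break toward smaller T.
    """
    if not T_grid:
        raise ValueError("empty T grid")
    curve: list[tuple[int, float]] = []
    for T in T_grid:
        cfg = replace(base_config, T=T, seed=_derived_seed(base_config.seed, T))
        model = fit_lda(corpus, cfg)
        curve.append((T, model.log_evidence))
        log.info(
            "query %s: T=%d alpha=%.4f beta=%g log_evidence=%.2f",
            corpus.query_id, T, cfg.alpha, cfg.beta, model.log_evidence,
        )
    best_T = max(curve, key=lambda te: (te[1], -te[0]))[0]
    return best_T, curve


def uniform_topic_model(D: int, config: LdaConfig) -> TopicModel:
    """Fallback model for a corpus with no tokens: uniform θ everywhere."""
    T = config.T
    return TopicModel(
        theta=np.full((D, T), 1.0 / T),
        phi=np.full((T, 1), 1.0),
        config=config,
        log_evidence=0.0,
    )
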