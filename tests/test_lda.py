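import math

import numpy as np
import pytest

from ldarank.corpus import corpus_from_token_ids
from ldarank.lda import (
    LdaConfig,
    ZeroTokenCorpusError,
    alpha_from_T,
    estimate_phi,
    estimate_theta,
    fit_lda,
    gibbs_init,
    gibbs_sweep,
    log_evidence_harmonic,
    sample_log_likelihood,
    select_T,
)
from ldarank.synthetic import SyntheticSpec, generate_lda_corpus

from oracles import exact_log_evidence, greedy_topic_l1


@pytest.mark.parametrize("T, expected", [(10, 1.0), (100, 0.1), (50, 0.2), (4, 2.5)])
def test_alpha_from_T_keeps_total_prior_mass_constant(T, expected):
    assert alpha_from_T(T) == pytest.approx(expected)


def test_config_validation():
    with pytest.raises(ValueError):
        LdaConfig(T=0, beta=0.1)
    with pytest.raises(ValueError):
        LdaConfig(T=2, beta=0.1, n_sweeps=10, burn_in=10)
    assert LdaConfig(T=20, beta=0.1).alpha == pytest.approx(0.5)


def test_gibbs_init_reproducible_and_consistent(tiny_corpus):
    corpus, _ = tiny_corpus
    cfg = LdaConfig(T=3, beta=0.1, n_sweeps=10, burn_in=2, seed=7)
    s1 = gibbs_init(corpus, cfg)
    s2 = gibbs_init(corpus, cfg)
    assert np.array_equal(s1.z, s2.z)
    s1.check_consistency()
    assert s1.n_dt.sum() == corpus.n_tokens


def test_gibbs_init_single_topic_assigns_topic_zero(tiny_corpus):
    corpus, _ = tiny_corpus
    state = gibbs_init(corpus, LdaConfig(T=1, beta=0.1, n_sweeps=5, burn_in=1, seed=0))
    assert (state.z == 0).all()


def test_gibbs_init_rejects_zero_token_corpus():
    corpus = corpus_from_token_ids("q", [[], []], [])
    with pytest.raises(ZeroTokenCorpusError):
        gibbs_init(corpus, LdaConfig(T=2, beta=0.1, n_sweeps=5, burn_in=1))


def test_sweep_preserves_count_consistency(tiny_corpus):
    corpus, _ = tiny_corpus
    cfg = LdaConfig(T=3, beta=0.1, n_sweeps=10, burn_in=2, seed=1)
    state = gibbs_init(corpus, cfg)
    for _ in range(100):
        gibbs_sweep(state, corpus, cfg)
    state.check_consistency()


def test_sweep_single_topic_is_identity(tiny_corpus):
    corpus, _ = tiny_corpus
    cfg = LdaConfig(T=1, beta=0.1, n_sweeps=5, burn_in=1, seed=1)
    state = gibbs_init(corpus, cfg)
    gibbs_sweep(state, corpus, cfg)
    assert (state.z == 0).all()
    state.check_consistency()


def test_sweep_posterior_matches_exact_enumeration():
    """Long-run topic-assignment frequencies on a 4-token corpus match the
    exact collapsed posterior computed by enumerating all assignments."""
    token_ids = [[0, 1], [1, 1]]
    V, T, beta = 2, 2, 0.5
    corpus = corpus_from_token_ids("q", token_ids, ["w0", "w1"])
    cfg = LdaConfig(T=T, beta=beta, alpha_T_constant=2.0, n_sweeps=30000,
                    burn_in=100, sample_lag=1, seed=11)
    alpha = cfg.alpha
    # exact posterior probability that the two tokens of document 0 share a
    # topic (a label-symmetric statistic), by enumerating all assignments
    import itertools
    from scipy.special import gammaln, logsumexp

    docs = [0, 0, 1, 1]
    words = [0, 1, 1, 1]
    log_same, log_all = [], []
    for z in itertools.product(range(T), repeat=4):
        n_dt = np.zeros((2, T))
        n_tw = np.zeros((T, V))
        for d, w, t in zip(docs, words, z):
            n_dt[d, t] += 1
            n_tw[t, w] += 1
        lp = sample_log_likelihood(n_tw, n_tw.sum(axis=1), beta) + sum(
            gammaln(n_dt[d] + alpha).sum() for d in range(2)
        )
        log_all.append(lp)
        if z[0] == z[1]:
            log_same.append(lp)
    p_same_exact = math.exp(logsumexp(log_same) - logsumexp(log_all))
    state = gibbs_init(corpus, cfg)
    hits = 0
    n_samples = 20000
    for sweep in range(n_samples):
        gibbs_sweep(state, corpus, cfg)
        if sweep >= 100:
            hits += state.z[0] == state.z[1]
    p_same_mc = hits / (n_samples - 100)
    assert p_same_mc == pytest.approx(p_same_exact, abs=0.02)


def test_estimate_theta_matches_smoothed_estimator(tiny_corpus):
    corpus, _ = tiny_corpus
    cfg = LdaConfig(T=2, beta=0.1, alpha_T_constant=2.0, n_sweeps=5, burn_in=1, seed=3)
    state = gibbs_init(corpus, cfg)
    theta = estimate_theta(state, cfg)
    # alpha = 1 here; row formula (n_dt + 1) / (N_d + 2)
    d0 = state.n_dt[0]
    assert theta[0] == pytest.approx((d0 + 1.0) / (d0.sum() + 2.0))
    assert theta.sum(axis=1) == pytest.approx(np.ones(corpus.D), abs=1e-9)
    assert (theta > 0).all()


def test_estimate_theta_uniform_row_for_empty_passage():
    corpus = corpus_from_token_ids("q", [[0, 0], []], ["w0"])
    cfg = LdaConfig(T=4, beta=0.1, n_sweeps=5, burn_in=1, seed=0)
    state = gibbs_init(corpus, cfg)
    theta = estimate_theta(state, cfg)
    assert theta[1] == pytest.approx([0.25, 0.25, 0.25, 0.25])


def test_estimate_phi_direct_arithmetic():
    corpus = corpus_from_token_ids("q", [[0, 0, 1]], ["w0", "w1"])
    cfg = LdaConfig(T=2, beta=0.5, n_sweeps=5, burn_in=1, seed=5)
    state = gibbs_init(corpus, cfg)
    phi = estimate_phi(state, cfg)
    t = state.n_tw[0]
    assert phi[0] == pytest.approx((t + 0.5) / (t.sum() + 1.0))
    assert phi.sum(axis=1) == pytest.approx(np.ones(2), abs=1e-9)
    # a topic with zero tokens gets the uniform row
    if state.n_t[1] == 0:
        assert phi[1] == pytest.approx([0.5, 0.5])


@pytest.mark.parametrize(
    "lls, expected",
    [
        ([-3.5, -3.5, -3.5], -3.5),
        ([math.log(0.5), math.log(0.25)], math.log(1.0 / 3.0)),
    ],
)
def test_log_evidence_harmonic_closed_forms(lls, expected):
    assert log_evidence_harmonic(lls) == pytest.approx(expected)


def test_log_evidence_harmonic_rejects_empty():
    with pytest.raises(ValueError):
        log_evidence_harmonic([])


def test_harmonic_estimate_near_exact_on_tiny_corpus(tiny_corpus):
    corpus, token_ids = tiny_corpus
    T, beta = 2, 0.5
    cfg = LdaConfig(T=T, beta=beta, n_sweeps=2600, burn_in=500, sample_lag=1, seed=21)
    exact = exact_log_evidence(token_ids, corpus.V, T, cfg.alpha, beta)
    model = fit_lda(corpus, cfg)
    assert model.log_evidence == pytest.approx(exact, abs=0.3)


def test_fit_lda_deterministic_under_seed(tiny_corpus):
    corpus, _ = tiny_corpus
    cfg = LdaConfig(T=3, beta=0.1, n_sweeps=50, burn_in=10, sample_lag=5, seed=9)
    m1 = fit_lda(corpus, cfg)
    m2 = fit_lda(corpus, cfg)
    assert np.array_equal(m1.theta, m2.theta)
    assert np.array_equal(m1.phi, m2.phi)
    assert m1.log_evidence == m2.log_evidence


def test_fit_lda_single_topic_theta_all_ones(tiny_corpus):
    corpus, _ = tiny_corpus
    m = fit_lda(corpus, LdaConfig(T=1, beta=0.1, n_sweeps=10, burn_in=2, seed=0))
    assert m.theta == pytest.approx(np.ones((corpus.D, 1)))


def test_fit_lda_recovers_generating_topics():
    """φ̂ recovers φ* on a corpus drawn from the generative process."""
    spec = SyntheticSpec(T_true=3, V=40, D=100, doc_length=60,
                         alpha_true=10 / 3, beta_true=0.05, seed=17)
    corpus, _, phi_true = generate_lda_corpus(spec)
    cfg = LdaConfig(T=3, beta=0.05, n_sweeps=500, burn_in=250, sample_lag=10, seed=18)
    model = fit_lda(corpus, cfg)
    assert greedy_topic_l1(model.phi, phi_true) <= 0.25


def test_select_T_single_grid_value(tiny_corpus):
    corpus, _ = tiny_corpus
    cfg = LdaConfig(T=2, beta=0.5, n_sweeps=40, burn_in=10, sample_lag=2, seed=4)
    best, curve = select_T(corpus, [3], cfg)
    assert best == 3
    assert len(curve) == 1 and curve[0][0] == 3


def test_select_T_returns_full_curve(tiny_corpus):
    corpus, _ = tiny_corpus
    cfg = LdaConfig(T=2, beta=0.5, n_sweeps=40, burn_in=10, sample_lag=2, seed=4)
    best, curve = select_T(corpus, [1, 2, 3], cfg)
    assert [T for T, _ in curve] == [1, 2, 3]
    assert best in (1, 2, 3)
    evidences = dict(curve)
    assert evidences[best] == max(e for _, e in curve)


def test_evidence_seed_insensitivity_on_tiny_corpus(tiny_corpus):
    """Two independent chains agree on log p(w|T) within Monte-Carlo noise."""
    corpus, token_ids = tiny_corpus
    cfg = LdaConfig(T=2, beta=0.5, n_sweeps=2600, burn_in=500, sample_lag=1, seed=31)
    e1 = fit_lda(corpus, cfg).log_evidence
    e2 = fit_lda(corpus, LdaConfig(T=2, beta=0.5, n_sweeps=2600, burn_in=500,
                                   sample_lag=1, seed=32)).log_evidence
    assert abs(e1 - e2) < 0.3
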