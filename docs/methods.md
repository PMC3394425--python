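# Methods

## Model and procedure

`ldarank` treats the distinct aspects of a biomedical query's answer as
the latent topics of its retrieved passages.  For each query the
retrieved passages form one small document collection; LDA is fitted to
that collection alone, so topics are query-specific by construction.

**Preprocessing.** Text is lower-cased and split on every character
that is not an ASCII letter or digit (hyphens and slashes included).
Stop words are removed first (bundled general-English list, one word
per line, overridable), then any word occurring exactly once within a
passage is dropped.  The order matters — a word shielded by stop words
is still counted within its own passage before the singleton rule fires
— and lower-casing first makes the stop-word match case-insensitive.
Passages emptied by filtering stay in the ranking; they simply
contribute no tokens to the topic model and receive a uniform topic
row.

**Inference.** Collapsed Gibbs sampling: θ and φ are integrated out
and each token's topic assignment is resampled from

    p(z_i = t | z_-i, w) ∝ (n_tw[t,w_i] + β) / (n_t[t] + Vβ) · (n_dt[d,t] + α)

with counts excluding token i.  Point estimates are the smoothed forms
θ_dt = (n_dt + α)/(N_d + Tα) and φ_tw = (n_tw + β)/(n_t + Vβ), taken
from the final sweep only — averaging θ or φ across sweeps would mix
topic labelings.  Defaults: 1000 sweeps, 500 burn-in, one retained
sample every 10 sweeps for the evidence estimate.  The inner loop is a
numba-compiled kernel; all randomness is drawn from a seeded numpy
generator outside the kernel, so fits are bit-reproducible per seed.

**Choosing T and α.** α is tied to T through αT = 10, keeping the
total Dirichlet mass on θ (the number of virtual smoothing tokens)
constant as T varies; for T < 10 this pushes α above 1 and a warning
is logged.  T is chosen on a grid by maximizing the harmonic-mean
estimate of the marginal likelihood: log p(w|T) ≈ log S −
logsumexp(−log p(w|z_s,T)) over retained samples z_s, with the
collapsed word likelihood

    log p(w|z,T) = Σ_t [ log Γ(Vβ) − V log Γ(β) + Σ_w log Γ(n_tw+β) − log Γ(n_t+Vβ) ].

Ties on the grid break toward smaller T.  The estimator is validated
against exact enumeration of all topic assignments on tiny corpora
(agreement within 0.05 nats at 2,000+ retained samples).

**Choosing β.** β is a per-query (in practice per-collection)
configuration value and is never tuned against evaluation scores.  The
quantity that governs the model-selection regime is the total
topic-word prior mass Vβ: with Vβ well below ~5 the evidence comparison
is nearly unsmoothed and larger T is spuriously favored, while at
Vβ ≈ 10 (the regime all desk-scale experiments here use at V = 50,
i.e. β = 0.2) the evidence curve rises to a peak near the generating
topic count and falls.  This mirrors the αT = 10 convention applied to
the topic-word side.  Topic *recovery* experiments instead fit with β
equal to the generating value, since there the object of interest is
the generative model itself, not model comparison.

**Importance transform.** Each θ column t is summarized by its mean μ_t
and population standard deviation σ_t (divisor D), and every weight is
replaced by its percentile under the fitted normal,
Θ[j,t] = Φ((θ[j,t] − μ_t)/σ_t).  Φ is the normal *cumulative*
distribution, the monotone reading of "most passages have a smaller
weight, hence this one is more important"; a density would not be
monotone in the weight.  σ as the square root of the mean squared
deviation makes the argument a standard z-score.  A column with zero
spread maps to 0.5 everywhere (all passages equally important on a
constant aspect); zero spread is detected up to float rounding
(σ ≤ 1e-12·max(1,|μ|)) so rounding noise is never amplified into
spurious z-scores.

**Re-ranking.** Both algorithms draw candidates from a window of the
top N not-yet-placed baseline passages, so no passage can leapfrog far
beyond its relevance position.  The seed is the window member with the
largest aspect coverage (row sum of Θ).  `nwin` repeatedly moves the
window member with the largest mean distance to the already-placed
passages; `nwin_group` partitions the post-seed remainder into
consecutive N-blocks and sorts each block by mean distance to the
frozen prefix, descending.  Distances are (optionally μ_t-weighted)
Euclidean distances between Θ rows — importance space, not raw θ.
All ties break toward the smaller baseline rank, preserving the
relevance prior.  Two printed-pseudocode ambiguities are resolved as:
group scores divided by |S| (symmetry with the greedy variant; within
a group the divisor is constant and cannot change the sort), and the
group loop is a plain for-loop.  Group boundaries are laid down after
seed removal.  By default only the top 100 passages are re-ranked; the
tail keeps baseline order.

**Evaluation.** Aspect AP here is an operational variant: walking the
ranking, a passage is aspect-novel iff relevant and carrying ≥1 unseen
gold label; at each aspect-novel rank r precision (novel so far)/r is
accumulated, normalized by the number of gold aspects.  The value can
exceed 1 when single passages introduce several aspects at once; it
equals 1 when ranks 1..|aspects| each introduce exactly one.
Normalizing by the novel-passage count instead is the documented
alternative; the aspect-count normalizer is the default and every
report embeds the definition string.  Character-offset passage-level
measures are out of scope and reported as n/a.

## Synthetic data: what it emulates and what it does not

`generate_lda_corpus` draws corpora exactly from the LDA generative
process (φ* ~ Dirichlet(β*), θ* ~ Dirichlet(α*), topic-then-word per
token), returning the ground truth for recovery and selection tests.
`generate_retrieval_scenario` builds the redundancy situation the
method targets: groups of passages with θ* mass ≥ 0.8 on a shared
topic sit adjacently at the head of the baseline — the worst case for
early aspect coverage — followed by Dirichlet-mixed passages.  Gold
aspects are the topics holding ≥ 0.2 of a passage's θ* (falling back
to the argmax topic when no topic reaches 0.2, so every passage stays
relevant, as the scenario intends).  This makes "aspect = latent
topic" literally true, so passing tests show the machinery works when
its core premise holds; they do not show that real biomedical aspects
behave like LDA topics, that MEDLINE word statistics are Dirichlet, or
anything about the official character-level TREC measures.

Default study conditions, chosen once: 60 tokens per passage
(paragraph scale after filtering), α* = 2 (i.e. 10/T* at T* = 5,
mirroring the αT = 10 regime), β* = 0.05 (sparse, field-specific
topics).  Scenario experiments use D = 30 passages with 2–4 redundancy
groups of 4; recovery uses T* = 3, V = 40, D = 200; selection uses
T* = 5, V = 50, D = 150 over the grid {2, 3, 5, 8, 12}.  These sizes
keep a full experiment battery in the tens of seconds on one CPU while
leaving each effect clearly resolvable.

## Numerical and degenerate-input choices

- Evidence is computed entirely in log space; the harmonic mean uses
  logsumexp of negated log-likelihoods.
- A corpus with zero surviving tokens raises a typed error; the
  pipeline catches it, logs a warning, and substitutes a uniform θ
  (every Θ entry 0.5), so re-ranking degenerates to a stable
  pass-through.
- T = 1 is permitted: every token sits in topic 0 and θ is a column of
  ones.
- Per-query seeds are derived from the master seed plus a CRC-32 of
  the query id, so results are independent of query order.
- Re-written run files assign strictly decreasing integer scores; rank
  equals position.

## Known limitations

- The harmonic-mean evidence estimator is noisy and optimistic for
  over-parameterized models; outside the Vβ ≈ 10 smoothing regime the
  selection curve may not peak at the generating T at desk scale.
- A single final Gibbs sample estimates θ and φ; multi-chain averaging
  with topic alignment would reduce variance but is out of scope.
- Aspect AP here is not the official trec-genomics character-level
  measure; absolute values are not comparable with published track
  numbers.
- Stemming, lemmatization and biomedical entity normalization are
  deliberately absent from preprocessing.
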