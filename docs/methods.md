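# Methods

This note documents the models implemented in `semdens`, the choices made
where the published method description left room, the synthetic data the
package validates itself on, and the limits of what those validations show.

## Preprocessing

Utterances carry a participant id and a speaker role; analyses run on
participant speech only (an `--speaker interviewer` path exists for the
interviewer control analysis). Sentences are split on terminal punctuation,
tokenized, POS-tagged and lemmatized, then reduced to content words —
nouns, verbs, adjectives, adverbs — expressed as POS-prefixed lemma keys
(`NN_voice`, `VB_hear`). Sentences longer than 60 tokens are dropped, not
truncated, and logged; `n_j` counts content *tokens*, so a repeated word
counts each time it is said.

The tagging backend is pluggable (`tag_tokens(tokens) -> (surface, coarse
tag, lemma)` over the coarse set `{NN, VB, JJ, RB, IN, CC, DT, PR,
OTHER}`). The built-in backend is a deterministic lexicon-and-suffix rule
tagger with a table of irregular verb lemmas; it is adequate for
conversational English and for the pseudo-word fixtures (unknown words
default to nouns), and a Penn-style statistical tagger can be mapped in via
`map_penn_tag`. The backend name is recorded in run reports.

**Shuffle control.** `pos_shuffle` permutes content words across a
transcript uniformly *within* each POS category, preserving sentence count,
sentence lengths, per-position POS patterns, and the per-POS word multiset.
The default scope is per participant — the participant is the predictive
unit, and per-transcript shuffling keeps each participant's word inventory
fixed — with a cohort-wide scope available via flag.

## Word embeddings

Keys are POS-prefixed lemmas. Default training configuration: skip-gram,
200 dimensions, symmetric window of 5, 4 epochs; persistence in the
word2vec text format plus a two-column frequency table. The trainer is an
in-package skip-gram with negative sampling written on numpy (5 negatives
from the unigram^0.75 distribution, linearly decaying learning rate,
deterministic for a fixed seed); it is intended for the modest corpora this
package trains, and any externally trained embeddings in the text format
load directly.

Probe vocabularies ("the most commonly written words") are selected by
*cumulative token coverage*: the shortest frequency-ranked prefix whose
token counts reach the requested fraction of the corpus, ties broken
lexicographically. A rank-based alternative (top fraction of vocabulary
types) is available via `mode="rank"`.

## Vector unpacking and semantic density

Sentence vectors are unit-normalized sums of content-word embeddings;
out-of-vocabulary words are skipped and logged, and a sentence with no
in-vocabulary word is excluded from all vector analyses.

Unpacking minimises E = ½‖y − Σᵢ wᵢxᵢ‖² by plain gradient descent
(Δwᵢ = η·Σ_dims (y − ŷ)·xᵢ) over the full lexicon, with weights initialised
at zero — deterministic, and the first step seeds exactly the words most
aligned with the sentence. After each iteration t, weights below
t/(τ·max_iterations) are set *exactly* to zero; defaults τ = 100 and
max_iterations = 5000. Pruning is by signed value by default (negative
weights are zeroed — negative meaning components have no interpretation in
the density ratio); magnitude pruning is a flag.

Numerical choices:

* η defaults to 0.01. Gradient descent on this quadratic is stable for
  η < 2/λ_max of the candidate Gram matrix; for a cluster of c words at
  mutual cosine ρ, λ_max ≈ 1 + (c−1)ρ.
* A safe early stop is on by default: descent halts when the per-iteration
  cost change falls below `convergence_tol` (1e-10) *and* no surviving
  weight lies below the final threshold 1/τ, so no pruning that the full
  schedule would perform is pending. Setting the tolerance to 0 runs the
  exact schedule.
* `UnpackingConfig.desk_scale()` (η = 0.1, 300 iterations) is the
  configuration used for the package's small synthetic spaces (~120 words,
  d = 24). Partial convergence is deliberate: it is the regime in which the
  method behaves as designed, with sentence words carrying high weights and
  correlated neighbours a low tail. A fully converged solution on a small
  lexicon reproduces the sentence's exactly-equal composition weights and
  contains no selectable structure.

**Component selection.** Nonzero weights are rank-ordered (by magnitude)
and every split into a high/low pair is scored by the two-group one-way F
ratio (between-group mean square over within-group mean square; a size-1
group contributes zero within-group variance; a perfect split has F = ∞;
ties break toward the smaller high group, i.e. fewer components). The high
group of the best split is the component set, m. If m/n ≤ 0.25 the split
with the *second* highest F is used instead, once, and flagged
`repartitioned` — very low densities usually reflect heavy word repetition
isolating one dominant weight. Degenerate cases: ≤ 2 nonzero weights, or
weights whose relative spread is below 1e-3 (F undefined up to float
noise), select all nonzero weights. m can exceed n on overcomplete
lexicons where correlated non-sentence words survive pruning; values are
reported as computed and flagged, never clamped. At toy scale this means
absolute densities are not calibrated to the 0–1 range seen with a full
vocabulary; group contrasts are the meaningful quantity.

**Comparators.** Idea density = (VB + JJ + RB + IN + CC tokens) / all
tokens of the tagged sentence. Information value = mean word-vector length
and resultant length over *unnormalized* embeddings.

## Latent content analysis

Per participant, each probe word's score is the *maximum* cosine between
its embedding and any sentence vector — monotone in the sentence set and
able to register topics never explicitly voiced. Group profiles average
scores across participants. The baseline contrast defaults to

    weighted(p) = c_group(p) · log(mean_base / c_base(p))

the group cosine as term frequency and the log inverse relative baseline
prevalence as the idf analogue; a probe as close to the baseline as the
average probe gets weight zero, and baseline scores are floored at 1e-6
before the log. The plain difference c_group − c_base ships as a
sensitivity method. (Document-frequency idf proper degenerates on a
two-column matrix of continuous cosines; both implemented variants are
recorded in output metadata.) The top-k positive probes (default k = 50,
ties lexicographic) are reduced to 2-D and clustered with k-means++ over
k = 2..10, keeping the silhouette-maximal labeling. The reduction defaults
to PCA — deterministic, stable on the small probe sets the package
typically clusters — with t-SNE (the stochastic-neighbor method) available
via `reduction="tsne"`. In the automated pipeline the concept cluster is
the one with the highest mean contrast weight among its members; the
concept vector is the unit-normalized sum of member embeddings and the
predictor is its maximum cosine to each participant's sentences.

## Prediction and evaluation

Binary logistic models are fit by maximum likelihood (statsmodels). Small
clinical cohorts sit near quasi-complete separation; when fitted
probabilities pin to 0/1 and coefficients diverge (or the optimizer fails),
the model is refit with a small ridge penalty (λ = 1e-4, intercept
unpenalized, Newton iterations, SEs from the penalized Hessian) and flagged
— reproducible finite coefficients instead of runaway ones. Wald χ²(1) =
(β/SE)²; the single-predictor decision boundary is −β₀/β₁ (the value where
p = 0.5); classification threshold 0.5, configurable. Confusion metrics
report undefined ratios (e.g. precision with no positive predictions) as
explicit `None`, never 0. No multiple-testing correction is applied
anywhere. Note one printed-report discrepancy in the source results this
package mirrors: the concept-predictor cutoff printed as 0.742 is not the
value implied by the printed coefficients (−(−7.047)/9.744 ≈ 0.723); the
coefficient-derived boundary is treated as authoritative.

## Synthetic cohorts: what they emulate

`FixtureSpec` defaults are the package's study conditions: 120 words in 12
orthogonal-centered concepts (d = 24, within-concept cosine 0.8, Zipf
frequencies), 10 sentences of 4–6 content words per participant (matching
the ~5 content words per sentence of the interview cohorts), group sizes
7/23 mirroring the training composition, and strong effects of 0.8.

* **Density effect**: with this probability a positive-group sentence draws
  all words (with replacement) from one random concept — semantic
  near-duplicates plus occasional literal repeats, the two faces of
  redundant speech.
* **Negative group**: generated by the *same* draw process (without the
  concept bias) and then scrambled — tokens re-dealt across the
  transcript's sentences with lengths preserved. The groups therefore share
  one word-inventory distribution and differ only in sentence organisation,
  which is precisely the property the density statistic claims to measure;
  after a POS shuffle the groups are exchangeable by construction.
* **Concept effect**: positive-group draws mix toward a designated target
  concept, raising sentence cosines to it without requiring specific words.
* **Baseline corpus**: independent uniform draws that by default exclude
  the target concept (`target_weight=0`) — a norm corpus rarely dwells on
  the pathological topic, which is what makes base-rate contrast
  informative; `target_weight=1` reproduces the null process exactly for
  null-centering checks.

The end-to-end model comparison uses a moderate-effect condition (groups
14/26, density effect 0.5, concept effect 0.25) so that each
single-predictor model retains errors the other predictor can resolve and
a strict combined-model win is measurable.

What passing these tests shows: the implementation computes what it claims
(exact oracles), and the statistics recover effects planted through the
mechanisms they target, at realistic cohort sizes. What it does not show:
performance on real speech — pseudo-word cohorts have no syntax, no
discourse structure, a vocabulary three orders of magnitude smaller than a
trained lexicon, and planted effects far cleaner than clinical reality. At
full vocabulary scale unpacking retains 30–50 nonzero weights per sentence;
on toy lexicons the count is bounded by the lexicon and the absolute
density scale shifts accordingly.

## Known limitations

* The rule-based tagger is deliberately small; real transcripts deserve a
  statistical tagger mapped onto the coarse tag set.
* The in-package skip-gram trainer is serial numpy and not meant for
  hundred-million-word corpora.
* The exact tf-idf variant used on continuous cosines in the source method
  is underdetermined; two defensible forms are implemented and recorded in
  metadata.
* Whether pruning in the source method was by signed value or magnitude is
  unknown; both are implemented (signed default). Whether the second-best-F
  fallback iterates when the second split is also low-density is unknown;
  this implementation applies it once.
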