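# Methods

This note documents the models and procedures implemented in
`fluencylab`, the assumptions behind them, the defaults that matter, and
what the synthetic-data tests do and do not establish.

## Data model

A session is an ordered list of time-stamped utterances.  Onsets are
seconds from cue offset with millisecond precision.  Canonicalization
(de-abbreviation, de-inflection) is treated as transcription input, not
computed; the canonical form defaults to the surface form.  Administrator
utterances are retained for completeness but never scored, and they do
not split inter-word intervals (the interval between two valid words
spans anything between them).

Status labelling is two-staged and order-matters: an utterance whose
canonical form recurs is a **repetition** regardless of validity —
recurrence alone defines the label — and only non-repetitions are then
checked for **intrusion** (animal task: absence from the animal lexicon;
letter F: not starting with "f", or membership in an explicit
proper-noun list, since orthographic case in transcripts is unreliable).
Consequence: raw + repetitions + intrusions always equals the
participant-token count, and a repeated intrusion counts as a
repetition.  The raw score counts valid words only.

Cluster and timing scores are computed over valid words by default;
`include_repetitions=True` is available everywhere for sensitivity
analyses, since practice differs across labs on whether repeated words
participate in clusters.

## Cluster partitioning

A run of consecutive words is a cluster when its words form a complete
subgraph of the linkage relation; cluster size is the word count minus
one and switches are the cluster count minus one, so a lone word is a
cluster of size 0.  Complete-subgraph runs can overlap; the partitioner
resolves ties greedily left to right (extend the current run iff the next
word is related to *every* word in it), which is deterministic, respects
list order, and for shared-subcategory linkage reduces to "runs whose
running subcategory intersection stays nonempty".  Identical words are
defined as linked (reachable only under include-repetitions scoring).

## Rule-based (Troyer-style) linkage

Letter-F predicates act on ARPAbet pronunciations: rhyme (identical
phoneme suffix from the last primary-stressed vowel, falling back to the
last vowel; the rime may be the whole syllable, so monosyllabic
identical-rime pairs count), homonymy (identical stress-stripped
pronunciations, different spellings), one-vowel difference (equal-length
stress-stripped sequences differing at exactly one position, a vowel in
both), and the orthographic first-two-letters test.  With several
dictionary pronunciations a predicate holds if *any* pairing satisfies
it, mirroring how a rater credits any valid reading.  Words missing from
the pronunciation lexicon fall back to the orthographic predicate alone;
no grapheme-to-phoneme fallback is attempted.

## Animal network construction

* **Co-occurrence seed.**  For every unordered pair the number of
  position pairs within window distance w (default 2: adjacent or one
  intervening word) carrying that pair is compared with a one-sided
  binomial null: N = total within-window position pairs in the corpus,
  per-slot probability p = 2 f_u f_v from marginal relative frequencies.
  An edge requires tail probability < α (default 0.001), interpreted
  per-pair with no multiplicity correction.  A within-list permutation
  null is provided as an alternative; the binomial is the default
  because it is deterministic and fast.  The exact null of the original
  corpus-based method is underdetermined, so both are documented rather
  than asserted as *the* published procedure.
* **GTOM.**  Neighbourhoods are expanded to radius m (default 2), then
  overlap(i,j) = (|N(i)∩N(j)| + a_ij)/(min(|N(i)|,|N(j)|) + 1 − a_ij) on
  the expanded adjacency; dissimilarity is 1 − overlap with zero
  diagonal.  Isolated vertices get overlap 0 by convention.
* **Modules.**  Average-linkage agglomerative clustering of the
  dissimilarity matrix; the module count is a parameter, and the
  automatic mode cuts the dendrogram at the largest gap between merge
  heights.  Modules are completed into cliques (edges are only ever
  added).
* **Attachment.**  Words excluded by the seeding step join the module of
  their nearest cosine neighbour among already-networked words (the
  membership grows as words attach), processed in lexicographic order
  with lexicographic tie-breaks, so the result is reproducible.

## Letter-F union network

Three symmetric similarity layers over the vocabulary: semantic
(embedding cosine), orthographic (negative character-level Levenshtein
distance), phonological (Needleman–Wunsch global alignment of
stress-stripped phoneme sequences).  The substitution score is the
Jaccard overlap of tagged binary articulatory features (consonants:
place, manner, voicing; vowels: height, backness, roundedness) mapped
affinely onto [−1, +1] — so G/K, velar stops differing only in voicing,
outscore G/SH — with linear gap penalty −0.5.  This parameterization is
a documented default, configurable via an explicit substitution table.
Each layer is z-transformed over unique pairs; pairs involving a word
missing from a resource receive that layer's minimum z-weight and can
never be linked through it.

Thresholds come from an exhaustive 3-D grid search (default step 0.05 SD
over [−1, +4] SD per layer, a range that covers plausible optima with
margin): for each triple, the union adjacency (strictly above threshold
in *any* layer) restricted to the judged pairs is compared with each
rater by Cohen's κ, and the triple maximizing mean κ wins; ties break
toward the largest (sparsest) thresholds, lexicographically on
(semantic, phonological, orthographic), for stability.  The search is
vectorized (per-class predicted-positive counts via boolean matrix
products), so the ~10⁶-point default grid runs in seconds.

Network statistics: mean degree 2E/V; density as a percentage of
possible edges; mean local clustering with degree-<2 vertices counting
0; mean shortest path length over the largest connected component.

## Slope difference

The cumulative valid-word count is modelled as y = c(1 − e^(−mt)), fit by
bounded nonlinear least squares to (tᵢ, i).  Bounds c ∈ (0, 20N],
m ∈ (0, 10]; the generous asymptote bound matters because a near-linear
early-phase list is best fit by a large c with c·m equal to the output
rate.  Five starts (heuristic (N, ln2/t_half) plus four log-normally
perturbed copies) guard against local minima; the best attained SSE
wins.  Tied onsets are perturbed by +1 ms with a warning.  Repetitions
and intrusions are excluded from the curve by default, mirroring the raw
score; a flag includes them.

A transition is linked iff its empirical slope 1/IWI strictly exceeds
the model slope c·m·e^(−mt*) at the interval midpoint; exact equality is
a switch (conservative, measure-zero).  Uniform time rescaling by k
rescales m by 1/k and preserves every label (tested).  Because the curve
is fitted to the same session it classifies, the method is
*self-normalizing*: a uniformly fast or slow participant is re-centred,
and labels reflect within-session timing contrasts only.  This is why a
degenerate walk with no switches at all yields roughly balanced labels
rather than all-linked ones — only the contrast between fast
within-group and slow between-group transitions is detectable.

## Timing scores

Speed scores transform IWIs by a fourth root (the IWI distribution is
strongly right-skewed), min–max normalize within a pool, invert, and sum
per participant, separately for switch and edge transitions.  The
normalization pool defaults to the whole dataset per task and transition
type — making "the fastest transition scores 1.0" a cross-participant
statement and the sums comparable across people — with a per-session
scope available; the choice is not settled by the originating
literature, so both are implemented.  A single-value pool is assigned
the midpoint 0.5.  The Mayr regression uses raw seconds (the fourth root
belongs to the speed scores only) and returns missing values, not
zeros, when fewer than two IWIs exist.

## Agreement and correlation

The pair universe for κ comparisons is the set of unordered pairs that
occur consecutively at least once in the corpus, because slope-difference
linkage is undefined elsewhere; a vocabulary-wide universe is available
when comparing only the corpus-independent techniques.  A pair counts as
slope-difference-linked when linked in at least half of its consecutive
occurrences (exactly half counts).  κ uses the standard contingency
formula with the convention κ = 1 when both label vectors are constant
and identical.  Correlation matrices residualize every score on raw via
OLS first, so raw has correlation 0 with everything by construction; a
constant raw vector degrades gracefully to centering.

## Bayesian models

Logistic regression with independent N(0, 100²) priors on all
coefficients (effectively flat at this scale, but regularizing under
separation).  The Laplace fit finds the mode by damped Newton iterations
and takes the posterior to be normal with covariance the inverse negative
Hessian; 2,000 seeded draws from it feed WAIC, HDIs, and predictions.
MCMC is an adaptive random-walk Metropolis, proposal covariance
2.38²/d times the Laplace covariance with acceptance-rate adaptation
during warmup; it is deterministic given the seed and reports effective
sample sizes (warning below 100).  The posterior is log-concave, so both
estimators agree on their common summaries (tested).

WAIC = −2(lppd − p_waic) with the variance-based penalty; weights are
exp(−Δ/2), normalized.  Classification metrics use the posterior
predictive mean probability with a 0.5 cut (the threshold is not dictated
by the problem; it is exposed as a parameter).  NRI defaults to the
continuous (category-free) variant with a threshold variant available,
since published usage is split.  Demographic coding: dummies for male,
HS / some college / college graduate (reference: less than high school),
white, belt / buckle (reference: non-belt).  Novel scores are
residualized on raw before entering a design, so base and extended models
differ only in information beyond the raw count.

## Synthetic data

The generator emulates the study conditions the analyses assume: 60-s
sessions whose cumulative count follows the saturating exponential
(per-participant c lognormal, median 16 words, σ 0.25 — about 15 valid
words per session; m lognormal, median 0.05 /s, σ 0.3), a modular random
walk (stay probability 0.75 over 6 modules × 8 words) with lognormal IWI
multipliers of median 0.6 within modules and 1.8 between (σ 0.3) applied
to the instantaneous inverse retrieval rate, repetition/intrusion rates
0.05/0.02, and a 1,280-participant cohort with logistic outcomes.  The
default outcome coefficients are anchored to effect sizes reported for a
large ICI case-control cohort (raw −0.079, repetitions 0.073, intrusions
0.257, plus demographic terms).  A latent impairment score L ~ N(0,1)
reduces c and inflates the between-module multiplier — impairment slows
switches more than edges — and enters the outcome logit (default weight
0.5), so timing scores carry signal beyond raw and model-comparison
exercises are meaningful.  All streams derive from one master seed via
`default_rng([seed, stream, ...])`.

What the generator does *not* emulate: real lexical statistics (word
frequencies, typicality gradients), speech errors other than simple
repetitions/intrusions, administrator interruptions, recording or
transcription noise, and the case–control matching process.  Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under the stated generative model, not clinical validity on
real cohorts.

Coverage checks fit the same design the outcomes were generated from
(latent weight 0: the fitted model is the generating model, the regime
in which nominal coverage is defined).  With the latent pathway active,
raw-score coefficients are deliberately confounded — that configuration
exercises model *comparison*, not parameter recovery.

## Numerical choices and degenerate inputs

Empty sessions score zero (not an error); partitioning an empty sequence
is an error.  Fewer than 3 valid words cannot support a curve fit;
single-word sessions yield one chain of size 0.  AUC is an error on
single-class outcomes; NRI requires both events and non-events.  Grid
thresholds use strict inequality.  OLS and κ edge cases (constant raw,
constant identical raters) degrade to documented conventions rather than
NaN surprises.  Problem sizes in the test-suite simulations (e.g., 200
noisy curve fits, 100 coverage replicates at n = 1,280, 1,000 random
partition instances) were chosen as the smallest sizes at which the
checked statistics are stable.

## Known limitations

* The co-occurrence null and the alignment substitution matrix are
  documented defaults, not reconstructions of any specific published
  parameterization; results that depend on them (module counts,
  thresholds) will differ across corpora and parameter choices.
* The greedy left-to-right cluster rule is one resolution of an
  ambiguity inherent in complete-subgraph scoring; alternative tie rules
  can split runs differently on densely linked lists.
* The random-walk Metropolis sampler is adequate for the ≤ ~20-parameter
  designs used here but mixes slowly in higher dimensions; effective
  sample size warnings should be heeded.
* Out of scope by design: audio processing and transcription, case
  ascertainment and matching, and publication-grade figure rendering.
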