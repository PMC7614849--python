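# Methods

This package implements a desk-scale pipeline for studying whether the
language of forum users carries a detectable signal of depression
*before* the date at which they were (self-reportedly) diagnosed. It
covers four linked analyses — matched case-control cohort construction,
lexical-specificity corpus profiling, temporal risk-window text
classification, and sentiment-trajectory regression — exercised
end-to-end on a synthetic corpus generator, because the forum datasets
such studies use are access-restricted.

## Cohort construction

A *case* is a user whose history contains a diagnosis-disclosure post
annotated with an ordinal **recency** code describing how long before
the post the diagnosis occurred: 0 unspecified, 1 "in the past", 2 up
to 2 months, 3 between 2 months and 1 year, 4 between 1 and 3 years,
5 more than 3 years. The estimated diagnosis date is the disclosure
date minus a per-category offset. Codes 0 and 1 admit no estimate and
those users are dropped. For the bounded categories we use the
interval midpoint (30, 213 and 730 days), minimizing worst-case error
within the stated interval; the open-ended category 5 uses its lower
bound, 1095 days. All offsets are configurable.

An estimate is *valid* only when it falls strictly between the user's
first observed post and the disclosure post; an estimate that coincides
with either endpoint carries no usable pre-diagnosis observation
window, so both comparisons are strict.

Matching is 1:k on activity volume: a control candidate matches a case
when its number of posts before the case's estimated diagnosis date
differs from the case's count `d` by at most 15% of `d` (the
denominator is the case's count, read literally from the matching
rule's phrasing; the boundary is inclusive, so 115 matches 100).
Candidates are examined sequentially in a seeded random shuffle,
first-accept rather than best-match, and a matched control is never
reused for another case. Cases with fewer than k in-tolerance
candidates are excluded; every exclusion carries a reason code in the
cohort's ledger. Matching uses pre-diagnosis counts only; whole-history
counting is available through `UserRecord.post_count_before`.

The temporal experiments use a further restriction: cases (and their
controls) must have at least one post in the final two weeks before the
reference date, and surviving controls are randomly thinned to an exact
k (seeded), giving e.g. the 1:3 rebalanced subset.

## Synthetic corpus generator

The generator is first-class, tested code: it defines the conditions
under which every downstream stage is validated.

* **Classes and lexicons.** Case and control posts draw a configurable
  fraction (`lexicon_mixing`, default 0.10) of their tokens from
  class-specific Zipf-weighted lexicons (affective/relationship terms
  for cases, gaming/trading terms for controls), the rest from a shared
  background vocabulary. Mixing 1.0 with disjoint lexicons makes the
  classes linearly separable; mixing 0 makes them indistinguishable.
* **Volumes.** Posts per user are negative binomial (over-dispersed;
  mean 526.1 for cases and 521.1 for controls, dispersion r = 5), post
  lengths are lognormal with log-sd 1.0 and log-means chosen so the
  expected words-per-post are 47.3 (cases) and 22.4 (controls) — the
  published summary statistics of the reference corpus. Lengths are
  rounded to integers with a floor of one word.
* **Timestamps.** Post times are uniform over an observation span
  (default 104 weeks) ending at the user's estimated diagnosis date;
  no published inter-post time distribution exists, so uniformity is a
  documented, configurable choice. All cases share an anchor
  disclosure date with a 0-6 day jitter and recency category 3, and
  control histories end at the earliest possible estimated date, so a
  control's pre-diagnosis post count does not depend on which case it
  is compared against. A planted fraction of cases (default 0.2,
  mirroring the 14-of-70 attrition of the reference derivation) stops
  posting three weeks before the estimated date; the remaining cases
  are guaranteed one final-week post. Consequently the two-week
  activity filter reproducibly retains 80% of cases.
* **Matchability.** Each case receives `ceil(pool_factor * k)`
  dedicated pool controls whose total post counts are drawn inside the
  ±15% band of the case's pre-diagnosis count, so 1:k matching is
  feasible by construction (an explicitly synthetic convenience: real
  pools guarantee nothing).
* **Sentiment.** Each post's three-valued sentiment is drawn
  hierarchically. The probability of being *sentimental* (non-neutral)
  follows a logistic model whose log-odds are linear in the diagnosis
  indicator (planted coefficient 0.163, i.e. an odds ratio of 1.18),
  standardized time-to-diagnosis (0), standardized word count (0.04)
  and the diagnosis x time interaction (0), plus a per-user Gaussian
  intercept (sd 0.3). Within sentimental posts, the negative share is
  band-constant for controls (0.444) and elevated for cases (0.55
  baseline, 0.65 inside the peak band, default the 4-8-week band), so
  case negativity peaks there while the sentimentality model stays
  exactly well-specified. Word-count standardization at generation
  time uses the theoretical lognormal moments of the control class;
  the regression standardizes empirically, a discrepancy that is
  negligible at the corpus sizes used.
* **Valence tokens.** Sentimental posts embed one to three tokens from
  a signed valence inventory matching their planted label; neutral
  posts embed none. The default sentiment scorer (signed lexicon sum)
  therefore recovers the planted labels, which is deliberate: the
  package's contract is the analysis machinery, not a sentiment model.

What the generator does **not** emulate: real topicality and vocabulary
scale, bursty posting, label noise in self-reports, drift between
classes' posting schedules. Passing tests therefore demonstrate the
correctness of the pipeline's logic and inference under its stated
model, not classifier performance on real forums.

`simulate_sentiment_observations` is a lighter observation-level
simulator drawing from exactly the regression model (with empirical
standardization), used for parameter-recovery and size/power checks
without paying for text generation.

## Lexical specificity

For a term occurring f times in a subcorpus of n tokens, F times in
the pooled corpus of N tokens, the score is `-log10 P(X >= f)` with X
hypergeometric(N, F, n): the number of decimal orders of surprise of
the observed over-representation under token exchangeability. Only the
upper tail is scored — terms at or below the expected count n·F/N get
0, since the ranking targets prominence, not avoidance. The tail is
summed in log space from log-gamma binomial coefficients in blocks,
stopping once a block falls below 1e-16 of the running peak
(hypergeometric tails decay super-geometrically past the mode), so
scores of tens of thousands — far beyond what any direct probability
representation could hold — remain finite and correctly ordered. The
implementation agrees with an exact rational-arithmetic tail sum to 10
significant digits on all tested instances with N <= 200 and with
`scipy.stats.hypergeom.sf` wherever the latter does not underflow.
Lemmatization is pluggable (default: lowercasing), since no specific
lemmatizer is canonical here.

## Classification experiments

User texts are single-line concatenations of their normalized posts
(quotation characters collapsed to an apostrophe, line breaks to
spaces) inside a risk window. Windows and 4-week bands are half-open
in weeks-before-reference space: a post exactly 4.0 weeks before the
reference date belongs to the 4-8-week band, and the reference day
itself is never included, preventing post-diagnosis leakage. (A post
at exactly 24.0 weeks falls outside the last band; the six bands tile
the open interval up to 24 weeks.)

Features are TF-IDF (smoothed document frequencies, vocabulary capped
at 10,000), mean-pooled 300-d word embeddings, or their concatenation.
The embedding table is pluggable; the default is a deterministic
hashed-random table (each token's vector seeded from a stable digest),
which preserves bag-of-words geometry — identical class lexicons yield
higher within- than between-class cosine similarity — without shipping
pretrained vectors. The default classifier is a linear-kernel SVM;
any scikit-learn style estimator factory can be substituted.

Evaluation is label-stratified 5-fold cross-validation (stratification
is a deliberate choice: at 70 cases unstratified folds can be
degenerate), repeated 3 times with distinct fold seeds; the feature
transformer is refit on training folds only. Out-of-fold predictions
are pooled per repeat into PPV, sensitivity and F1 (computed as
2TP/(2TP+FP+FN), the harmonic mean in one correctly-rounded division);
means and SDs are reported across repeats. The naive all-positive
baseline has the closed form F1 = 2/(2+k) on a 1:k design, which the
measured route reproduces exactly.

For bounded-context scorers a sliding-window harness splits the token
stream into 512-token windows (stride 512 by default, final partial
window kept) and aggregates per-window probabilities by their mean,
thresholded at 0.5; empty inputs return probability 0.5 flagged "no
content". Misclassification profiling reports a user's chief topic
(single-topic LDA over their posts), their top TF-IDF terms against
the cohort, and occurrence counts of the reference class vocabularies.

## Sentiment regressions

Per-post observations carry the diagnosis indicator, time to the
(inherited) estimated diagnosis date in weeks, word count, a
three-valued sentiment and the derived sentimental indicator. Band
summaries average each user's within-band sentiment shares and then
average across users within class; users with no posts in a band are
dropped from that band's average by default (counting them as 0% is
available as a switch, since the convention is not standard).

The sentimentality model is a logistic regression with a per-user
Gaussian random intercept, fitted by maximizing the marginal
likelihood. The intercept is integrated out with 41-node Gauss-Hermite
quadrature — the quadrature refinement of the Laplace approximation —
optimized by L-BFGS with the analytic gradient, warm-started at the
plain-logistic solution; standard errors come from the numerically
differentiated observed information, p-values are Wald. On shared
datasets the fit matches `lme4::glmer` to about four decimals in
coefficients, standard errors and intercept SD (a test reproduces this
comparison). Continuous covariates are z-standardized before fitting —
the scale on which reported coefficient tables are plausible — and a
raw-scale refit is available via `standardize=False`. Zero-word posts
are retained. Degenerate cases are surfaced, not patched: separation
and non-convergence raise diagnostic errors.

The multinomial model (neutral reference) is fitted as the equivalent
series of logistic models — positive-vs-neutral and negative-vs-neutral
on the corresponding subsets, sharing the full-table standardization —
which for two-category data coincides with joint multinomial maximum
likelihood (verified against `statsmodels.MNLogit`). The series fits
contain no random effect; odds ratios are exp(beta) throughout.

## Problem sizes and numerical choices

Tests and the pipeline's demo configuration run scaled-down corpora
(tens of cases, tens of posts per user); full study-scale generation
(70 cases, 1:10 matching, ~520 posts/user) is used where cohort counts
themselves are under test. Parameter-recovery checks use 100
replicates of 500 users x 100 posts; size checks use 200 null
replicates of 200 users x 25 posts. Quadrature uses 41 nodes; the
specificity tail truncates at a relative 1e-16; matching, fold
assignment, subsampling and generation each consume an explicit seed,
and the pipeline derives per-stage seeds from one master seed by fixed
offsets.

## Known limitations

* The recency-to-offset map is a point convention for interval data;
  category-5 estimates are lower bounds.
* The generator's guaranteed matchability and shared anchor date
  remove two sources of real-world attrition (sparse pools,
  heterogeneous calendars).
* The hashed-random embedding preserves lexical, not semantic,
  geometry; conclusions about embedding features transfer to
  pretrained tables only qualitatively.
* The mixed model supports a single random intercept (per user) —
  random slopes are out of scope.
* Specificity scores are upper-tail only and unigram only.
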