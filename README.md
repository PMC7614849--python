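# prodromal-text

Tools for asking whether the posting history of a forum user carries a
detectable signal of depression *before* the date they report being
diagnosed. The package builds matched case-control cohorts from
recency-annotated diagnosis disclosures, profiles class vocabularies
with hypergeometric lexical specificity, runs temporal risk-window text
classification experiments, and fits sentimentality regressions over
the weeks preceding the estimated diagnosis date. Because the forum
corpora used for such studies are access-restricted, a fully seeded
synthetic generator with a ground-truth ledger stands in for the data,
making every stage testable end to end.

Intended users: computational epidemiologists and NLP researchers who
want a transparent, reproducible reference implementation of this
study design.

## The core quantities

* **Estimated diagnosis date** — disclosure-post date minus an offset
  implied by an ordinal recency code (codes 0-1 unusable; 2 → 30 d,
  3 → 213 d, 4 → 730 d, 5 → 1095 d).
* **1:k matched design** — each case paired with k controls whose
  pre-diagnosis post count c satisfies |c − d| / d ≤ 0.15, where d is
  the case's count; first-accept in seeded random order, no reuse.
* **Lexical specificity** — for a term with subcorpus count f (of n
  tokens) and global count F (of N), the score is
  −log₁₀ P(X ≥ f), X ~ Hypergeometric(N, F, n), computed in log space
  so corpus-scale scores (tens of thousands) stay finite.
* **Naive baseline** — the all-positive classifier on a 1:k design has
  PPV = 1/(1+k), sensitivity 1, hence F1 = 2/(2+k).
* **Sentimentality model** — logit P(non-neutral post) =
  β₀ + β_d·diagnosis + β_t·time + β_w·words + β_{dt}·diagnosis×time
  + b_user, with b_user ~ N(0, σ²) integrated out by Gauss-Hermite
  quadrature; odds ratios are exp(β). A neutral-reference multinomial
  variant is fitted as the equivalent series of logistic models.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from prodromal_text import (
    GeneratorConfig, generate_cohort, build_cohort, temporal_subset,
    build_windowed_dataset, crossval, naive_baseline_f1,
    make_observations, fit_sentimentality_logistic,
)

users, annotations, truth = generate_cohort(GeneratorConfig(seed=1))
cohort = build_cohort(users, annotations, k=10, seed=2)
print(len(cohort.cases), cohort.n_users)
# 70 770                      <- 70 cases, each with 10 matched controls

sub = temporal_subset(cohort, window_weeks=2, k_out=3, seed=3)
print(len(sub.cases), sub.n_users)
# 56 224                      <- cases active in the final fortnight, 1:3

m = crossval(build_windowed_dataset(sub, weeks=12), repeats=3, seed=4)
print(f"{m.f1:.3f} vs naive {naive_baseline_f1(3):.3f}")
# 1.000 vs naive 0.400        <- TF-IDF SVM on the last 12 weeks of text

obs = make_observations(sub, sentiments=truth.post_sentiments)
table = fit_sentimentality_logistic(obs).table
print(table.loc["diagnosis"].round(3).to_dict())
# {'beta': 0.163, 'odds_ratio': 1.177, 'se': 0.058, 'p': 0.005}
```

The classifier clears the 0.400 all-positive floor easily — with 10% of
tokens drawn from disjoint class lexicons, week-scale concatenations
are linearly separable (lower `lexicon_mixing` to make the task hard).
The diagnosis coefficient recovers the planted log-odds of 0.163
(cases ≈ 1.18 times the odds of a sentimental post).

The same stages are available on the command line:

```bash
prodromal-text simulate --seed 1 --out data/
prodromal-text build-cohort --users data/users.jsonl \
    --annotations data/annotations.jsonl --k 10 --out data/cohort.json
prodromal-text run-all --out pipeline_out/   # all stages + report.md
```

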