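"""Per-post sentiment labelling, temporal-band summaries, and the
sentimentality regressions.

A post is *sentimental* when its three-valued sentiment label is not
neutral.  Two models quantify the association between an eventual
depression diagnosis and post sentiment:

* a logistic mixed-effects regression of the sentimental indicator on
  the diagnosis indicator, time to the estimated diagnosis (weeks),
  post word count and the diagnosis x time interaction, with a
  per-user random intercept (marginal likelihood via Gauss-Hermite
  quadrature, see :mod:`.glmm`);
* a multinomial model with neutral as the reference category, fitted
  as the equivalent series of logistic models (positive-vs-neutral and
  negative-vs-neutral on the corresponding subsets), each with the
  same four fixed effects.

Continuous covariates are z-standardized before fitting (the
coefficient scale of the reported tables); refitting on raw scales is
available.  Odds ratios are exp(beta); p-values are Wald.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._lexicons import NEGATIVE_VALENCE, POSITIVE_VALENCE
from .cohort_builder import MatchedCohort
from .corpus_io import Post, tokenize
from .glmm import MixedLogitResult, fit_logistic_random_intercept
from .temporal_classify import BAND_WEEKS, N_BANDS

__all__ = [
    "SENTIMENTS",
    "LexiconSentimentScorer",
    "label_sentiment",
    "make_observations",
    "band_percentages",
    "fit_sentimentality_logistic",
    "fit_multinomial",
    "or_from_beta",
    "RegressionTable",
]

logger = logging.getLogger(__name__)

SENTIMENTS = ("negative", "neutral", "positive")
TERMS = ("intercept", "diagnosis", "time_weeks", "word_count", "diagnosis:time")


class LexiconSentimentScorer:
    """Deterministic signed-lexicon scorer: each token in the negative
    (positive) valence list contributes -1 (+1); the sign of the sum is
    the label, zero evidence is neutral."""

    def __init__(
        self,
        positive: Sequence[str] = POSITIVE_VALENCE,
        negative: Sequence[str] = NEGATIVE_VALENCE,
    ):
        self.positive = frozenset(w.lower() for w in positive)
        self.negative = frozenset(w.lower() for w in negative)

    def __call__(self, text: str) -> str:
        score = 0
        for tok in tokenize(text):
            t = tok.lower()
            if t in self.positive:
                score += 1
            elif t in self.negative:
                score -= 1
        return "positive" if score > 0 else "negative" if score < 0 else "neutral"


def label_sentiment(post: Post, scorer: Callable[[str], str] | None = None) -> str:
    """Three-valued sentiment of one post (default: lexicon scorer)."""
    scorer = scorer or LexiconSentimentScorer()
    label = scorer(post.text)
    if label not in SENTIMENTS:
        raise ValueError(f"scorer returned unknown label {label!r}")
    return label


def make_observations(
    cohort: MatchedCohort,
    scorer: Callable[[str], str] | None = None,
    sentiments: Mapping[str, Sequence[str]] | None = None,
    max_weeks: float | None = None,
) -> pd.DataFrame:
    """Per-post observation table for the regressions and band summaries.

    Sentiment comes either from ``sentiments`` (per-user label lists
    aligned with the date-ordered posts, e.g. a ground-truth ledger) or
    from ``scorer`` applied to each post's text.  Controls inherit
    their case's estimated diagnosis date.  Columns: ``user_id,
    diagnosis, time_weeks, word_count, sentiment, sentimental, band``
    (band is 0-5 inside the 24 pre-diagnosis weeks, else NA).
    """
    if sentiments is None:
        scorer = scorer or LexiconSentimentScorer()
    rows = []
    for user, label, ref in cohort.members():
        user_sents = sentiments.get(user.user_id) if sentiments is not None else None
        if user_sents is not None and len(user_sents) != len(user.posts):
            raise ValueError(f"sentiment list mismatch for {user.user_id!r}")
        for i, post in enumerate(user.posts):
            t = (ref - post.date).days / 7.0
            if t < 0 or (max_weeks is not None and t > max_weeks):
                continue
            sent = user_sents[i] if user_sents is not None else scorer(post.text)
            band = int(t // BAND_WEEKS) if t < N_BANDS * BAND_WEEKS else -1
            rows.append((user.user_id, label, t, post.word_count, sent,
                         int(sent != "neutral"), band))
    df = pd.DataFrame(rows, columns=["user_id", "diagnosis", "time_weeks",
                                     "word_count", "sentiment", "sentimental",
                                     "band"])
    df["band"] = df["band"].where(df["band"] >= 0, pd.NA)
    return df


def band_percentages(
    observations: pd.DataFrame, include_empty_as_zero: bool = False
) -> pd.DataFrame:
    """Average per-user percentage of negative/neutral/positive posts in
    each 4-week band, by class.

    Per user and band the shares sum to 100; users with no posts in a
    band contribute nothing to that band's average (set
    ``include_empty_as_zero`` to count them as 0% instead).
    """
    obs = observations.dropna(subset=["band"]).copy()
    obs["band"] = obs["band"].astype(int)
    per_user = (
        obs.groupby(["diagnosis", "user_id", "band"])["sentiment"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=list(SENTIMENTS), fill_value=0.0)
        * 100.0
    )
    if include_empty_as_zero:
        users = obs[["diagnosis", "user_id"]].drop_duplicates()
        full = pd.MultiIndex.from_tuples(
            [(d, u, b) for d, u in users.itertuples(index=False)
             for b in range(N_BANDS)],
            names=["diagnosis", "user_id", "band"],
        )
        per_user = per_user.reindex(full, fill_value=0.0)
    return per_user.groupby(["diagnosis", "band"]).mean()


@dataclass
class RegressionTable:
    """Coefficient table of one fitted model.

    ``table`` is indexed by term with columns ``beta, odds_ratio, se,
    p``; ``scale`` records whether continuous covariates were
    z-standardized.
    """

    table: pd.DataFrame
    model: str
    scale: str = "standardized"
    random_intercept_sd: float | None = None
    loglik: float | None = None

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def or_from_beta(beta: float) -> float:
    """Odds ratio implied by a log-odds coefficient: exp(beta)."""
    return float(np.exp(beta))


def _design(obs: pd.DataFrame, standardize: bool) -> tuple[np.ndarray, list[str]]:
    t = obs["time_weeks"].to_numpy(dtype=float)
    w = obs["word_count"].to_numpy(dtype=float)
    d = obs["diagnosis"].to_numpy(dtype=float)
    if standardize:
        t = (t - t.mean()) / t.std()
        w = (w - w.mean()) / w.std()
    X = np.column_stack([np.ones(len(obs)), d, t, w, d * t])
    return X, list(TERMS)


def _as_table(params, se, pvals, names) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "beta": params,
            "odds_ratio": np.exp(params),
            "se": se,
            "p": pvals,
        },
        index=pd.Index(names, name="term"),
    )


def fit_sentimentality_logistic(
    observations: pd.DataFrame,
    random_intercept_by_user: bool = True,
    standardize: bool = True,
    n_quad: int = 41,
) -> RegressionTable:
    """Logistic (mixed-effects) regression of the sentimental indicator.

    Fixed effects: diagnosis, time to estimated diagnosis (weeks), post
    word count, and the diagnosis x time interaction; random intercept
    per user (optional).  Requires at least two users per class.
    """
    for cls in (0, 1):
        if observations.loc[observations["diagnosis"] == cls, "user_id"].nunique() < 2:
            raise ValueError("need at least 2 users per class")
    y = observations["sentimental"].to_numpy(dtype=float)
    X, names = _design(observations, standardize)
    scale = "standardized" if standardize else "raw"
    if random_intercept_by_user:
        res = fit_logistic_random_intercept(
            y, X, observations["user_id"].to_numpy(), names=names, n_quad=n_quad
        )
        table = _as_table(res.params, res.se, res.pvalues, names)
        return RegressionTable(table, "logistic_mixed", scale,
                               random_intercept_sd=res.sigma_u,
                               loglik=res.loglik)
    import statsmodels.api as sm
    fit = sm.Logit(y, X).fit(disp=0)
    table = _as_table(fit.params, fit.bse, fit.pvalues, names)
    return RegressionTable(table, "logistic", scale, loglik=float(fit.llf))


def fit_multinomial(
    observations: pd.DataFrame,
    reference: str = "neutral",
    standardize: bool = True,
) -> dict[str, RegressionTable]:
    """Multinomial sentiment model with ``reference`` as base category,
    fitted as the equivalent series of logistic models: for each
    non-reference outcome, outcome-vs-reference logistic regression on
    the subset of posts with one of the two labels.

    Covariate standardization uses the full observation table (shared
    scale across the series).  All three labels must be present.
    """
    present = set(observations["sentiment"].unique())
    missing = set(SENTIMENTS) - present
    if missing:
        raise ValueError(f"missing sentiment categories: {sorted(missing)}")
    if reference not in SENTIMENTS:
        raise ValueError(f"unknown reference category {reference!r}")
    import statsmodels.api as sm

    X_all, names = _design(observations, standardize)
    scale = "standardized" if standardize else "raw"
    out: dict[str, RegressionTable] = {}
    for outcome in SENTIMENTS:
        if outcome == reference:
            continue
        mask = observations["sentiment"].isin([outcome, reference]).to_numpy()
        y = (observations.loc[mask, "sentiment"] == outcome).to_numpy(dtype=float)
        fit = sm.Logit(y, X_all[mask]).fit(disp=0)
        out[outcome] = RegressionTable(
            _as_table(fit.params, fit.bse, fit.pvalues, names),
            f"multinomial[{outcome} vs {reference}]", scale,
            loglik=float(fit.llf),
        )
    return out
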