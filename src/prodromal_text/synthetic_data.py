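"""Synthetic forum-corpus generator with a ground-truth ledger.

The generator emulates the statistical structure that the downstream
analyses assume, so every stage of the pipeline can be exercised and
tested without access to restricted forum data:

* two user classes (prospective cases vs controls) whose posts draw a
  configurable fraction of tokens from disjoint class lexicons, the
  rest from a shared background vocabulary;
* over-dispersed per-user post counts (negative binomial) and
  right-skewed post lengths (lognormal), with class-specific targets
  matching published corpus summaries (≈47 words/post for cases,
  ≈22 for controls, ≈520-530 posts/user);
* post timestamps uniform over an observation span ending at the
  user's estimated diagnosis date (cases) or a common anchor
  (controls), with a planted fraction of cases falling silent in the
  final weeks (these are the users a recent-activity filter drops);
* three-valued per-post sentiment drawn from a logistic model whose
  log-odds of being "sentimental" (non-neutral) are linear in the
  diagnosis indicator, standardized time-to-diagnosis, standardized
  word count and their interaction, plus a per-user random intercept.
  Within sentimental posts the negative share of case posts peaks in a
  configurable 4-week band before the estimated diagnosis date;
* valence tokens embedded in each post's text consistent with its
  planted sentiment, so a lexicon scorer can recover the labels.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._lexicons import (
    BACKGROUND_TERMS,
    CASE_TERMS,
    CONTROL_TERMS,
    NEGATIVE_VALENCE,
    POSITIVE_VALENCE,
    as_distribution,
)
from .cohort_builder import DEFAULT_RECENCY_RULES
from .corpus_io import DiagnosisAnnotation, Post, UserRecord

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "plant_sentiment_trajectory",
    "simulate_sentiment_observations",
    "write_truth",
]

SENTIMENTS = ("negative", "neutral", "positive")


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent generator configurations."""


def _default_length_params() -> dict[str, tuple[float, float]]:
    # lognormal mean exp(mu + s^2/2): targets 47.3 / 22.4 words per post
    s = 1.0
    return {
        "depressed": (math.log(47.3) - 0.5 * s * s, s),
        "control": (math.log(22.4) - 0.5 * s * s, s),
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults reproduce the reference
    study conditions (70 cases, 10 controls per case, ±15%-matchable
    pool, 20% of cases inactive in the final fortnight, diagnosis →
    sentimentality log-odds 0.163)."""

    n_cases: int = 70
    controls_per_case: int = 10
    #: dedicated pool candidates generated per case, as multiple of k
    pool_factor: float = 2.0
    lexicon_case: Sequence[str] | Mapping[str, float] = CASE_TERMS
    lexicon_control: Sequence[str] | Mapping[str, float] = CONTROL_TERMS
    lexicon_background: Sequence[str] | Mapping[str, float] = BACKGROUND_TERMS
    #: fraction of (non-valence) tokens drawn from the class lexicon
    lexicon_mixing: float = 0.1
    #: class -> (mean, negative-binomial dispersion r)
    post_count_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"depressed": (526.1, 5.0), "control": (521.1, 5.0)}
    )
    #: class -> (log-mean, log-sd) of lognormal words/post
    post_length_distribution: dict[str, tuple[float, float]] = field(
        default_factory=_default_length_params
    )
    observation_span_weeks: int = 104
    #: class -> (negative, neutral, positive) band-baseline rates.  For
    #: cases the sentimentality level is *derived* from the control rate
    #: and the planted log-odds; only the negative:positive split of the
    #: depressed tuple is used.
    sentiment_base_rates: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "control": (0.20, 0.55, 0.25),
            "depressed": (0.27, 0.51, 0.22),
        }
    )
    #: 4-week band (0 = final month) with elevated case negativity
    negativity_peak_band: int = 1
    #: case negative share of sentimental posts inside the peak band
    peak_negative_share: float = 0.65
    planted_sentimentality_log_odds: float = 0.163
    planted_time_log_odds: float = 0.0
    planted_wordcount_log_odds: float = 0.04
    planted_interaction_log_odds: float = 0.0
    user_intercept_sd: float = 0.3
    recency_category: int = 3
    anchor_date: _dt.date = _dt.date(2015, 6, 1)
    #: diagnosis-post dates are anchor + U{0..jitter-1} days
    anchor_jitter_days: int = 7
    #: fraction of cases with no posts in the final `recent_gap_weeks`
    recent_gap_fraction: float = 0.2
    recent_gap_weeks: int = 3
    max_valence_tokens: int = 3
    min_posts_per_user: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.controls_per_case < 1:
            raise ConfigurationError("need n_cases >= 1 and k >= 1")
        if self.pool_factor < 1.0:
            raise ConfigurationError(
                "pool_factor < 1 cannot supply k candidates per case"
            )
        if not 0.0 <= self.lexicon_mixing <= 1.0:
            raise ConfigurationError("lexicon_mixing must lie in [0, 1]")
        if not 0.0 <= self.recent_gap_fraction < 1.0:
            raise ConfigurationError("recent_gap_fraction must lie in [0, 1)")
        for cls, (mean, r) in self.post_count_distribution.items():
            if mean <= 0 or r <= 0:
                raise ConfigurationError(f"post counts for {cls}: mean, r > 0")
        for cls, rates in self.sentiment_base_rates.items():
            arr = np.asarray(rates, dtype=float)
            if arr.shape != (3,) or np.any(arr < 0) or not math.isclose(
                arr.sum(), 1.0, abs_tol=1e-9
            ):
                raise ConfigurationError(
                    f"sentiment rates for {cls} must be 3 probabilities summing to 1"
                )
        if not DEFAULT_RECENCY_RULES[self.recency_category].usable:
            raise ConfigurationError(
                f"recency category {self.recency_category} admits no date estimate"
            )
        if self.recent_gap_weeks * 7 >= self.observation_span_weeks * 7 - 1:
            raise ConfigurationError("recent gap swallows the whole span")

    # ---- derived quantities of the planted sentiment model ----------

    @property
    def control_sentimentality(self) -> float:
        neg, neu, pos = self.sentiment_base_rates["control"]
        return neg + pos

    @property
    def control_negative_share(self) -> float:
        neg, _, pos = self.sentiment_base_rates["control"]
        return neg / (neg + pos)

    @property
    def case_negative_share(self) -> float:
        neg, _, pos = self.sentiment_base_rates["depressed"]
        return neg / (neg + pos)

    def wordcount_moments(self) -> tuple[float, float]:
        """Theoretical mean/sd of words-per-post (control class), used to
        standardize the word-count covariate at generation time."""
        mu, s = self.post_length_distribution["control"]
        m = math.exp(mu + 0.5 * s * s)
        sd = m * math.sqrt(math.exp(s * s) - 1.0)
        return m, sd

    def time_moments(self) -> tuple[float, float]:
        """Mean/sd of weeks-to-diagnosis under uniform posting."""
        span = float(self.observation_span_weeks)
        return span / 2.0, span / math.sqrt(12.0)


@dataclass
class GroundTruth:
    """Per-user and per-post latent state of a generated corpus."""

    labels: dict[str, str]
    case_est_dates: dict[str, _dt.date]
    post_sentiments: dict[str, list[str]]
    user_intercepts: dict[str, float]
    planted: dict[str, float]

    def validate_coverage(self, users: Sequence[UserRecord]) -> None:
        for u in users:
            if u.user_id not in self.labels:
                raise ValueError(f"truth missing user {u.user_id!r}")
            if len(self.post_sentiments[u.user_id]) != len(u.posts):
                raise ValueError(f"truth sentiment length mismatch for {u.user_id!r}")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_planted": truth.planted}) + "\n")
        for uid, label in truth.labels.items():
            rec = {
                "user_id": uid,
                "label": label,
                "user_intercept": truth.user_intercepts[uid],
                "post_sentiments": truth.post_sentiments[uid],
            }
            if uid in truth.case_est_dates:
                rec["estimated_diagnosis_date"] = truth.case_est_dates[uid].isoformat()
            fh.write(json.dumps(rec) + "\n")


# --------------------------------------------------------------------
# sentiment planting


def _sample_sentiments(
    weeks_to: np.ndarray,
    wordcount_z: np.ndarray,
    is_case: bool,
    config: GeneratorConfig,
    rng: np.random.Generator,
    user_intercept: float,
) -> list[str]:
    """Draw per-post sentiment labels from the planted logistic model."""
    t_mean, t_sd = config.time_moments()
    t_z = (weeks_to - t_mean) / t_sd
    diag = 1.0 if is_case else 0.0
    eta = (
        logit(config.control_sentimentality)
        + config.planted_sentimentality_log_odds * diag
        + config.planted_time_log_odds * t_z
        + config.planted_wordcount_log_odds * wordcount_z
        + config.planted_interaction_log_odds * diag * t_z
        + user_intercept
    )
    sentimental = rng.random(len(eta)) < expit(eta)
    if is_case:
        band = np.floor(weeks_to / 4.0).astype(int)
        share = np.where(
            (band == config.negativity_peak_band) & (weeks_to >= 0),
            config.peak_negative_share,
            config.case_negative_share,
        )
    else:
        share = np.full(len(eta), config.control_negative_share)
    negative = rng.random(len(eta)) < share
    out = np.where(sentimental, np.where(negative, "negative", "positive"), "neutral")
    return out.tolist()


def plant_sentiment_trajectory(
    user: UserRecord,
    est_date: _dt.date,
    is_case: bool,
    config: GeneratorConfig,
    rng: np.random.Generator | int | None = 0,
    user_intercept: float | None = None,
) -> list[str]:
    """Sentiment labels for an existing user's posts under the planted
    model (controls inherit the matched case's estimated date).

    Case negativity is maximal in the configured peak band; control
    rates are band-constant; the case-vs-control log-odds of a post
    being sentimental equals ``planted_sentimentality_log_odds`` at the
    covariate means.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if user_intercept is None:
        user_intercept = rng.normal(0.0, config.user_intercept_sd)
    weeks = np.array([(est_date - p.date).days / 7.0 for p in user.posts])
    wc = np.array([p.word_count for p in user.posts], dtype=float)
    m, sd = config.wordcount_moments()
    return _sample_sentiments(weeks, (wc - m) / sd, is_case, config, rng,
                              user_intercept)


# --------------------------------------------------------------------
# corpus generation


def _nb_counts(rng, n, mean, r, minimum):
    p = r / (r + mean)
    return np.maximum(rng.negative_binomial(r, p, size=n), minimum)


def _lognormal_lengths(rng, n, mu, s):
    return np.maximum(np.rint(rng.lognormal(mu, s, size=n)).astype(int), 1)


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[UserRecord], list[DiagnosisAnnotation], GroundTruth]:
    """Generate cases, a matchable control pool, diagnosis annotations
    and the ground-truth ledger.

    Every case receives ``ceil(pool_factor * k)`` dedicated pool
    controls whose total post counts fall inside the ±15% matching band
    of the case's pre-diagnosis count, so 1:k matching is feasible by
    construction.  Byte-identical output for identical (config, seed).
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    offset = _dt.timedelta(days=DEFAULT_RECENCY_RULES[config.recency_category]
                           .offset_days)
    span_days = config.observation_span_weeks * 7
    gap_days = config.recent_gap_weeks * 7
    floor_est = config.anchor_date - offset  # earliest estimated date

    n_cases, k = config.n_cases, config.controls_per_case
    n_dedicated = math.ceil(config.pool_factor * k)
    n_gap = round(config.recent_gap_fraction * n_cases)
    gap_cases = set(rng.choice(n_cases, size=n_gap, replace=False).tolist())

    wc_mean, wc_sd = config.wordcount_moments()
    users: list[UserRecord] = []
    annotations: list[DiagnosisAnnotation] = []
    truth = GroundTruth(
        labels={}, case_est_dates={}, post_sentiments={}, user_intercepts={},
        planted={
            "sentimentality_log_odds": config.planted_sentimentality_log_odds,
            "time_log_odds": config.planted_time_log_odds,
            "wordcount_log_odds": config.planted_wordcount_log_odds,
            "interaction_log_odds": config.planted_interaction_log_odds,
            "user_intercept_sd": config.user_intercept_sd,
            "peak_band": float(config.negativity_peak_band),
        },
    )

    # pending[i] = (uid, label, dates, lengths, sentiments); text filled later
    pending: list[tuple[str, str, np.ndarray, np.ndarray, list[str]]] = []

    def _add_user(uid, label, est_for_bands, dates_ord, lengths, is_case, b_u):
        weeks = np.array([(est_for_bands - d).days / 7.0 for d in dates_ord])
        sentiments = _sample_sentiments(
            weeks, (lengths - wc_mean) / wc_sd, is_case, config, rng, b_u)
        truth.labels[uid] = label
        truth.user_intercepts[uid] = float(b_u)
        truth.post_sentiments[uid] = sentiments
        pending.append((uid, label, dates_ord, lengths, sentiments))

    case_counts = _nb_counts(
        rng, n_cases, *config.post_count_distribution["depressed"],
        config.min_posts_per_user)
    mu_d, s_d = config.post_length_distribution["depressed"]
    mu_c, s_c = config.post_length_distribution["control"]

    for i in range(n_cases):
        uid = f"d{i:04d}"
        jitter = int(rng.integers(0, config.anchor_jitter_days))
        dpd = config.anchor_date + _dt.timedelta(days=jitter)
        est = dpd - offset
        n_posts = int(case_counts[i])
        if i in gap_cases:
            # silent in the final `recent_gap_weeks`
            day_offsets = rng.integers(gap_days, span_days, size=n_posts)
        else:
            day_offsets = rng.integers(1, span_days, size=n_posts)
            day_offsets[0] = rng.integers(1, 8)  # guaranteed final-week post
        dates = np.sort(np.array([est - _dt.timedelta(days=int(o))
                                  for o in day_offsets]))
        lengths = _lognormal_lengths(rng, n_posts, mu_d, s_d)
        b_u = rng.normal(0.0, config.user_intercept_sd)
        _add_user(uid, "depressed", est, dates, lengths, True, b_u)
        truth.case_est_dates[uid] = est
        annotations.append(DiagnosisAnnotation(
            user_id=uid, diagnosis_post_date=dpd, recency=config.recency_category))

        # dedicated matchable pool controls for this case: total counts
        # inside the ±15% band of the case's pre-diagnosis count
        lo = math.ceil(0.85 * n_posts)
        hi = math.floor(1.15 * n_posts)
        ctrl_counts = rng.integers(lo, hi + 1, size=n_dedicated)
        for j, c_count in enumerate(ctrl_counts):
            cid = f"c{i:04d}_{j:02d}"
            c_off = rng.integers(1, span_days, size=int(c_count))
            c_dates = np.sort(np.array([floor_est - _dt.timedelta(days=int(o))
                                        for o in c_off]))
            c_len = _lognormal_lengths(rng, int(c_count), mu_c, s_c)
            b_c = rng.normal(0.0, config.user_intercept_sd)
            _add_user(cid, "control", floor_est, c_dates, c_len, False, b_c)

    users = _assemble_texts(pending, config, rng)
    truth.validate_coverage(users)
    return users, annotations, truth


def _assemble_texts(pending, config: GeneratorConfig, rng) -> list[UserRecord]:
    """Bulk-sample tokens and build UserRecords (single rng pass)."""
    case_vocab, case_p = _mixed_lexicon(config, "depressed")
    ctrl_vocab, ctrl_p = _mixed_lexicon(config, "control")
    neg_words = np.array(NEGATIVE_VALENCE, dtype=object)
    pos_words = np.array(POSITIVE_VALENCE, dtype=object)

    # per-post valence token counts (0 for neutral posts)
    all_lengths = np.concatenate([p[3] for p in pending]) if pending else np.array([], int)
    all_sent = np.concatenate(
        [np.asarray(p[4], dtype=object) for p in pending]
    ) if pending else np.array([], object)
    n_posts_total = len(all_lengths)
    v_counts = np.zeros(n_posts_total, dtype=int)
    sentimental = all_sent != "neutral"
    v_counts[sentimental] = 1 + rng.integers(
        0, config.max_valence_tokens, size=int(sentimental.sum()))
    v_counts = np.minimum(v_counts, all_lengths)
    body_counts = all_lengths - v_counts

    is_case_post = np.concatenate(
        [np.full(len(p[3]), p[1] == "depressed") for p in pending]
    ) if pending else np.array([], bool)
    n_case_tokens = int(body_counts[is_case_post].sum())
    n_ctrl_tokens = int(body_counts[~is_case_post].sum())
    case_tokens = case_vocab[rng.choice(len(case_vocab), size=n_case_tokens,
                                        p=case_p)]
    ctrl_tokens = ctrl_vocab[rng.choice(len(ctrl_vocab), size=n_ctrl_tokens,
                                        p=ctrl_p)]
    n_neg = int(v_counts[all_sent == "negative"].sum())
    n_pos = int(v_counts[all_sent == "positive"].sum())
    neg_tokens = neg_words[rng.integers(0, len(neg_words), size=n_neg)]
    pos_tokens = pos_words[rng.integers(0, len(pos_words), size=n_pos)]

    users: list[UserRecord] = []
    ci = di = ni = pi = 0  # cursors into the token buffers
    post_idx = 0
    for uid, label, dates, lengths, sentiments in pending:
        posts = []
        for date, L, sent in zip(dates, lengths, sentiments):
            b = int(body_counts[post_idx])
            v = int(v_counts[post_idx])
            post_idx += 1
            if label == "depressed":
                body = case_tokens[di:di + b]; di += b
            else:
                body = ctrl_tokens[ci:ci + b]; ci += b
            if sent == "negative":
                val = neg_tokens[ni:ni + v]; ni += v
            elif sent == "positive":
                val = pos_tokens[pi:pi + v]; pi += v
            else:
                val = ()
            text = " ".join(list(body) + list(val))
            posts.append(Post(author_id=uid, date=date, text=text))
        users.append(UserRecord(user_id=uid, posts=posts, label=label))
    return users


def _mixed_lexicon(config: GeneratorConfig, cls: str):
    spec_terms = (config.lexicon_case if cls == "depressed"
                  else config.lexicon_control)
    cls_words, cls_p = as_distribution(spec_terms)
    bg_words, bg_p = as_distribution(config.lexicon_background)
    m = config.lexicon_mixing
    if m >= 1.0:
        return np.array(cls_words, dtype=object), cls_p
    if m <= 0.0:
        return np.array(bg_words, dtype=object), bg_p
    vocab = np.array(list(cls_words) + list(bg_words), dtype=object)
    probs = np.concatenate([m * cls_p, (1.0 - m) * bg_p])
    return vocab, probs / probs.sum()


# --------------------------------------------------------------------
# observation-level simulator for the regression models


def simulate_sentiment_observations(
    n_cases: int = 250,
    n_controls: int = 250,
    posts_per_user: int = 100,
    diagnosis_log_odds: float = 0.163,
    time_log_odds: float = 0.0,
    wordcount_log_odds: float = 0.04,
    interaction_log_odds: float = 0.0,
    base_sentimentality: float = 0.45,
    negative_share: float = 0.5,
    user_intercept_sd: float = 0.3,
    span_weeks: float = 24.0,
    length_log_mean: float = math.log(30.0) - 0.5,
    length_log_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-post sentiment observations from the exact model the
    sentimentality regressions fit (log-odds linear in diagnosis,
    z-scored time, z-scored word count and the diagnosis x time
    interaction, plus a per-user Gaussian intercept).

    Covariates are z-scored empirically within the generated sample, so
    the fitted model is well-specified by construction.  Columns:
    ``user_id, diagnosis, time_weeks, word_count, sentiment,
    sentimental``.
    """
    rng = np.random.default_rng(seed)
    n_users = n_cases + n_controls
    n = n_users * posts_per_user
    diag = np.repeat(np.concatenate([np.ones(n_cases), np.zeros(n_controls)]),
                     posts_per_user)
    uid = np.repeat(np.arange(n_users), posts_per_user)
    t = rng.uniform(0.0, span_weeks, size=n)
    wc = np.maximum(np.rint(rng.lognormal(length_log_mean, length_log_sd,
                                          size=n)), 1.0)
    b = np.repeat(rng.normal(0.0, user_intercept_sd, size=n_users),
                  posts_per_user)
    t_z = (t - t.mean()) / t.std()
    wc_z = (wc - wc.mean()) / wc.std()
    eta = (logit(base_sentimentality) + diagnosis_log_odds * diag
           + time_log_odds * t_z + wordcount_log_odds * wc_z
           + interaction_log_odds * diag * t_z + b)
    sentimental = rng.random(n) < expit(eta)
    negative = rng.random(n) < negative_share
    sentiment = np.where(sentimental,
                         np.where(negative, "negative", "positive"), "neutral")
    return pd.DataFrame({
        "user_id": uid,
        "diagnosis": diag.astype(int),
        "time_weeks": t,
        "word_count": wc.astype(int),
        "sentiment": sentiment,
        "sentimental": sentimental.astype(int),
    })
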