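"""Temporal windowing, features, user-level classification and
misclassification profiling.

Users are classified from the single-line concatenation of their posts
inside a risk window: either the last W weeks before the reference date
(a case's estimated diagnosis date, inherited by its matched controls)
or one of six 4-week bands covering the 24 weeks before it.  Windows
and bands are half-open, ``[reference - W, reference)``, so the
reference day itself is never included.

Evaluation uses label-stratified k-fold cross-validation, repeated with
distinct seeds; positive predictive value, sensitivity and their
harmonic mean (F1) are reported as mean and SD across repeats.  The
benchmark floor is the naive all-positive classifier, whose F1 on a 1:k
matched design is 2/(2+k) in closed form.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer, TfidfVectorizer
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import FeatureUnion, Pipeline
from sklearn.svm import LinearSVC

from .cohort_builder import MatchedCohort
from .corpus_io import Post, UserRecord, concat_user_text, tokenize

__all__ = [
    "WindowedDataset",
    "ClassificationMetrics",
    "ChunkingConfig",
    "ChunkAggregate",
    "window_posts",
    "build_windowed_dataset",
    "HashedRandomEmbedding",
    "MeanEmbeddingVectorizer",
    "make_feature_pipeline",
    "features",
    "metrics",
    "crossval",
    "naive_baseline_f1",
    "chunk_and_aggregate",
    "error_profile",
]

logger = logging.getLogger(__name__)

BAND_WEEKS = 4
N_BANDS = 6


def window_posts(
    user: UserRecord,
    reference: _dt.date,
    weeks: int | None = None,
    band: int | None = None,
) -> list[Post]:
    """Posts inside a half-open risk window before ``reference``.

    ``weeks`` selects ``[reference - weeks, reference)``; ``band`` b
    selects the 4-week slice ``[reference - (b+1)*4w, reference - b*4w)``
    (band 0 is the final month).  Exactly one of the two must be given.
    """
    if (weeks is None) == (band is None):
        raise ValueError("specify exactly one of weeks= or band=")
    if band is not None:
        if not 0 <= band < N_BANDS:
            raise ValueError(f"band must be in 0..{N_BANDS - 1}")
        # half-open in weeks-before space: w in [4b, 4b+4), so a post at
        # exactly 4.0 weeks belongs to the 4-8 band, not 0-4
        lo_days = band * BAND_WEEKS * 7
        hi_days = lo_days + BAND_WEEKS * 7
        return [p for p in user.posts
                if p.date < reference
                and lo_days <= (reference - p.date).days < hi_days]
    hi = reference
    lo = reference - _dt.timedelta(weeks=weeks)
    return [p for p in user.posts if lo <= p.date < hi]


@dataclass
class WindowedDataset:
    """Per-user single-line texts restricted to a risk window."""

    user_ids: list[str]
    texts: list[str]
    labels: np.ndarray  # 1 = case, 0 = control
    reference_dates: list[_dt.date]
    weeks: int | None = None
    band: int | None = None


def build_windowed_dataset(
    cohort: MatchedCohort,
    weeks: int | None = None,
    band: int | None = None,
) -> WindowedDataset:
    """Concatenated windowed text per cohort member (controls inherit
    the case's reference date).  ``weeks=None, band=None`` keeps the
    whole history."""
    uids, texts, labels, refs = [], [], [], []
    for user, label, ref in cohort.members():
        if weeks is None and band is None:
            selected = user.posts
        else:
            selected = window_posts(user, ref, weeks=weeks, band=band)
        sel = set(id(p) for p in selected)
        uids.append(user.user_id)
        texts.append(concat_user_text(user, lambda p: id(p) in sel))
        labels.append(label)
        refs.append(ref)
    return WindowedDataset(uids, texts, np.asarray(labels, dtype=int), refs,
                           weeks=weeks, band=band)


# --------------------------------------------------------------------
# features


class HashedRandomEmbedding:
    """Deterministic pluggable word-vector table.

    Each token maps to a fixed unit-scale Gaussian vector seeded from a
    stable digest of the token (plus a table seed), so any process
    produces identical vectors without shipping a pretrained table.
    """

    def __init__(self, dim: int = 300, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def get(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}\x00{token}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dim) / np.sqrt(self.dim)
            self._cache[token] = vec
        return vec

    def __contains__(self, token: str) -> bool:  # every token is in-vocabulary
        return True


class MeanEmbeddingVectorizer(BaseEstimator, TransformerMixin):
    """Average of the word vectors of in-vocabulary tokens.

    ``table`` needs ``get(token) -> vector`` and ``__contains__``
    (a plain dict works).  Documents with no in-vocabulary token map to
    the zero vector (logged).
    """

    def __init__(self, table=None, dim: int = 300):
        self.table = table
        self.dim = dim

    def fit(self, X, y=None):
        self.table_ = self.table if self.table is not None else \
            HashedRandomEmbedding(self.dim)
        return self

    def transform(self, X):
        if not hasattr(self, "table_"):
            self.fit(X)
        table = self.table_
        get = table.get if hasattr(table, "get") else table.__getitem__
        out = np.zeros((len(X), self.dim))
        for i, doc in enumerate(X):
            vecs = [get(tok) for tok in tokenize(doc) if tok in table]
            if vecs:
                out[i] = np.mean(vecs, axis=0)
            else:
                logger.info("document %d has no in-vocabulary token; zero vector", i)
        return out


def make_feature_pipeline(
    mode: str = "tfidf",
    embedding_table=None,
    max_features: int = 10_000,
    dim: int = 300,
):
    """Feature transformer for one of the three modes: ``tfidf`` (smoothed
    document-frequency weighting, vocabulary capped), ``embedding``
    (mean pooled word vectors) or ``both`` (concatenation)."""
    tfidf = TfidfVectorizer(max_features=max_features, smooth_idf=True)
    emb = MeanEmbeddingVectorizer(table=embedding_table, dim=dim)
    if mode == "tfidf":
        return tfidf
    if mode == "embedding":
        return emb
    if mode == "both":
        return FeatureUnion([("tfidf", tfidf), ("embedding", emb)])
    raise ValueError(f"unknown feature mode {mode!r}")


def features(
    corpus: Sequence[str],
    mode: str = "tfidf",
    embedding_table=None,
    max_features: int = 10_000,
):
    """Fit a feature transformer on ``corpus`` and return the matrix.

    For leakage-free evaluation use :func:`crossval`, which refits the
    transformer on the training folds only.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    transformer = make_feature_pipeline(mode, embedding_table, max_features)
    return transformer.fit_transform(corpus)


# --------------------------------------------------------------------
# metrics and cross-validation


@dataclass
class ClassificationMetrics:
    ppv: float
    sensitivity: float
    f1: float
    ppv_sd: float | None = None
    sensitivity_sd: float | None = None
    f1_sd: float | None = None
    per_repeat: list["ClassificationMetrics"] = field(default_factory=list)


def metrics(predictions: Sequence[int], labels: Sequence[int]) -> ClassificationMetrics:
    """PPV, sensitivity and F1 of the positive (case) class.

    Zero denominators yield 0 (logged); F1 is 0 when both PPV and
    sensitivity are 0.
    """
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.size == 0 or pred.shape != lab.shape:
        raise ValueError("predictions and labels must be equal-length, non-empty")
    tp = int(np.sum((pred == 1) & (lab == 1)))
    fp = int(np.sum((pred == 1) & (lab == 0)))
    fn = int(np.sum((pred == 0) & (lab == 1)))
    if tp + fp == 0:
        logger.info("no positive predictions; PPV set to 0")
        ppv = 0.0
    else:
        ppv = tp / (tp + fp)
    sens = tp / (tp + fn) if tp + fn else 0.0
    # 2TP/(2TP+FP+FN) is the harmonic mean of PPV and sensitivity in a
    # single correctly-rounded division
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    return ClassificationMetrics(ppv=ppv, sensitivity=sens, f1=f1)


def naive_baseline_f1(k: int) -> float:
    """F1 of the all-positive classifier on a 1:k matched design.

    PPV is the prevalence 1/(1+k), sensitivity 1, so F1 = 2/(2+k).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 / (2.0 + k)


def crossval(
    texts: Sequence[str] | WindowedDataset,
    labels: Sequence[int] | None = None,
    feature_mode: str = "tfidf",
    classifier_factory: Callable[[], BaseEstimator] | None = None,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
    embedding_table=None,
    max_features: int = 10_000,
) -> ClassificationMetrics:
    """Repeated stratified k-fold user-level classification.

    Per repeat: seeded stratified folds, transformer + classifier fit on
    the training folds only, out-of-fold predictions pooled into one
    PPV/sensitivity/F1 triple.  Means and SDs are taken across repeats.
    The default classifier is a linear-kernel SVM.
    """
    if isinstance(texts, WindowedDataset):
        labels = texts.labels
        texts = texts.texts
    y = np.asarray(labels, dtype=int)
    X = list(texts)
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValueError(f"need at least {folds} users per class")
    if classifier_factory is None:
        classifier_factory = lambda: LinearSVC(random_state=0)  # noqa: E731

    per_repeat: list[ClassificationMetrics] = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        pred = np.empty_like(y)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            pipe = Pipeline([
                ("features", make_feature_pipeline(feature_mode, embedding_table,
                                                   max_features)),
                ("clf", clone(classifier_factory())),
            ])
            try:
                pipe.fit([X[i] for i in tr], y[tr])
                pred[te] = pipe.predict([X[i] for i in te])
            except Exception as exc:
                raise RuntimeError(
                    f"classifier failed on repeat {r}, fold {fold}: {exc}"
                ) from exc
        per_repeat.append(metrics(pred, y))

    def _agg(attr):
        vals = np.array([getattr(m, attr) for m in per_repeat])
        return float(vals.mean()), float(vals.std(ddof=1)) if repeats > 1 else 0.0

    (ppv, ppv_sd) = _agg("ppv")
    (sens, sens_sd) = _agg("sensitivity")
    (f1, f1_sd) = _agg("f1")
    return ClassificationMetrics(ppv, sens, f1, ppv_sd, sens_sd, f1_sd, per_repeat)


# --------------------------------------------------------------------
# sliding-window chunking for bounded-context scorers


@dataclass(frozen=True)
class ChunkingConfig:
    window_tokens: int = 512
    stride_tokens: int = 512
    aggregation: str = "mean_probability"

    def __post_init__(self) -> None:
        if not 1 <= self.stride_tokens <= self.window_tokens:
            raise ValueError("need 1 <= stride_tokens <= window_tokens")
        if self.aggregation != "mean_probability":
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass(frozen=True)
class ChunkAggregate:
    probability: float
    n_chunks: int
    flag: str | None = None

    @property
    def decision(self) -> int:
        return int(self.probability >= 0.5)


def chunk_and_aggregate(
    tokens: Sequence[str],
    config: ChunkingConfig,
    scorer: Callable[[Sequence[str]], float],
) -> ChunkAggregate:
    """Split a token sequence into bounded windows, score each, and
    aggregate by mean probability (decision threshold 0.5).

    The final partial window is kept; empty input yields probability
    0.5 flagged ``"no content"``.
    """
    tokens = list(tokens)
    if not tokens:
        return ChunkAggregate(probability=0.5, n_chunks=0, flag="no content")
    probs = []
    start = 0
    while start < len(tokens):
        probs.append(float(scorer(tokens[start:start + config.window_tokens])))
        if start + config.window_tokens >= len(tokens):
            break
        start += config.stride_tokens
    return ChunkAggregate(probability=float(np.mean(probs)), n_chunks=len(probs))


# --------------------------------------------------------------------
# misclassification profiling


@dataclass
class ErrorProfile:
    topic_words: list[str]
    top_tfidf: list[str]
    vocabulary_counts: dict[str, dict[str, int]]


def error_profile(
    user: UserRecord,
    reference_vocabularies: Mapping[str, Sequence[str]],
    n_topic_words: int = 5,
    cohort_texts: Sequence[str] | None = None,
    n_tfidf: int = 10,
    seed: int = 0,
) -> ErrorProfile:
    """Lexical profile of one (mis)classified user: the chief topic of
    their posts (single-topic LDA), their top TF-IDF terms against the
    cohort, and occurrence counts of each reference-vocabulary term."""
    if not user.posts:
        raise ValueError(f"user {user.user_id!r} has no posts")
    docs = [concat_user_text(UserRecord(user.user_id, [p], user.label))
            for p in user.posts]

    cv = CountVectorizer(token_pattern=r"\S+", lowercase=True)
    counts = cv.fit_transform(docs)
    lda = LatentDirichletAllocation(n_components=1, random_state=seed)
    lda.fit(counts)
    vocab = np.asarray(cv.get_feature_names_out())
    topic_words = vocab[np.argsort(lda.components_[0])[::-1][:n_topic_words]].tolist()

    user_text = concat_user_text(user)
    fit_corpus = list(cohort_texts) if cohort_texts else docs
    if user_text not in fit_corpus:
        fit_corpus = fit_corpus + [user_text]
    tfidf = TfidfVectorizer(token_pattern=r"\S+", lowercase=True)
    tfidf.fit(fit_corpus)
    weights = tfidf.transform([user_text]).toarray()[0]
    terms = np.asarray(tfidf.get_feature_names_out())
    top_tfidf = terms[np.argsort(weights)[::-1][:n_tfidf]].tolist()
    top_tfidf = [t for t, w in zip(top_tfidf,
                                   sorted(weights, reverse=True)) if w > 0]

    tokens = [t.lower() for t in tokenize(user_text)]
    from collections import Counter
    tok_counts = Counter(tokens)
    vocab_counts = {
        cls: {term: tok_counts.get(term.lower(), 0) for term in terms_}
        for cls, terms_ in reference_vocabularies.items()
    }
    return ErrorProfile(topic_words, top_tfidf, vocab_counts)
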