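import datetime as dt

import numpy as np
import pytest

from conftest import make_user
from prodromal_text.corpus_io import Post, UserRecord
from prodromal_text.temporal_classify import (
    ChunkingConfig,
    HashedRandomEmbedding,
    MeanEmbeddingVectorizer,
    build_windowed_dataset,
    chunk_and_aggregate,
    crossval,
    error_profile,
    features,
    metrics,
    naive_baseline_f1,
    window_posts,
)

REF = dt.date(2015, 6, 1)


def _user_with_offsets(day_offsets, label="depressed"):
    posts = [Post("u", REF - dt.timedelta(days=o), f"post {o}")
             for o in day_offsets]
    return UserRecord("u", posts, label)


class TestWindowing:
    def test_weeks_window_half_open(self):
        user = _user_with_offsets([1, 14, 15, 28, 0])
        got = {(REF - p.date).days for p in window_posts(user, REF, weeks=2)}
        assert got == {1, 14}  # day 0 (reference) and day 15 excluded

    def test_band_boundaries(self):
        user = _user_with_offsets([27, 28, 35, 55])
        b0 = {(REF - p.date).days for p in window_posts(user, REF, band=0)}
        b1 = {(REF - p.date).days for p in window_posts(user, REF, band=1)}
        assert b0 == {27}
        assert b1 == {28, 35, 55}  # exactly 28 days falls in band 4-8, not 0-4

    def test_post_beyond_24_weeks_in_no_band(self):
        user = _user_with_offsets([25 * 7])
        assert all(not window_posts(user, REF, band=b) for b in range(6))

    def test_bands_partition_final_24_weeks(self):
        rng = np.random.default_rng(0)
        user = _user_with_offsets(rng.integers(0, 200, size=300).tolist())
        in_window = [p for p in user.posts
                     if REF - dt.timedelta(weeks=24) < p.date < REF]
        band_members = [window_posts(user, REF, band=b) for b in range(6)]
        assert sum(len(b) for b in band_members) == len(in_window)
        seen = [id(p) for b in band_members for p in b]
        assert len(seen) == len(set(seen))  # disjoint

    def test_exactly_one_mode_required(self):
        user = _user_with_offsets([1])
        with pytest.raises(ValueError):
            window_posts(user, REF, weeks=2, band=0)
        with pytest.raises(ValueError):
            window_posts(user, REF)


class TestMetrics:
    def test_all_correct(self):
        m = metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert (m.ppv, m.sensitivity, m.f1) == (1.0, 1.0, 1.0)

    def test_all_positive_on_balanced_design(self):
        m = metrics([1, 1], [1, 0])
        assert m.ppv == 0.5 and m.sensitivity == 1.0
        assert m.f1 == pytest.approx(0.667, abs=5e-4)

    def test_all_positive_on_one_to_ten(self):
        labels = [1] + [0] * 10
        m = metrics([1] * 11, labels)
        assert m.ppv == pytest.approx(0.091, abs=5e-4)
        assert m.f1 == pytest.approx(0.167, abs=5e-4)

    def test_zero_denominators(self):
        m = metrics([0, 0], [1, 0])
        assert m.ppv == 0.0 and m.sensitivity == 0.0 and m.f1 == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metrics([], [])

    @pytest.mark.parametrize("k", range(1, 11))
    def test_naive_closed_form_equals_measured_f1(self, k):
        """2/(2+k) is exactly the F1 of all-positive predictions on any
        1:k cohort."""
        labels = ([1] + [0] * k) * 7
        measured = metrics([1] * len(labels), labels).f1
        assert measured == naive_baseline_f1(k)


class TestFeatures:
    def test_identical_documents_identical_vectors(self):
        X = features(["aa bb cc", "aa bb cc", "aa cc cc"], mode="tfidf")
        assert np.allclose(X.toarray()[0], X.toarray()[1])

    def test_embedding_of_singleton_is_token_vector(self):
        table = HashedRandomEmbedding(dim=16, seed=0)
        vec = MeanEmbeddingVectorizer(table, dim=16).fit([]).transform(["word"])
        assert np.allclose(vec[0], table.get("word"))

    def test_embedding_table_deterministic(self):
        a = HashedRandomEmbedding(dim=8, seed=1).get("token")
        b = HashedRandomEmbedding(dim=8, seed=1).get("token")
        assert np.array_equal(a, b)
        c = HashedRandomEmbedding(dim=8, seed=2).get("token")
        assert not np.array_equal(a, c)

    def test_planted_lexicons_cluster_in_embedding_space(self, small_corpus,
                                                         small_cohort):
        ds = build_windowed_dataset(small_cohort)
        X = features(ds.texts, mode="embedding")
        X = X / np.linalg.norm(X, axis=1, keepdims=True)
        sim = X @ X.T
        y = ds.labels
        within = np.concatenate([sim[np.ix_(y == c, y == c)].ravel()
                                 for c in (0, 1)])
        between = sim[np.ix_(y == 0, y == 1)].ravel()
        assert within.mean() > between.mean()


class TestCrossval:
    def test_perfect_separation_reaches_f1_one(self):
        texts = [f"apple fruit {i}" for i in range(10)] + \
                [f"engine motor {i}" for i in range(10)]
        labels = [1] * 10 + [0] * 10
        m = crossval(texts, labels, repeats=2, seed=0)
        assert m.f1 == 1.0

    def test_no_signal_hovers_at_chance(self):
        """Identical text distribution in both classes: across label
        shuffles the mean F1 sits in the chance band for a 1:1 design."""
        rng = np.random.default_rng(0)
        words = ["aa", "bb", "cc", "dd", "ee"]
        texts = [" ".join(rng.choice(words, size=30)) for _ in range(30)]
        f1s = []
        for s in range(20):
            labels = np.array([1] * 15 + [0] * 15)
            rng.shuffle(labels)
            f1s.append(crossval(texts, labels, repeats=1, seed=s).f1)
        assert 0.3 < np.mean(f1s) < 0.7

    def test_stratified_folds(self):
        from sklearn.model_selection import StratifiedKFold
        y = np.array([1] * 14 + [0] * 42)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        global_ratio = y.mean()
        for _, te in skf.split(np.zeros(len(y)), y):
            n_pos = y[te].sum()
            assert abs(n_pos - global_ratio * len(te)) <= 1

    def test_too_few_users_rejected(self):
        with pytest.raises(ValueError):
            crossval(["x"] * 6, [1, 1, 1, 0, 0, 0], folds=5)


class TestChunking:
    def test_chunk_counts(self):
        cfg = ChunkingConfig(window_tokens=512, stride_tokens=512)
        agg = chunk_and_aggregate(["t"] * 1000, cfg, scorer=lambda c: 0.5)
        assert agg.n_chunks == 2
        short = chunk_and_aggregate(["t"] * 10, cfg, scorer=lambda c: 0.9)
        assert short.n_chunks == 1 and short.probability == 0.9

    def test_mean_aggregation_and_decision(self):
        cfg = ChunkingConfig(window_tokens=2, stride_tokens=2)
        probs = iter([0.8, 0.4])
        agg = chunk_and_aggregate(["a", "b", "c"], cfg,
                                  scorer=lambda c: next(probs))
        assert agg.probability == pytest.approx(0.6)
        assert agg.decision == 1

    def test_empty_text_flagged(self):
        agg = chunk_and_aggregate([], ChunkingConfig(), scorer=lambda c: 0.0)
        assert agg.probability == 0.5 and agg.flag == "no content"

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            ChunkingConfig(window_tokens=4, stride_tokens=5)


class TestErrorProfile:
    def test_vocabulary_counts(self):
        user = make_user("u", 2, "control", text="team played team game")
        prof = error_profile(user, {"control": ["team", "game", "shiny"],
                                    "depressed": ["feel"]})
        assert prof.vocabulary_counts["control"] == {"team": 4, "game": 2,
                                                     "shiny": 0}
        assert prof.vocabulary_counts["depressed"] == {"feel": 0}

    def test_dominant_words_surface_in_topic_and_tfidf(self):
        user = make_user("u", 6, "control", text="god jesus people amen")
        prof = error_profile(user, {}, n_topic_words=3)
        assert set(prof.topic_words) <= {"god", "jesus", "people", "amen"}
        assert "god" in prof.top_tfidf

    def test_user_without_posts_rejected(self):
        with pytest.raises(ValueError):
            error_profile(UserRecord("u", [], "control"), {})
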