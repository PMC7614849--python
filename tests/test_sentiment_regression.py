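import datetime as dt

import numpy as np
import pandas as pd
import pytest

from conftest import make_user
from prodromal_text.corpus_io import Post
from prodromal_text.sentiment_regression import (
    LexiconSentimentScorer,
    band_percentages,
    fit_multinomial,
    fit_sentimentality_logistic,
    label_sentiment,
    make_observations,
    or_from_beta,
)
from prodromal_text.synthetic_data import simulate_sentiment_observations


class TestOddsRatio:
    @pytest.mark.parametrize("beta, expected", [
        (0.163, 1.177),
        (0.190, 1.209),
        (0.151, 1.163),
        (0.0, 1.0),
    ])
    def test_exp_beta_at_three_decimals(self, beta, expected):
        assert round(or_from_beta(beta), 3) == expected


class TestLexiconScorer:
    def test_empty_text_is_neutral(self):
        assert label_sentiment(Post("u", dt.date(2015, 1, 1), "")) == "neutral"

    def test_signed_token_sums(self):
        scorer = LexiconSentimentScorer()
        assert scorer("sad awful lonely") == "negative"
        assert scorer("happy great") == "positive"
        assert scorer("sad happy") == "neutral"  # balanced evidence
        assert scorer("the game was fine") == "neutral"

    def test_recovers_planted_labels_on_generated_corpus(self, small_corpus):
        users, _, truth = small_corpus
        scorer = LexiconSentimentScorer()
        hits = total = 0
        for user in users[:60]:
            planted = truth.post_sentiments[user.user_id]
            for post, want in zip(user.posts, planted):
                hits += scorer(post.text) == want
                total += 1
        assert hits / total > 0.95


@pytest.fixture(scope="module")
def cohort_observations(small_corpus, small_cohort):
    _, _, truth = small_corpus
    return make_observations(small_cohort, sentiments=truth.post_sentiments)


class TestObservations:
    def test_sentimental_is_not_neutral_indicator(self, cohort_observations):
        obs = cohort_observations
        assert (obs["sentimental"] == (obs["sentiment"] != "neutral")).all()

    def test_band_assignment_matches_weeks(self, cohort_observations):
        obs = cohort_observations.dropna(subset=["band"])
        assert (obs["band"].astype(int) ==
                (obs["time_weeks"] // 4).astype(int)).all()
        assert (cohort_observations.loc[
            cohort_observations["band"].isna(), "time_weeks"] >= 24).all()

    def test_sentiment_list_mismatch_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="mismatch"):
            make_observations(small_cohort,
                              sentiments={u.user_id: ["neutral"]
                                          for u, _ in small_cohort.cases})


class TestBandPercentages:
    def _obs(self, rows):
        return pd.DataFrame(rows, columns=["user_id", "diagnosis", "time_weeks",
                                           "word_count", "sentiment",
                                           "sentimental", "band"])

    def test_all_neutral_gives_zero_everywhere(self):
        rows = [("u", 1, 1.0, 5, "neutral", 0, 0)] * 4
        bp = band_percentages(self._obs(rows))
        assert (bp["negative"] == 0).all() and (bp["positive"] == 0).all()
        assert (bp["neutral"] == 100).all()

    def test_two_of_four_negative_is_fifty_percent(self):
        rows = [("u", 1, 1.0, 5, s, int(s != "neutral"), 0)
                for s in ["negative", "negative", "neutral", "positive"]]
        bp = band_percentages(self._obs(rows))
        assert bp.loc[(1, 0), "negative"] == pytest.approx(50.0)

    def test_shares_sum_to_hundred(self, cohort_observations):
        bp = band_percentages(cohort_observations)
        assert np.allclose(bp[["negative", "neutral", "positive"]].sum(axis=1),
                           100.0)

    def test_case_negativity_peaks_in_band_one(self, cohort_observations):
        bp = band_percentages(cohort_observations)
        case_neg = bp.loc[1]["negative"]
        assert case_neg.idxmax() == 1


class TestLogisticMixed:
    def test_recovers_planted_effects(self):
        obs = simulate_sentiment_observations(
            n_cases=150, n_controls=150, posts_per_user=60,
            diagnosis_log_odds=0.163, wordcount_log_odds=0.04, seed=21)
        tab = fit_sentimentality_logistic(obs)
        diag = tab["diagnosis"]
        assert abs(diag["beta"] - 0.163) < 2 * diag["se"]
        assert tab["word_count"]["beta"] == pytest.approx(0.04, abs=0.03)
        assert tab.table["odds_ratio"].equals(np.exp(tab.table["beta"]))
        assert tab.random_intercept_sd == pytest.approx(0.3, abs=0.1)

    def test_fixed_effects_only_path(self):
        obs = simulate_sentiment_observations(n_cases=100, n_controls=100,
                                              posts_per_user=30, seed=4,
                                              user_intercept_sd=0.0)
        mixed = fit_sentimentality_logistic(obs)
        plain = fit_sentimentality_logistic(obs, random_intercept_by_user=False)
        assert np.allclose(mixed.table["beta"], plain.table["beta"], atol=1e-3)

    def test_needs_two_users_per_class(self):
        obs = simulate_sentiment_observations(n_cases=1, n_controls=5,
                                              posts_per_user=10, seed=0)
        with pytest.raises(ValueError, match="2 users"):
            fit_sentimentality_logistic(obs)


@pytest.fixture(scope="module")
def multinomial_obs():
    return simulate_sentiment_observations(
        n_cases=100, n_controls=100, posts_per_user=40, seed=8,
        negative_share=0.5, user_intercept_sd=0.0)


class TestMultinomial:
    @pytest.fixture()
    def obs(self, multinomial_obs):
        return multinomial_obs

    def test_series_fit_equals_joint_multinomial_on_two_categories(self, obs):
        """The positive-vs-neutral table from the series implementation
        matches a joint multinomial MLE restricted to those two
        categories (independent route via statsmodels MNLogit)."""
        import statsmodels.api as sm
        series = fit_multinomial(obs)["positive"]
        # same standardized design the series fit uses (full-table moments)
        t = obs["time_weeks"].to_numpy(float)
        w = obs["word_count"].to_numpy(float)
        d = obs["diagnosis"].to_numpy(float)
        t = (t - t.mean()) / t.std()
        w = (w - w.mean()) / w.std()
        X = np.column_stack([np.ones(len(obs)), d, t, w, d * t])
        mask = obs["sentiment"].isin(["positive", "neutral"]).to_numpy()
        y = (obs.loc[mask, "sentiment"] == "positive").astype(int).to_numpy()
        mn = sm.MNLogit(y, X[mask]).fit(disp=0)
        assert np.allclose(mn.params.ravel(), series.table["beta"], atol=1e-6)

    def test_symmetric_generation_gives_indistinguishable_diagnosis_effects(
            self, obs):
        tables = fit_multinomial(obs)
        pos = tables["positive"]["diagnosis"]
        neg = tables["negative"]["diagnosis"]
        joint_se = np.hypot(pos["se"], neg["se"])
        assert abs(pos["beta"] - neg["beta"]) < 2 * joint_se

    def test_reference_category_excluded_from_outputs(self, obs):
        tables = fit_multinomial(obs)
        assert set(tables) == {"positive", "negative"}

    def test_missing_category_rejected(self, obs):
        with pytest.raises(ValueError, match="missing"):
            fit_multinomial(obs[obs["sentiment"] != "positive"])
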