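import datetime as dt

import numpy as np
import pytest

from conftest import make_user
from prodromal_text.cohort_builder import (
    DEFAULT_RECENCY_RULES,
    ZeroActivityError,
    build_cohort,
    estimate_diagnosis_date,
    match_controls,
    temporal_subset,
    validate_case,
)
from prodromal_text.corpus_io import CorpusError, DiagnosisAnnotation, Post, UserRecord


class TestEstimateDiagnosisDate:
    @pytest.mark.parametrize("recency", [0, 1])
    def test_unusable_categories_yield_no_estimate(self, recency):
        ann = DiagnosisAnnotation("u", dt.date(2015, 6, 1), recency)
        assert estimate_diagnosis_date(ann) is None

    @pytest.mark.parametrize("recency, expected", [
        (2, dt.date(2015, 5, 2)),    # 30 days
        (3, dt.date(2014, 10, 31)),  # 213 days
        (4, dt.date(2013, 6, 1)),    # 730 days
        (5, dt.date(2012, 6, 1)),    # 1095 days
    ])
    def test_offsets(self, recency, expected):
        ann = DiagnosisAnnotation("u", dt.date(2015, 6, 1), recency)
        assert estimate_diagnosis_date(ann) == expected

    def test_unknown_category_raises(self):
        ann = DiagnosisAnnotation("u", dt.date(2015, 6, 1), 5)
        with pytest.raises(CorpusError, match="unknown recency"):
            estimate_diagnosis_date(ann, rules={2: DEFAULT_RECENCY_RULES[2]})


class TestValidateCase:
    def _ann(self):
        return DiagnosisAnnotation("u", dt.date(2015, 6, 1), 3)

    def test_inside_window_is_valid(self):
        user = make_user("u", 5, "depressed", start=dt.date(2014, 1, 1))
        assert validate_case(user, dt.date(2015, 1, 1), self._ann())

    def test_estimate_before_first_post_invalid(self):
        user = make_user("u", 5, "depressed", start=dt.date(2014, 1, 1))
        assert not validate_case(user, dt.date(2013, 12, 1), self._ann())

    def test_boundaries_are_strict(self):
        user = make_user("u", 5, "depressed", start=dt.date(2014, 1, 1))
        assert not validate_case(user, dt.date(2014, 1, 1), self._ann())
        assert not validate_case(user, dt.date(2015, 6, 1), self._ann())

    def test_no_posts_raises(self):
        with pytest.raises(CorpusError, match="no posts"):
            validate_case(UserRecord("u", [], "depressed"),
                          dt.date(2015, 1, 1), self._ann())


class TestMatchControls:
    EST = dt.date(2015, 1, 1)

    def _case(self, n=100):
        return (make_user("case", n, "depressed", start=dt.date(2014, 1, 1),
                          step_days=1), self.EST)

    def test_boundary_inclusive_at_exactly_15_percent(self):
        pool = [make_user("c115", 115)]
        assert match_controls(self._case(100), pool, k=1) is not None

    def test_just_over_tolerance_rejected(self):
        pool = [make_user("c116", 116)]
        assert match_controls(self._case(100), pool, k=1) is None

    def test_matched_removed_from_pool_unmatched_kept(self):
        pool = [make_user(f"c{i}", n) for i, n in
                enumerate([100, 110, 90, 200, 300])]
        matched = match_controls(self._case(100), pool, k=3, rng=0)
        assert matched is not None and len(matched) == 3
        assert len(pool) == 2
        assert all(len(u.posts) in (200, 300) for u in pool)

    def test_shortfall_leaves_pool_untouched(self):
        pool = [make_user("c1", 100), make_user("c2", 400)]
        assert match_controls(self._case(100), pool, k=2) is None
        assert len(pool) == 2

    def test_zero_pre_diagnosis_posts_signalled(self):
        late = make_user("case", 5, "depressed", start=dt.date(2015, 2, 1))
        with pytest.raises(ZeroActivityError):
            match_controls((late, self.EST), [make_user("c", 5)], k=1)

    def test_seeded_order_deterministic(self):
        mk = lambda: [make_user(f"c{i}", 100 + i) for i in range(12)]
        a = match_controls(self._case(100), mk(), k=5, rng=42)
        b = match_controls(self._case(100), mk(), k=5, rng=42)
        assert [u.user_id for u in a] == [u.user_id for u in b]


class TestBuildCohort:
    def test_cohort_invariants_on_generated_corpus(self, small_cohort,
                                                   small_config):
        k = small_config.controls_per_case
        assert small_cohort.k == k
        assert small_cohort.n_users == (1 + k) * len(small_cohort.cases)
        small_cohort.validate()  # tolerance + control uniqueness

    def test_matching_deterministic_given_seed(self, small_corpus):
        users, anns, _ = small_corpus
        a = build_cohort(users, anns, k=3, seed=9)
        b = build_cohort(users, anns, k=3, seed=9)
        assert [u.user_id for u, _ in a.cases] == [u.user_id for u, _ in b.cases]
        assert {u: [c.user_id for c in v] for u, v in a.controls.items()} == \
               {u: [c.user_id for c in v] for u, v in b.controls.items()}

    def test_unusable_recency_excluded_with_reason(self):
        user = make_user("d0", 50, "depressed", start=dt.date(2014, 1, 1))
        ann = DiagnosisAnnotation("d0", dt.date(2015, 6, 1), 0)
        cohort = build_cohort([user], [ann], k=1)
        assert cohort.exclusion_ledger["d0"] == "recency_unusable"
        assert cohort.cases == []

    def test_insufficient_controls_excluded_with_reason(self):
        user = make_user("d0", 50, "depressed", start=dt.date(2014, 1, 1))
        ann = DiagnosisAnnotation("d0", dt.date(2015, 6, 1), 3)
        pool = [make_user("c0", 500)]
        cohort = build_cohort([user] + pool, [ann], k=1)
        assert cohort.exclusion_ledger["d0"] == "insufficient_controls"

    def test_round_trip_json(self, tmp_path, small_cohort, small_corpus):
        path = tmp_path / "cohort.json"
        small_cohort.to_json(path)
        from prodromal_text.cohort_builder import MatchedCohort
        back = MatchedCohort.from_json(path, small_corpus[0])
        assert back.n_users == small_cohort.n_users
        back.validate()


class TestTemporalSubset:
    def test_case_inactive_in_final_window_excluded(self):
        est = dt.date(2015, 1, 1)
        case = UserRecord("d0", [Post("d0", est - dt.timedelta(weeks=3), "x"),
                                 Post("d0", est - dt.timedelta(weeks=30), "y")],
                          "depressed")
        ctrl = UserRecord("c0", [Post("c0", est - dt.timedelta(days=3), "z")],
                          "control")
        from prodromal_text.cohort_builder import MatchedCohort
        cohort = MatchedCohort(cases=[(case, est)], controls={"d0": [ctrl]}, k=1)
        out = temporal_subset(cohort, window_weeks=2, k_out=1)
        assert out.cases == []
        assert out.exclusion_ledger["d0"] == "inactive_final_window"

    def test_controls_reduced_to_exactly_k_out(self, small_cohort):
        out = temporal_subset(small_cohort, window_weeks=2, k_out=1, seed=4)
        for user, _ in out.cases:
            assert len(out.controls[user.user_id]) == 1
        assert out.n_users == 2 * len(out.cases)

    def test_subsampling_deterministic(self, small_cohort):
        a = temporal_subset(small_cohort, k_out=2, seed=8)
        b = temporal_subset(small_cohort, k_out=2, seed=8)
        assert {u: [c.user_id for c in v] for u, v in a.controls.items()} == \
               {u: [c.user_id for c in v] for u, v in b.controls.items()}

    def test_invalid_k_out(self, small_cohort):
        with pytest.raises(ValueError):
            temporal_subset(small_cohort, k_out=0)
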