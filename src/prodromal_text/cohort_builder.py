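"""Matched case-control cohort construction from recency-annotated
diagnosis disclosures.

The derivation has three steps:

1. *Date estimation* — a disclosure post's date minus an offset implied
   by its categorical recency code gives the estimated diagnosis date.
   Codes 0 ("unspecified") and 1 ("in the past") admit no estimate and
   those users are dropped.
2. *Validity filter* — the estimate must fall strictly between the
   user's first observed post and the disclosure post itself, otherwise
   it carries no usable pre-diagnosis signal.
3. *Matching* — for each retained case, k control users are sought whose
   number of posts before the case's estimated diagnosis date differs
   from the case's by at most a tolerance fraction (default 15%, taken
   relative to the case).  Candidates are examined sequentially in
   seeded random order, first-accept; a matched control is never reused
   for another case.  Cases for which fewer than k matches exist are
   excluded.

:func:`temporal_subset` further restricts a cohort to users with recent
activity (at least one post in the final weeks before the reference
date), re-balancing controls to an exact ratio, as required by
risk-window experiments.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import CorpusError, DiagnosisAnnotation, UserRecord

__all__ = [
    "RecencyRule",
    "DEFAULT_RECENCY_RULES",
    "MatchedCohort",
    "estimate_diagnosis_date",
    "validate_case",
    "match_controls",
    "build_cohort",
    "temporal_subset",
]


@dataclass(frozen=True)
class RecencyRule:
    """Offset convention for one recency category.

    Categories with bounded intervals use the interval midpoint as the
    point estimate; the open-ended top category uses its lower bound.
    """

    category: int
    offset_days: int | None
    usable: bool

    def __post_init__(self) -> None:
        if self.usable and (self.offset_days is None or self.offset_days <= 0):
            raise ValueError(f"usable category {self.category} needs a positive offset")


#: category -> rule: 0 unspecified / 1 "in the past" are unusable;
#: 2 "up to 2 months"   -> 30 d  (midpoint of 0-61 d)
#: 3 "2 months-1 year"  -> 213 d (midpoint of 61-365 d)
#: 4 "1-3 years"        -> 730 d (midpoint of 365-1095 d)
#: 5 ">3 years"         -> 1095 d (lower bound; interval unbounded)
DEFAULT_RECENCY_RULES: dict[int, RecencyRule] = {
    0: RecencyRule(0, None, False),
    1: RecencyRule(1, None, False),
    2: RecencyRule(2, 30, True),
    3: RecencyRule(3, 213, True),
    4: RecencyRule(4, 730, True),
    5: RecencyRule(5, 1095, True),
}


class ZeroActivityError(CorpusError):
    """Case has no posts before its estimated diagnosis date."""


def estimate_diagnosis_date(
    ann: DiagnosisAnnotation,
    rules: Mapping[int, RecencyRule] = DEFAULT_RECENCY_RULES,
) -> _dt.date | None:
    """Point estimate of the diagnosis date, or ``None`` when the recency
    category admits no estimate (categories 0 and 1 by default)."""
    try:
        rule = rules[ann.recency]
    except KeyError as exc:
        raise CorpusError(f"unknown recency category {ann.recency}") from exc
    if not rule.usable:
        return None
    return ann.diagnosis_post_date - _dt.timedelta(days=rule.offset_days)


def validate_case(
    user: UserRecord, est_date: _dt.date, ann: DiagnosisAnnotation
) -> bool:
    """True iff ``first_post < est_date < diagnosis_post`` (both strict)."""
    if not user.posts:
        raise CorpusError(f"user {user.user_id!r} has no posts")
    return user.first_post_date < est_date < ann.diagnosis_post_date


def match_controls(
    case: tuple[UserRecord, _dt.date],
    pool: list[UserRecord],
    k: int,
    tolerance: float = 0.15,
    rng: np.random.Generator | int | None = 0,
) -> list[UserRecord] | None:
    """First-accept matching of ``k`` controls on pre-diagnosis post count.

    Candidates are taken in a seeded random order; candidate ``c``
    matches case count ``d`` iff ``|c - d| / d <= tolerance`` (the
    denominator is the case's count).  On success the matched controls
    are removed from ``pool`` and returned; on shortfall ``None`` is
    returned and the pool is left untouched.

    Raises :class:`ZeroActivityError` when the case has no posts before
    its estimated diagnosis date (the ratio is undefined).
    """
    user, est_date = case
    d = user.post_count_before(est_date)
    if d == 0:
        raise ZeroActivityError(
            f"case {user.user_id!r} has no posts before {est_date}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    order = rng.permutation(len(pool))
    matched_idx: list[int] = []
    for i in order:
        c = pool[i].post_count_before(est_date)
        if abs(c - d) / d <= tolerance:
            matched_idx.append(i)
            if len(matched_idx) == k:
                break
    if len(matched_idx) < k:
        return None
    matched = [pool[i] for i in matched_idx]
    for i in sorted(matched_idx, reverse=True):
        del pool[i]
    return matched


@dataclass
class MatchedCohort:
    """Cases with their matched controls and the exclusion ledger.

    ``controls`` maps a case's user_id to its k matched controls, each
    of which inherits the case's estimated diagnosis date as reference
    date for every downstream temporal computation.
    """

    cases: list[tuple[UserRecord, _dt.date]]
    controls: dict[str, list[UserRecord]]
    k: int
    tolerance: float = 0.15
    exclusion_ledger: dict[str, str] = field(default_factory=dict)

    @property
    def n_users(self) -> int:
        return len(self.cases) + sum(len(v) for v in self.controls.values())

    def members(self) -> list[tuple[UserRecord, int, _dt.date]]:
        """Flat view: (user, label 1=case / 0=control, reference date)."""
        out: list[tuple[UserRecord, int, _dt.date]] = []
        for user, est in self.cases:
            out.append((user, 1, est))
            for ctrl in self.controls[user.user_id]:
                out.append((ctrl, 0, est))
        return out

    def validate(self) -> None:
        seen: set[str] = set()
        for user, est in self.cases:
            ctrls = self.controls.get(user.user_id)
            if ctrls is None or len(ctrls) != self.k:
                raise CorpusError(
                    f"case {user.user_id!r} has {0 if ctrls is None else len(ctrls)}"
                    f" controls, expected {self.k}"
                )
            d = user.post_count_before(est)
            for ctrl in ctrls:
                if ctrl.user_id in seen:
                    raise CorpusError(f"control {ctrl.user_id!r} reused")
                seen.add(ctrl.user_id)
                c = ctrl.post_count_before(est)
                if d == 0 or abs(c - d) / d > self.tolerance:
                    raise CorpusError(
                        f"pair ({user.user_id!r}, {ctrl.user_id!r}) violates "
                        f"tolerance: |{c}-{d}|/{d} > {self.tolerance}"
                    )

    def to_json(self, path: str | Path) -> None:
        obj = {
            "k": self.k,
            "tolerance": self.tolerance,
            "cases": [
                {
                    "user_id": u.user_id,
                    "estimated_diagnosis_date": est.isoformat(),
                    "control_ids": [c.user_id for c in self.controls[u.user_id]],
                }
                for u, est in self.cases
            ],
            "exclusion_ledger": self.exclusion_ledger,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(
        cls, path: str | Path, users: Iterable[UserRecord]
    ) -> "MatchedCohort":
        by_id = {u.user_id: u for u in users}
        obj = json.loads(Path(path).read_text())
        cases = []
        controls = {}
        for c in obj["cases"]:
            cases.append((by_id[c["user_id"]],
                          _dt.date.fromisoformat(c["estimated_diagnosis_date"])))
            controls[c["user_id"]] = [by_id[i] for i in c["control_ids"]]
        return cls(cases=cases, controls=controls, k=obj["k"],
                   tolerance=obj.get("tolerance", 0.15),
                   exclusion_ledger=obj.get("exclusion_ledger", {}))


def build_cohort(
    users: Sequence[UserRecord],
    annotations: Sequence[DiagnosisAnnotation],
    k: int = 10,
    tolerance: float = 0.15,
    seed: int = 0,
    rules: Mapping[int, RecencyRule] = DEFAULT_RECENCY_RULES,
) -> MatchedCohort:
    """Full derivation: estimate dates, filter, and match 1:k.

    Depressed users without an annotation, with an unusable recency
    code, with an estimate outside their posting history, with no
    pre-diagnosis posts, or with fewer than ``k`` in-tolerance
    candidates are excluded with a reason code in the ledger.
    """
    rng = np.random.default_rng(seed)
    ann_by_id = {a.user_id: a for a in annotations}
    pool = [u for u in users if u.label == "control"]
    cohort = MatchedCohort(cases=[], controls={}, k=k, tolerance=tolerance)

    for user in users:
        if user.label != "depressed":
            continue
        ann = ann_by_id.get(user.user_id)
        if ann is None:
            cohort.exclusion_ledger[user.user_id] = "no_annotation"
            continue
        est = estimate_diagnosis_date(ann, rules)
        if est is None:
            cohort.exclusion_ledger[user.user_id] = "recency_unusable"
            continue
        if not user.posts:
            cohort.exclusion_ledger[user.user_id] = "no_posts"
            continue
        if not validate_case(user, est, ann):
            cohort.exclusion_ledger[user.user_id] = "estimate_outside_history"
            continue
        try:
            matched = match_controls((user, est), pool, k, tolerance, rng)
        except ZeroActivityError:
            cohort.exclusion_ledger[user.user_id] = "no_pre_diagnosis_posts"
            continue
        if matched is None:
            cohort.exclusion_ledger[user.user_id] = "insufficient_controls"
            continue
        cohort.cases.append((user, est))
        cohort.controls[user.user_id] = matched
    return cohort


def temporal_subset(
    cohort: MatchedCohort,
    window_weeks: int = 2,
    k_out: int = 3,
    seed: int = 0,
) -> MatchedCohort:
    """Restrict to users with at least one post in the final
    ``window_weeks`` before the reference date, and rebalance to exactly
    ``k_out`` controls per case (seeded random subsampling).

    Cases without recent activity, and cases left with fewer than
    ``k_out`` recently-active controls, are dropped with ledger codes.
    """
    if k_out <= 0:
        raise ValueError("k_out must be positive")
    rng = np.random.default_rng(seed)
    window = _dt.timedelta(weeks=window_weeks)
    out = MatchedCohort(cases=[], controls={}, k=k_out, tolerance=cohort.tolerance,
                        exclusion_ledger=dict(cohort.exclusion_ledger))

    def active(user: UserRecord, est: _dt.date) -> bool:
        lo = est - window
        return any(lo <= p.date < est for p in user.posts)

    for user, est in cohort.cases:
        if not active(user, est):
            out.exclusion_ledger[user.user_id] = "inactive_final_window"
            continue
        eligible = [c for c in cohort.controls[user.user_id] if active(c, est)]
        if len(eligible) < k_out:
            out.exclusion_ledger[user.user_id] = "insufficient_active_controls"
            continue
        keep = rng.choice(len(eligible), size=k_out, replace=False)
        out.cases.append((user, est))
        out.controls[user.user_id] = [eligible[i] for i in sorted(keep)]
    return out
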