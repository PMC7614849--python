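"""Hypergeometric lexical specificity for subcorpus profiling.

For a term with global frequency F in a corpus of N tokens, observed f
times in a subcorpus of n tokens, the specificity score is

    score = -log10 P(X >= f),   X ~ Hypergeometric(N, F, n)

i.e. the surprise (in decimal orders of magnitude) of seeing the term
at least f times in the subcorpus if tokens were exchangeable.  Only
over-representation is scored: when f is at or below the expected count
n*F/N the score is 0.  The tail is accumulated in log space using
log-gamma binomial coefficients, so scores remain finite and ordered
even when the probability underflows any floating-point representation
(corpus-scale scores can reach tens of thousands of decimal orders).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .corpus_io import UserRecord, tokenize

__all__ = [
    "SubcorpusCounts",
    "SpecificityScore",
    "lemmatize_and_count",
    "specificity",
    "rank_terms",
    "relative_frequency",
]

_LN10 = np.log(10.0)
#: tail terms smaller than this fraction of the running maximum are negligible
_TAIL_RTOL = 1e-16
_BLOCK = 2048


def _log_binom(a: float, b: np.ndarray | float) -> np.ndarray | float:
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def specificity(f: int, F: int, n: int, N: int) -> float:
    """-log10 of the hypergeometric upper-tail probability P(X >= f).

    Returns 0.0 for terms not over-represented (f at or below the
    expected count n*F/N, including f = 0).  Raises ``ValueError`` when
    the count invariants f <= F, f <= n, F <= N, n <= N, n >= 1 fail.
    """
    if not (0 <= f <= F <= N and f <= n <= N and n >= 1):
        raise ValueError(
            f"invalid counts: f={f}, F={F}, n={n}, N={N} "
            "(need 0 <= f <= F <= N, f <= n <= N, n >= 1)"
        )
    if f == 0 or f * N <= n * F:  # at/below expectation: not over-represented
        return 0.0
    k_max = min(n, F)
    log_denom = _log_binom(N, n)

    log_total = -np.inf
    log_peak = -np.inf
    k = f
    while k <= k_max:
        ks = np.arange(k, min(k + _BLOCK, k_max + 1), dtype=float)
        terms = _log_binom(F, ks) + _log_binom(N - F, n - ks) - log_denom
        block_total = float(np.logaddexp.reduce(terms))
        log_total = float(np.logaddexp(log_total, block_total))
        log_peak = max(log_peak, float(terms.max()))
        # stop once the block has fallen far below the accumulated peak
        # (hypergeometric tails decay super-geometrically past the mode)
        if terms[-1] < log_peak + np.log(_TAIL_RTOL):
            break
        k += _BLOCK
    return max(0.0, -log_total / _LN10)


@dataclass(frozen=True)
class SpecificityScore:
    term: str
    score: float
    f: int


class SubcorpusCounts:
    """Token counts per class subcorpus against the pooled corpus."""

    def __init__(self, class_counts: dict[str, Counter]) -> None:
        self.class_counts = class_counts
        self.class_totals = {c: sum(cnt.values()) for c, cnt in class_counts.items()}
        self.global_counts: Counter = Counter()
        for cnt in class_counts.values():
            self.global_counts.update(cnt)
        self.N = sum(self.global_counts.values())

    def counts_for(self, term: str, cls: str) -> tuple[int, int, int, int]:
        """(f, n, F, N) for one term in one subcorpus."""
        return (
            self.class_counts[cls][term],
            self.class_totals[cls],
            self.global_counts[term],
            self.N,
        )

    @property
    def classes(self) -> list[str]:
        return list(self.class_counts)


def lemmatize_and_count(
    users: Iterable[UserRecord],
    lemmatizer: Callable[[str], str] | None = None,
) -> SubcorpusCounts:
    """Lemma counts per class subcorpus.

    ``lemmatizer`` maps a token to its lemma; the default lowercases
    (identity lemmatization), keeping the core dependency-light while
    accepting any richer pluggable mapper.
    """
    lemmatizer = lemmatizer or str.lower
    class_counts: dict[str, Counter] = {}
    for user in users:
        counter = class_counts.setdefault(user.label, Counter())
        for post in user.posts:
            counter.update(lemmatizer(tok) for tok in tokenize(post.text))
    return SubcorpusCounts(class_counts)


def rank_terms(
    counts: SubcorpusCounts, top_m: int = 10
) -> dict[str, list[SpecificityScore]]:
    """Top ``top_m`` terms per class by descending specificity.

    Ties break by descending subcorpus frequency, then lexicographic
    term.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    out: dict[str, list[SpecificityScore]] = {}
    for cls in counts.classes:
        n = counts.class_totals[cls]
        scored = []
        for term, f in counts.class_counts[cls].items():
            F = counts.global_counts[term]
            scored.append(SpecificityScore(term, specificity(f, F, n, counts.N), f))
        scored.sort(key=lambda s: (-s.score, -s.f, s.term))
        out[cls] = scored[:top_m]
    return out


def relative_frequency(f: int, n: int) -> float:
    """Share of the subcorpus made up by a term, as a percentage."""
    if n < 1:
        raise ValueError("subcorpus size n must be >= 1")
    return 100.0 * f / n
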