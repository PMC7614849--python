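"""Default token inventories for the synthetic corpus generator and the
lexicon sentiment scorer.

The class-specific lists follow the qualitative pattern seen in forum
depression corpora: prospective cases over-use first-person, affective
and relationship vocabulary, while controls over-use hobby/community
vocabulary (gaming, trading).  Weights are Zipf-like ranks, normalised
at load time.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CASE_TERMS",
    "CONTROL_TERMS",
    "BACKGROUND_TERMS",
    "NEGATIVE_VALENCE",
    "POSITIVE_VALENCE",
    "as_distribution",
]

# Over-represented in the depressed subcorpus.
CASE_TERMS = (
    "people", "know", "thing", "feel", "time",
    "woman", "go", "want", "life", "relationship",
)

# Over-represented in the control subcorpus.
CONTROL_TERMS = (
    "game", "trade", "key", "team", "play",
    "player", "shiny", "hatch", "thank", "add",
)

# Shared filler vocabulary, used by both classes.
BACKGROUND_TERMS = (
    "the", "i", "to", "a", "and", "of", "it", "in", "is", "that",
    "my", "for", "you", "was", "on", "with", "this", "but", "have", "not",
    "be", "so", "at", "they", "just", "like", "what", "when", "we", "there",
    "about", "get", "me", "if", "one", "do", "all", "would", "really", "out",
)

# Valence inventories: the generator emits these in step with each
# post's planted sentiment; the default scorer counts them with signs.
NEGATIVE_VALENCE = (
    "sad", "hopeless", "tired", "awful", "miserable",
    "lonely", "worthless", "anxious", "crying", "empty",
)
POSITIVE_VALENCE = (
    "happy", "great", "love", "excited", "wonderful",
    "proud", "fun", "amazing", "grateful", "cheerful",
)


def as_distribution(terms) -> tuple[tuple[str, ...], np.ndarray]:
    """Zipf-weighted probability table over ``terms`` (rank r gets 1/r)."""
    if isinstance(terms, dict):
        words = tuple(terms)
        w = np.asarray([terms[t] for t in words], dtype=float)
    else:
        words = tuple(terms)
        w = 1.0 / np.arange(1, len(words) + 1)
    if len(words) == 0 or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("lexicon must be non-empty with positive weights")
    return words, w / w.sum()
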