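"""Data model and JSONL I/O for forum-user post histories.

A corpus is a set of users, each a dated sequence of posts carrying a
binary class label (``depressed`` / ``control``).  Users who disclose a
diagnosis additionally carry an annotation giving the date of the
disclosure post and a categorical *recency* code (0-5) describing how
long before that post the diagnosis happened.

File formats (one JSON object per line):

``users.jsonl``
    ``{"user_id": str, "label": "depressed"|"control",
    "posts": [["YYYY-MM-DD", "text"], ...]}``

``annotations.jsonl``
    ``{"user_id": str, "diagnosis_post_date": "YYYY-MM-DD", "recency": 0-5}``

Text normalization follows the convention used throughout the package:
every quotation character becomes a single apostrophe and every line
break becomes a space, so a post (and a user's concatenated history) is
always a single-line string.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

__all__ = [
    "Post",
    "UserRecord",
    "DiagnosisAnnotation",
    "Label",
    "normalize_text",
    "tokenize",
    "concat_user_text",
    "read_users",
    "write_users",
    "read_annotations",
    "write_annotations",
]

VALID_LABELS = ("depressed", "control")
Label = str

# Quotation characters collapsed to an apostrophe: straight double quote,
# curly single/double quotes, and backtick.  U+0027 maps to itself.
_QUOTE_TABLE = str.maketrans({
    '"': "'",  # straight double quote
    "‘": "'",  # left single quote
    "’": "'",  # right single quote
    "“": "'",  # left double quote
    "”": "'",  # right double quote
    "`": "'",  # backtick
    "\n": " ",
    "\r": " ",
})


def normalize_text(raw: str) -> str:
    """Return ``raw`` with quotation characters collapsed to ``'`` and
    line breaks replaced by spaces (one space per replaced character).

    Idempotent and total; the result contains no ``\\n`` or ``\\r``.
    """
    return raw.translate(_QUOTE_TABLE)


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization of normalized text (the package-wide
    definition of a "word")."""
    return normalize_text(text).split()


class CorpusError(ValueError):
    """Raised on malformed or invalid corpus records."""


@dataclass(frozen=True)
class Post:
    """A single forum post at day resolution."""

    author_id: str
    date: _dt.date
    text: str

    @property
    def word_count(self) -> int:
        """Whitespace-token count of the normalized text."""
        return len(tokenize(self.text))


@dataclass
class UserRecord:
    """One user's labelled, date-ordered post history."""

    user_id: str
    posts: list[Post]
    label: Label

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise CorpusError(
                f"user {self.user_id!r}: unknown label {self.label!r}; "
                f"expected one of {VALID_LABELS}"
            )
        self.posts = sorted(self.posts, key=lambda p: p.date)

    @property
    def first_post_date(self) -> _dt.date:
        if not self.posts:
            raise CorpusError(f"user {self.user_id!r} has no posts")
        return self.posts[0].date

    def post_count_before(self, cutoff: _dt.date) -> int:
        """Number of posts strictly before ``cutoff``."""
        return sum(1 for p in self.posts if p.date < cutoff)


@dataclass(frozen=True)
class DiagnosisAnnotation:
    """Recency-coded diagnosis disclosure for one user.

    ``recency`` codes: 0 unspecified; 1 in the past; 2 up to 2 months
    ago; 3 between 2 months and 1 year ago; 4 between 1 and 3 years
    ago; 5 more than 3 years ago.
    """

    user_id: str
    diagnosis_post_date: _dt.date
    recency: int

    def __post_init__(self) -> None:
        if self.recency not in range(6):
            raise CorpusError(
                f"user {self.user_id!r}: recency {self.recency!r} not in 0-5"
            )


def concat_user_text(
    user: UserRecord,
    subset: Callable[[Post], bool] | None = None,
) -> str:
    """Normalized texts of the selected posts joined by single spaces,
    in chronological order.  Empty selection yields ``""``.
    """
    posts = user.posts if subset is None else [p for p in user.posts if subset(p)]
    return " ".join(normalize_text(p.text) for p in posts)


def _parse_date(s: str, where: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(s)
    except (TypeError, ValueError) as exc:
        raise CorpusError(f"{where}: invalid date {s!r}") from exc


def _iter_jsonl(path: str | Path) -> Iterator[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            if not isinstance(obj, dict):
                raise CorpusError(f"{path}:{lineno}: expected a JSON object")
            yield lineno, obj


def read_users(path: str | Path) -> list[UserRecord]:
    """Read and validate a ``users.jsonl`` file.

    Posts are re-sorted by date; malformed lines raise :class:`CorpusError`
    naming the line number.
    """
    users: list[UserRecord] = []
    for lineno, obj in _iter_jsonl(path):
        try:
            uid = str(obj["user_id"])
            posts = [
                Post(author_id=uid, date=_parse_date(d, f"user {uid}"), text=str(t))
                for d, t in obj.get("posts", [])
            ]
            users.append(UserRecord(user_id=uid, posts=posts, label=obj["label"]))
        except (KeyError, TypeError) as exc:
            raise CorpusError(f"{path}:{lineno}: invalid user record: {exc}") from exc
    return users


def write_users(users: Iterable[UserRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in users:
            fh.write(json.dumps({
                "user_id": u.user_id,
                "label": u.label,
                "posts": [[p.date.isoformat(), p.text] for p in u.posts],
            }, ensure_ascii=False) + "\n")


def read_annotations(path: str | Path) -> list[DiagnosisAnnotation]:
    """Read and validate an ``annotations.jsonl`` file."""
    anns: list[DiagnosisAnnotation] = []
    for lineno, obj in _iter_jsonl(path):
        try:
            anns.append(DiagnosisAnnotation(
                user_id=str(obj["user_id"]),
                diagnosis_post_date=_parse_date(
                    obj["diagnosis_post_date"], f"{path}:{lineno}"),
                recency=int(obj["recency"]),
            ))
        except (KeyError, TypeError) as exc:
            raise CorpusError(f"{path}:{lineno}: invalid annotation: {exc}") from exc
    return anns


def write_annotations(
    annotations: Iterable[DiagnosisAnnotation], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(json.dumps({
                "user_id": a.user_id,
                "diagnosis_post_date": a.diagnosis_post_date.isoformat(),
                "recency": a.recency,
            }) + "\n")
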