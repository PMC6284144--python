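"""Tweet corpus containers and I/O.

A corpus is an ordered collection of short messages collected over a fixed
window (here, a single World AIDS Day), each carrying the metadata that
infoveillance pipelines rely on: message type (an original "unique" tweet
vs. a forwarded retweet), the author's follower count (used to estimate the
audience a message was disseminated to), a language tag and a timestamp.

Two interchangeable on-disk formats are supported: a header-row CSV with
RFC-4180 quoting, and a record-per-line JSON ("records") format with the
same field names.  Reading never silently drops data — malformed records
are counted and reported on the returned corpus.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Literal

import warnings

__all__ = [
    "Tweet",
    "Corpus",
    "SchemaError",
    "read_corpus",
    "write_corpus",
    "filter_language",
    "dedupe_unique",
    "aggregate_reach",
    "top_disseminators",
]

REQUIRED_FIELDS = (
    "id",
    "text",
    "timestamp",
    "username",
    "message_type",
    "follower_count",
    "language",
)

MAX_TWEET_CHARS = 280


class SchemaError(ValueError):
    """A corpus file is missing required fields."""


@dataclass(frozen=True)
class Tweet:
    """One short message with collection metadata."""

    id: str
    text: str
    timestamp: datetime
    username: str
    message_type: Literal["unique", "retweet"]
    follower_count: int
    language: str
    location: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("text must be non-empty")
        if self.follower_count < 0:
            raise ValueError("follower_count must be >= 0")
        if self.message_type not in ("unique", "retweet"):
            raise ValueError(f"unknown message_type {self.message_type!r}")
        if len(self.text) > MAX_TWEET_CHARS:
            warnings.warn(
                f"tweet {self.id} exceeds {MAX_TWEET_CHARS} characters",
                stacklevel=2,
            )


@dataclass
class Corpus:
    """A labeled, ordered tweet collection for one timepoint.

    ``n_unique`` counts messages flagged as originals; ``reach`` is the sum
    of follower counts over *all* messages (originals and retweets), the
    corpus-level dissemination summary.
    """

    label: str
    tweets: list[Tweet]
    n_malformed: int = 0
    n_unique: int = field(init=False)
    reach: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_unique = sum(1 for t in self.tweets if t.message_type == "unique")
        self.reach = sum(t.follower_count for t in self.tweets)
        if self.n_unique > len(self.tweets):  # pragma: no cover - arithmetic
            raise ValueError("n_unique exceeds message count")

    def __len__(self) -> int:
        return len(self.tweets)


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


def _tweet_from_record(rec: dict) -> Tweet:
    return Tweet(
        id=str(rec["id"]),
        text=str(rec["text"]),
        timestamp=_parse_timestamp(str(rec["timestamp"])),
        username=str(rec["username"]),
        message_type=str(rec["message_type"]),
        follower_count=int(rec["follower_count"]),
        language=str(rec["language"]),
        location=(str(rec["location"]) if rec.get("location") else None),
    )


def read_corpus(
    path: str | Path,
    format: Literal["delimited", "records"] = "delimited",
    label: str | None = None,
) -> Corpus:
    """Read a corpus from ``path``.

    ``delimited`` is header-row CSV; ``records`` is one JSON object per
    line.  Records that violate the tweet invariants (empty text, negative
    follower count, bad enum/timestamp) are excluded and tallied in the
    returned corpus's ``n_malformed``.

    Raises
    ------
    SchemaError
        If any required field is absent from the header / first record.
    """
    path = Path(path)
    if format == "delimited":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [f for f in REQUIRED_FIELDS if f not in header]
            if missing:
                raise SchemaError(f"missing required fields: {', '.join(missing)}")
            raw_records: list[dict] = list(reader)
    elif format == "records":
        raw_records = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    raw_records.append(json.loads(line))
        if raw_records:
            missing = [f for f in REQUIRED_FIELDS if f not in raw_records[0]]
            if missing:
                raise SchemaError(f"missing required fields: {', '.join(missing)}")
    else:
        raise ValueError(f"unknown format {format!r}")

    tweets: list[Tweet] = []
    n_malformed = 0
    for rec in raw_records:
        try:
            tweets.append(_tweet_from_record(rec))
        except (ValueError, KeyError, TypeError):
            n_malformed += 1
    return Corpus(
        label=label if label is not None else path.stem,
        tweets=tweets,
        n_malformed=n_malformed,
    )


def write_corpus(
    corpus: Corpus,
    path: str | Path,
    format: Literal["delimited", "records"] = "delimited",
) -> None:
    """Write a corpus in either supported format (UTF-8)."""
    path = Path(path)
    rows = [
        {
            "id": t.id,
            "text": t.text,
            "timestamp": t.timestamp.isoformat(),
            "username": t.username,
            "message_type": t.message_type,
            "follower_count": t.follower_count,
            "language": t.language,
            "location": t.location or "",
        }
        for t in corpus.tweets
    ]
    fields = list(REQUIRED_FIELDS) + ["location"]
    if format == "delimited":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "records":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def filter_language(corpus: Corpus, keep: str) -> Corpus:
    """Keep only tweets whose language tag equals ``keep`` (case-insensitive),
    preserving order."""
    keep_cf = keep.casefold()
    kept = [t for t in corpus.tweets if t.language.casefold() == keep_cf]
    return Corpus(label=corpus.label, tweets=kept, n_malformed=corpus.n_malformed)


_RT_PREFIX = re.compile(r"^\s*rt\s+@\w+\s*:?\s*", re.IGNORECASE)
_WS = re.compile(r"\s+")


def canonical_text(text: str) -> str:
    """Strip any leading ``RT @user:`` prefix, normalize whitespace, casefold."""
    stripped = _RT_PREFIX.sub("", text)
    return _WS.sub(" ", stripped).strip().casefold()


def dedupe_unique(
    corpus: Corpus, by: Literal["text", "flag"] = "text"
) -> tuple[Corpus, list[int]]:
    """Collapse retweet duplicates onto their original message.

    In the default ``text`` mode a message is unique if its canonical text
    (leading retweet prefix stripped, whitespace-normalized, case-folded)
    has not been seen before; later messages with the same canonical text
    collapse onto that first occurrence.  ``flag`` mode instead trusts the
    collector's ``message_type`` field: every message flagged "unique" is
    kept, and retweets collapse onto the first kept message with a matching
    canonical text (or are kept themselves if none exists).

    Returns the corpus of unique tweets plus, aligned with it, the number
    of messages that collapsed onto each.  Message count is conserved:
    ``sum(1 + c for c in counts) == len(corpus)``.
    """
    uniques: list[Tweet] = []
    counts: list[int] = []
    seen: dict[str, int] = {}
    for tweet in corpus.tweets:
        key = canonical_text(tweet.text)
        if by == "flag" and tweet.message_type == "unique":
            seen.setdefault(key, len(uniques))
            uniques.append(tweet)
            counts.append(0)
            continue
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(uniques)
            uniques.append(tweet)
            counts.append(0)
    deduped = Corpus(
        label=corpus.label, tweets=uniques, n_malformed=corpus.n_malformed
    )
    return deduped, counts


def aggregate_reach(corpus: Corpus) -> int:
    """Total follower count summed over all messages — the corpus "reach"."""
    return sum(t.follower_count for t in corpus.tweets)


def top_disseminators(corpus: Corpus, k: int) -> list[tuple[str, int]]:
    """The ``k`` usernames with the largest summed follower counts,
    descending; ties broken lexicographically by username."""
    if k < 1:
        raise ValueError("k must be >= 1")
    totals: dict[str, int] = {}
    for t in corpus.tweets:
        totals[t.username] = totals.get(t.username, 0) + t.follower_count
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def concat(label: str, corpora: Iterable[Corpus]) -> Corpus:
    """Concatenate corpora in order under a new label."""
    tweets: list[Tweet] = []
    n_malformed = 0
    for c in corpora:
        tweets.extend(c.tweets)
        n_malformed += c.n_malformed
    return Corpus(label=label, tweets=tweets, n_malformed=n_malformed)
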