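"""Synthetic tweet corpora with planted hierarchical topic structure.

Real World AIDS Day tweet streams are not redistributable, so every
downstream stage is exercised on generated corpora whose ground truth is
known.  Each unique document draws its tokens from a mixture of a leaf
topic's word distribution and a shared Zipfian background; each leaf topic
carries *anchor words* that are (near-)impossible under the other topics,
so a successful clustering must isolate them.  Retweets duplicate an
existing unique document verbatim behind an ``RT @user:`` prefix, follower
counts follow a discretized log-normal (a heavy tail that reproduces
billions-scale aggregate reach from modest corpus sizes), and timestamps
fall inside a single-day window.

Recovery of the planted structure is scored with the adjusted Rand index
and cluster purity.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.cluster import contingency_matrix

from .corpus import Corpus, Tweet

__all__ = [
    "SyntheticSpec",
    "SpecValidationError",
    "default_spec",
    "sample_corpus",
    "evaluate_recovery",
    "write_labels",
    "read_labels",
]


class SpecValidationError(ValueError):
    """A SyntheticSpec field violates its invariant (the message names it)."""


@dataclass
class SyntheticSpec:
    """Full description of a plantable corpus.

    ``topic_word_dists`` maps each leaf topic id to a categorical
    distribution over ``vocabulary``; ``anchor_words`` lists, per topic,
    terms whose probability under every other topic is at most one tenth
    of their own.  ``background_mix`` is the per-token probability of
    drawing from the Zipfian ``background_dist`` instead of the topic.
    ``doc_length_dist`` is an inclusive uniform integer range (support must
    stay within [3, 50]).  ``topic_tree`` records the planted hierarchy as
    a nested tuple of leaf topic ids.
    """

    n_docs: int
    vocabulary: list[str]
    topic_tree: tuple
    topic_word_dists: dict[int, np.ndarray]
    anchor_words: dict[int, list[str]]
    background_dist: np.ndarray
    background_mix: float = 0.2
    doc_length_dist: tuple[int, int] = (8, 20)
    retweet_rate: float = 0.4
    follower_dist: tuple[float, float] = (6.0, 2.5)  # log-normal (mu, sigma)
    timestamp_window: tuple[datetime, datetime] = (
        datetime(2014, 12, 1, tzinfo=timezone.utc),
        datetime(2014, 12, 2, tzinfo=timezone.utc),
    )
    topic_weights: dict[int, float] | None = None
    seed: int = 0
    label: str = "synthetic"

    def leaf_topics(self) -> list[int]:
        return sorted(self.topic_word_dists)

    def validate(self) -> None:
        if self.n_docs < 1:
            raise SpecValidationError("n_docs must be a positive integer")
        if not 0.0 <= self.background_mix <= 1.0:
            raise SpecValidationError("background_mix must lie in [0, 1]")
        if not 0.0 <= self.retweet_rate <= 1.0:
            raise SpecValidationError("retweet_rate must lie in [0, 1]")
        lo, hi = self.doc_length_dist
        if lo < 3 or hi > 50 or lo > hi:
            raise SpecValidationError(
                "doc_length_dist support must lie within [3, 50]"
            )
        nv = len(self.vocabulary)
        if abs(float(self.background_dist.sum()) - 1.0) > 1e-9:
            raise SpecValidationError("background_dist must sum to 1")
        if self.background_dist.shape != (nv,):
            raise SpecValidationError("background_dist length must match vocabulary")
        index = {w: i for i, w in enumerate(self.vocabulary)}
        for topic, dist in self.topic_word_dists.items():
            if dist.shape != (nv,):
                raise SpecValidationError(
                    f"topic_word_dists[{topic}] length must match vocabulary"
                )
            if abs(float(dist.sum()) - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"topic_word_dists[{topic}] must sum to 1"
                )
            if np.any(dist < 0):
                raise SpecValidationError(
                    f"topic_word_dists[{topic}] must be nonnegative"
                )
        for topic, words in self.anchor_words.items():
            own = self.topic_word_dists[topic]
            for w in words:
                i = index[w]
                for other, dist in self.topic_word_dists.items():
                    if other != topic and dist[i] * 10.0 > own[i] + 1e-15:
                        raise SpecValidationError(
                            f"anchor_words[{topic}] term {w!r} is not >=10x "
                            f"more probable than under topic {other}"
                        )

    def expected_token_prob(self, topic: int, word: str) -> float:
        """Per-token probability of ``word`` in a topic-``topic`` document
        under the generating mixture."""
        i = self.vocabulary.index(word)
        return (1.0 - self.background_mix) * float(
            self.topic_word_dists[topic][i]
        ) + self.background_mix * float(self.background_dist[i])


# Hashtag-like realistic terms mixed into the shared background vocabulary
# so end-to-end demos read plausibly.
_HASHTAG_TERMS = [
    "worldaidsday",
    "hivawareness",
    "endaids",
    "knowyourstatus",
    "getested",
    "redribbon",
]


def default_spec(
    n_docs: int = 1000,
    n_topics: int = 4,
    background_mix: float = 0.2,
    retweet_rate: float = 0.4,
    seed: int = 0,
    label: str = "synthetic",
    topic_weights: dict[int, float] | None = None,
) -> SyntheticSpec:
    """A ready-made spec with ``n_topics`` leaf topics in a balanced planted
    hierarchy (pairs of leaves share a branch vocabulary), 2 anchors per
    topic, 20 topic words per topic, 10 shared words per branch and a
    150-word Zipfian background."""
    if n_topics < 2 or n_topics % 2:
        raise SpecValidationError("n_topics must be an even integer >= 2")
    n_branch = n_topics // 2
    anchors = {t: [f"topic{t}anchor{j}" for j in range(2)] for t in range(n_topics)}
    topic_words = {
        t: [f"t{t}w{j:02d}" for j in range(20)] for t in range(n_topics)
    }
    branch_words = {b: [f"branch{b}w{j}" for j in range(10)] for b in range(n_branch)}
    background_words = [f"w{j:04d}" for j in range(150 - len(_HASHTAG_TERMS))]
    background_words = _HASHTAG_TERMS + background_words

    vocabulary: list[str] = []
    for t in range(n_topics):
        vocabulary.extend(anchors[t])
        vocabulary.extend(topic_words[t])
    for b in range(n_branch):
        vocabulary.extend(branch_words[b])
    vocabulary.extend(background_words)
    index = {w: i for i, w in enumerate(vocabulary)}
    nv = len(vocabulary)

    # Zipfian background over the shared background words.
    ranks = np.arange(1, len(background_words) + 1, dtype=np.float64)
    zipf = 1.0 / ranks**1.1
    zipf /= zipf.sum()
    background = np.zeros(nv)
    for w, p in zip(background_words, zipf):
        background[index[w]] = p

    dists: dict[int, np.ndarray] = {}
    for t in range(n_topics):
        d = np.zeros(nv)
        for w in anchors[t]:
            d[index[w]] = 0.08  # anchors: 16% of topic-token mass
        for w in topic_words[t]:
            d[index[w]] = 0.72 / 20.0
        for w in branch_words[t // 2]:
            d[index[w]] = 0.12 / 10.0
        d /= d.sum()
        dists[t] = d

    tree = tuple(
        (2 * b, 2 * b + 1) for b in range(n_branch)
    )
    return SyntheticSpec(
        n_docs=n_docs,
        vocabulary=vocabulary,
        topic_tree=tree,
        topic_word_dists=dists,
        anchor_words=anchors,
        background_dist=background,
        background_mix=background_mix,
        retweet_rate=retweet_rate,
        seed=seed,
        label=label,
        topic_weights=topic_weights,
    )


def sample_corpus(spec: SyntheticSpec) -> tuple[Corpus, np.ndarray]:
    """Draw a corpus from ``spec``: ``n_docs`` unique documents plus
    ``floor(retweet_rate * n_docs)`` retweet duplicates, fully reproducible
    from ``spec.seed``.  Returns the corpus and, aligned with its tweets,
    the planted leaf-topic id of every message (retweets inherit their
    source's topic)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    topics = spec.leaf_topics()
    if spec.topic_weights is None:
        weights = np.full(len(topics), 1.0 / len(topics))
    else:
        weights = np.array([spec.topic_weights[t] for t in topics], dtype=np.float64)
        weights /= weights.sum()

    vocab = np.asarray(spec.vocabulary, dtype=object)
    lo, hi = spec.doc_length_dist
    start, end = spec.timestamp_window
    window = (end - start).total_seconds()
    mu, sigma = spec.follower_dist

    tweets: list[Tweet] = []
    labels: list[int] = []
    n_users = max(spec.n_docs // 2, 10)

    doc_topics = rng.choice(topics, size=spec.n_docs, p=weights)
    for i in range(spec.n_docs):
        t = int(doc_topics[i])
        length = int(rng.integers(lo, hi + 1))
        from_bg = rng.random(length) < spec.background_mix
        words = np.empty(length, dtype=object)
        n_bg = int(from_bg.sum())
        if n_bg:
            words[from_bg] = rng.choice(vocab, size=n_bg, p=spec.background_dist)
        if length - n_bg:
            words[~from_bg] = rng.choice(
                vocab, size=length - n_bg, p=spec.topic_word_dists[t]
            )
        tweets.append(
            Tweet(
                id=f"{spec.label}-{i:06d}",
                text=" ".join(words),
                timestamp=start + timedelta(seconds=float(rng.random() * window)),
                username=f"user{int(rng.integers(n_users))}",
                message_type="unique",
                follower_count=int(rng.lognormal(mu, sigma)),
                language="en",
            )
        )
        labels.append(t)

    n_retweets = int(spec.retweet_rate * spec.n_docs)
    for j in range(n_retweets):
        src = int(rng.integers(spec.n_docs))
        origin = tweets[src]
        tweets.append(
            Tweet(
                id=f"{spec.label}-rt{j:06d}",
                text=f"RT @{origin.username}: {origin.text}",
                timestamp=start + timedelta(seconds=float(rng.random() * window)),
                username=f"user{int(rng.integers(n_users))}",
                message_type="retweet",
                follower_count=int(rng.lognormal(mu, sigma)),
                language="en",
            )
        )
        labels.append(int(doc_topics[src]))

    return Corpus(label=spec.label, tweets=tweets), np.asarray(labels)


def evaluate_recovery(
    predicted_labels, planted_labels
) -> dict[str, float]:
    """Adjusted Rand index and cluster purity of a predicted partition
    against the planted topics.  Both metrics are invariant to relabeling
    of the predicted clusters."""
    pred = np.asarray(predicted_labels)
    true = np.asarray(planted_labels)
    if pred.shape != true.shape:
        raise ValueError("label sequences must have the same length")
    if pred.size < 2:
        raise ValueError("need at least 2 labels")
    cont = contingency_matrix(true, pred)
    purity = float(cont.max(axis=0).sum() / cont.sum())
    return {
        "ari": float(adjusted_rand_score(true, pred)),
        "purity": purity,
    }


def write_labels(path: str | Path, doc_ids: list[str], labels) -> None:
    """Two-column (doc id, topic id) tab-delimited file."""
    lines = [f"{d}\t{l}" for d, l in zip(doc_ids, labels, strict=True)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    labels: list[int] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line:
            d, l = line.split("\t")
            ids.append(d)
            labels.append(int(l))
    return ids, np.asarray(labels)
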