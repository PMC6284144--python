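from datetime import datetime, timezone

import pytest

from hiertweet.corpus import Corpus, Tweet
from hiertweet.textprep import PrepOptions


def make_tweet(
    id="t0",
    text="hello world",
    username="alice",
    message_type="unique",
    follower_count=10,
    language="en",
    hour=12,
):
    return Tweet(
        id=id,
        text=text,
        timestamp=datetime(2014, 12, 1, hour, tzinfo=timezone.utc),
        username=username,
        message_type=message_type,
        follower_count=follower_count,
        language=language,
    )


@pytest.fixture
def unigram_prep():
    """Unigrams, no stopword removal beyond defaults, raw counts."""
    return PrepOptions(
        ngram_min=1, ngram_max=1, min_term_docfreq=1,
        weighting="tf", normalize_docs=False,
    )


@pytest.fixture
def twelve_tweet_corpus():
    """Hand-built 12-message fixture with two retweet chains.

    Messages 0-9 are originals; messages 10 and 11 retweet messages 0 and
    1 respectively, and message 9 duplicates message 0's text verbatim
    while still flagged unique.  Canonical-text dedup therefore yields 9
    unique tweets with collapse counts [2, 1, 0, 0, 0, 0, 0, 0, 0].

    Hand term counts over the 9 unique tweets (tweet-level containment,
    stemmed unigrams): "stigma" in 0,1,2,8 -> 4 (message 9 collapses into
    0); "fight" in 1,3,4 -> 3; "cure" in 2,3,5 -> 3; "hope" in 6,7,8 -> 3
    ("hope"/"hoping" both stem to hope).
    """
    texts = [
        "end stigma now",                     # 0
        "stigma and the fight",               # 1
        "cure research stigma",               # 2
        "fight for a cure today",             # 3
        "keep up the fight",                  # 4
        "cure is coming",                     # 5
        "hope for everyone",                  # 6
        "hoping for better days",             # 7
        "hope ends stigma",                   # 8
        "end stigma now",                     # 9 duplicate text, flagged unique
    ]
    tweets = [
        make_tweet(id=f"m{i}", text=t, username=f"u{i % 4}",
                   follower_count=100 * (i + 1))
        for i, t in enumerate(texts)
    ]
    tweets.append(
        make_tweet(id="m10", text="RT @u0: end stigma now",
                   username="u5", message_type="retweet", follower_count=50)
    )
    tweets.append(
        make_tweet(id="m11", text="RT @u1: stigma and the fight",
                   username="u6", message_type="retweet", follower_count=60)
    )
    return Corpus(label="fixture", tweets=tweets)
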