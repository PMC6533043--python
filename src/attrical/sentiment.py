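"""Lexicon-based tweet scoring and per-user emotion measurement.

Each tweet is scored on the integer scale [-4, 4] (negative = strength of
negative emotion, positive = strength of positive emotion, 0 = neutral).
A user's emotional state is the mean score over their original (non-retweet)
posts. Users enter the measured sample only if they pass the eligibility
filter: more than 10 original tweets and more than 50 tokens in total.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon

__all__ = [
    "TweetScore",
    "preprocess",
    "score_tweet",
    "score_post",
    "user_emotion",
    "eligibility_filter",
    "measure_emotions",
]

_STRIP_RE = re.compile(r"(?:@\S+|#\S+|https?://\S+|www\.\S+)")

MIN_TWEETS = 10  # eligibility requires strictly more than this
MIN_WORDS = 50  # and strictly more total tokens than this


@dataclass(frozen=True)
class TweetScore:
    """Score of a single tweet: value in [-4, 4], token count, usability flag."""

    value: int
    n_tokens: int
    used: bool


def preprocess(text: str) -> List[str]:
    """Strip @-mentions, #-hashtags and URLs, lower-case, split on whitespace."""
    cleaned = _STRIP_RE.sub(" ", text or "")
    return cleaned.lower().split()


def score_tweet(tokens: Sequence[str], lexicon: Lexicon) -> TweetScore:
    """Score a tokenised tweet.

    The positive strength P is the maximum positive lexicon strength over
    the tokens (default 1 when no positive term occurs); the negative
    strength N is the minimum negative strength (default -1). The tweet
    score is P + N, which lies in [-4, 4]. Tokens absent from the lexicon
    contribute nothing.
    """
    pos, neg = 1, -1
    for tok in tokens:
        s = lexicon.get(tok)
        if s is None:
            continue
        if s > pos:
            pos = s
        elif s < neg:
            neg = s
    return TweetScore(value=pos + neg, n_tokens=len(tokens), used=len(tokens) > 0)


def score_post(tokens: Sequence[str], is_retweet: bool, lexicon: Lexicon) -> TweetScore:
    """Score one post; retweets and empty posts are marked unusable."""
    score = score_tweet(tokens, lexicon)
    if is_retweet:
        return TweetScore(value=score.value, n_tokens=score.n_tokens, used=False)
    return score


def user_emotion(
    posts: Iterable[tuple[Sequence[str], bool]], lexicon: Lexicon
) -> Optional[float]:
    """Mean tweet score over a user's usable (original, non-empty) posts.

    ``posts`` yields (tokens, is_retweet) pairs. Returns None when the user
    has no usable post, in which case the user is flagged missing upstream.
    """
    values = [
        s.value
        for tokens, is_rt in posts
        if (s := score_post(tokens, is_rt, lexicon)).used
    ]
    if not values:
        return None
    return float(np.mean(values))


def eligibility_filter(posts: pd.DataFrame) -> pd.Index:
    """User ids with > MIN_TWEETS original posts and > MIN_WORDS total tokens.

    ``posts`` must have columns user_id, tokens (list of str), is_retweet.
    Both counts are taken after retweet exclusion.
    """
    originals = posts.loc[~posts["is_retweet"].astype(bool)]
    if originals.empty:
        return pd.Index([], name="user_id")
    grp = originals.groupby("user_id")
    n_tweets = grp.size()
    n_words = grp["tokens"].apply(lambda col: int(sum(len(t) for t in col)))
    keep = (n_tweets > MIN_TWEETS) & (n_words > MIN_WORDS)
    return pd.Index(n_tweets.index[keep], name="user_id")


def measure_emotions(posts: pd.DataFrame, lexicon: Lexicon) -> pd.DataFrame:
    """Per-user emotion table from a post stream.

    Returns a DataFrame indexed by user_id with columns ``emotion`` (mean
    tweet score over usable posts, NaN when no usable post) and
    ``n_tweets_in_use`` (the observational-bias covariate: how many tweets
    the emotion measurement is based on).
    """
    rows = {}
    for uid, sub in posts.groupby("user_id"):
        vals = [
            score_post(tokens, bool(is_rt), lexicon).value
            for tokens, is_rt in zip(sub["tokens"], sub["is_retweet"])
            if not bool(is_rt) and len(tokens) > 0
        ]
        rows[uid] = (float(np.mean(vals)) if vals else np.nan, len(vals))
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["emotion", "n_tweets_in_use"]
    )
    out.index.name = "user_id"
    out["n_tweets_in_use"] = out["n_tweets_in_use"].astype(int)
    return out.sort_index()
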