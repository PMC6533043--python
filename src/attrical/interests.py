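"""Hashtag-interest profiling and between-group similarity.

Users are grouped by dropout state or by emotion tercile; each group's
hashtag corpus is ranked by TF-IDF, and posting-interest similarity
between two groups is the Spearman rank correlation of their scores over
the union vocabulary, with absent tags scored 0 by contract.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Hashable, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError

__all__ = [
    "TagProfile",
    "emotion_terciles",
    "build_profiles",
    "rank_correlation",
    "correlation_matrix",
]

log = logging.getLogger(__name__)

TERCILE_LABELS = ("negative", "neutral", "positive")


@dataclass
class TagProfile:
    """TF-IDF scores of one group's hashtag corpus."""

    group: Hashable
    scores: Dict[str, float]  # tag -> tf * idf, nonzero tags only

    @property
    def n_tags(self) -> int:
        return len(self.scores)


def emotion_terciles(emotions: pd.Series) -> pd.Series:
    """Split users into three near-equal groups by emotion score.

    Users are ranked by emotion (ties broken by stable user-id order) and
    split into negative / neutral / positive thirds; when n is not a
    multiple of 3 the lower groups receive the extra users (10 users ->
    sizes 4/3/3 with the lowest-score group largest). Returns a Series of
    labels indexed like the input.
    """
    emo = emotions.dropna()
    if len(emo) < 3:
        raise DegenerateInputError("tercile split requires at least 3 scored users")
    if emo.nunique() == 1:
        warnings.warn("all emotion scores equal; terciles split by stable order", stacklevel=2)
    order = emo.sort_index(kind="stable").sort_values(kind="stable").index
    n = len(order)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = pd.Series(index=emo.index, dtype=object)
    start = 0
    for label, size in zip(TERCILE_LABELS, sizes):
        labels.loc[order[start : start + size]] = label
        start += size
    return labels.reindex(emotions.index)


def build_profiles(corpora: Mapping[Hashable, Iterable[str]]) -> Dict[Hashable, TagProfile]:
    """TF-IDF profiles for a comparison set of group corpora.

    ``corpora`` maps each group label to the flat sequence of hashtags in
    that group's posts (tags are lower-cased, compared exactly). With G
    groups, tf(t, group) is the tag count in the group's corpus and
    idf(t) = ln(1 + G / g_t) where g_t is the number of groups containing
    t — smoothed so that a ubiquitous tag keeps a small positive score.
    Tags absent from a group score 0 by contract (they simply do not appear
    in its profile). A group without hashtags yields an empty, flagged
    profile.
    """
    counts: Dict[Hashable, Dict[str, int]] = {}
    for group, tags in corpora.items():
        c: Dict[str, int] = {}
        for tag in tags:
            tag = tag.lower()
            c[tag] = c.get(tag, 0) + 1
        counts[group] = c
        if not c:
            log.warning("group %r has no hashtags; empty profile", group)
    G = len(counts)
    df_count: Dict[str, int] = {}
    for c in counts.values():
        for tag in c:
            df_count[tag] = df_count.get(tag, 0) + 1
    profiles = {}
    for group, c in counts.items():
        profiles[group] = TagProfile(
            group=group,
            scores={t: n * math.log(1.0 + G / df_count[t]) for t, n in c.items()},
        )
    return profiles


def _union_scores(a: TagProfile, b: TagProfile) -> Tuple[np.ndarray, np.ndarray]:
    union = sorted(set(a.scores) | set(b.scores))
    xa = np.array([a.scores.get(t, 0.0) for t in union])
    xb = np.array([b.scores.get(t, 0.0) for t in union])
    return xa, xb


def rank_correlation(
    a: TagProfile, b: TagProfile, method: str = "asymptotic"
) -> Tuple[float, float]:
    """Spearman rank correlation between two profiles over the union tag set.

    Tags absent from a profile are scored 0; average ranks resolve ties.
    ``method`` "asymptotic" uses the large-sample t approximation for the
    two-sided p-value; "exact" enumerates rank permutations (available for
    union vocabularies of at most 8 tags). Raises DegenerateInputError when
    the union has fewer than 3 tags or either score list has no rank
    variation.
    """
    xa, xb = _union_scores(a, b)
    if len(xa) < 3:
        raise DegenerateInputError("Spearman correlation needs >= 3 union tags")
    if np.all(xa == xa[0]) or np.all(xb == xb[0]):
        raise DegenerateInputError("no rank variation in at least one profile")
    rho, p = stats.spearmanr(xa, xb)
    if method == "exact":
        n = len(xa)
        if n > 8:
            raise ValueError("exact permutation p-value available only for <= 8 union tags")
        ra, rb = stats.rankdata(xa), stats.rankdata(xb)
        obs = abs(np.corrcoef(ra, rb)[0, 1])
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = abs(np.corrcoef(ra, rb[list(perm)])[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def correlation_matrix(
    row_profiles: Mapping[Hashable, TagProfile],
    col_profiles: Mapping[Hashable, TagProfile],
) -> pd.DataFrame:
    """Pairwise Spearman rho (p in a parallel frame) between two profile sets.

    Returns a DataFrame of (rho, p) tuples indexed by row group, one column
    per column group; degenerate pairs yield (NaN, NaN).
    """
    out = {}
    for rk, rp in row_profiles.items():
        row = {}
        for ck, cp in col_profiles.items():
            try:
                row[ck] = rank_correlation(rp, cp)
            except DegenerateInputError:
                row[ck] = (float("nan"), float("nan"))
        out[rk] = row
    return pd.DataFrame.from_dict(out, orient="index")
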