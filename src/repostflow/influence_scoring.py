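"""Per-user influence scores (h, g, hg) and quantile influence categories.

Reposts of a user's original posts play the role citations play in
bibliometrics.  The h index is the largest ``h`` such that the user's
h-th most-reposted post has at least ``h`` reposts; the g index is the
largest ``g`` (capped at the number of posts) such that the top ``g``
posts together collect at least ``g**2`` reposts; the hg index is
``sqrt(h * g)``, balancing consistent diffusion power against the scale
of the user's biggest hits.

Users are then binned into six influence categories by their position in
the hg distribution: very_high (top 1%), high (1-5%), upper_mid (5-10%),
mid (10-30%), lower_mid (30-50%), low (bottom 50%), each category
excluding its upper threshold.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

#: Influence categories, most influential first.
CATEGORIES = ["very_high", "high", "upper_mid", "mid", "lower_mid", "low"]

#: Upper percentile-fraction boundary of each category (exclusive).
_BOUNDARIES = [0.01, 0.05, 0.10, 0.30, 0.50, 1.0000001]


def _check_counts(repost_counts: Iterable[int]) -> np.ndarray:
    counts = np.asarray(list(repost_counts), dtype=np.int64)
    if counts.size and counts.min() < 0:
        raise ValueError("repost counts must be non-negative")
    return counts


def h_index(repost_counts: Iterable[int]) -> int:
    """Largest h such that at least h posts have >= h reposts each."""
    counts = _check_counts(repost_counts)
    if counts.size == 0:
        return 0
    desc = np.sort(counts)[::-1]
    ranks = np.arange(1, desc.size + 1)
    ok = desc >= ranks
    return int(ranks[ok][-1]) if ok.any() else 0


def g_index(repost_counts: Iterable[int], cap_at_n_posts: bool = True) -> int:
    """Largest g such that the top g posts total at least g**2 reposts.

    By default g is capped at the number of posts (Egghe's original
    convention), which preserves h <= g <= n_posts.  With
    ``cap_at_n_posts=False`` the cumulative total is extended past the
    last post (fictitious zero-repost posts), so a single 100-repost post
    yields g = 10 instead of 1.
    """
    counts = _check_counts(repost_counts)
    if counts.size == 0:
        return 0
    desc = np.sort(counts)[::-1]
    cum = np.cumsum(desc)
    n = desc.size
    gmax = n if cap_at_n_posts else int(math.isqrt(int(cum[-1])))
    best = 0
    for g in range(1, gmax + 1):
        total = cum[min(g, n) - 1]
        if total >= g * g:
            best = g
    return best


def hg_index(h: int, g: int) -> float:
    """Geometric mean sqrt(h * g) of the two indices."""
    if h < 0 or g < 0:
        raise ValueError("h and g must be non-negative")
    return math.sqrt(h * g)


def compute_scores(events: pd.DataFrame, users: pd.DataFrame) -> pd.DataFrame:
    """Score every user in the user table from the event log.

    Only reposts inside the log's observation window count (the log *is*
    the window).  Users with no original posts, or none that were
    reposted, score h = g = hg = 0.

    Returns a frame with columns ``user_id, n_posts, total_reposts, h, g,
    hg`` covering all users.
    """
    posts = events[events["event_type"] == "post"]
    reposts = events[events["event_type"] == "repost"]
    repost_counts = reposts["post_id"].value_counts()
    per_post = posts[["event_id", "user_id"]].copy()
    per_post["n_reposts"] = per_post["event_id"].map(repost_counts).fillna(0).astype(int)

    rows = []
    grouped = per_post.groupby("user_id")["n_reposts"]
    by_user = {uid: counts.to_numpy() for uid, counts in grouped}
    for uid in users["user_id"]:
        counts = by_user.get(uid, np.empty(0, dtype=np.int64))
        h = h_index(counts)
        g = g_index(counts)
        rows.append((uid, counts.size, int(counts.sum()), h, g, hg_index(h, g)))
    return pd.DataFrame(rows, columns=["user_id", "n_posts", "total_reposts", "h", "g", "hg"])


def assign_categories(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign the six quantile influence categories from hg scores.

    Users are ranked by hg descending.  Each tie block of identical hg
    values shares a single mid-rank percentile — the mean 0-based rank of
    the block plus one half, divided by N — so users with equal hg always
    receive equal categories, a fully tied mass sits at the 50th
    percentile (category ``low``), and with all-distinct scores the
    category populations match the nominal quantile widths.  The
    degenerate single-user input is assigned ``very_high``.

    Returns columns ``user_id, hg, percentile_rank, category`` where
    ``percentile_rank`` is the mid-rank percentile in [0, 100] (smaller =
    more influential).
    """
    if len(scores) == 0:
        raise ValueError("assign_categories requires at least one user")
    df = scores[["user_id", "hg"]].sort_values(
        ["hg", "user_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    n = len(df)
    ranks = np.arange(n, dtype=float)
    # mid-rank within each tie block of equal hg
    mean_rank = pd.Series(ranks).groupby(df["hg"].to_numpy()).transform("mean").to_numpy()
    frac = (mean_rank + 0.5) / n
    cat_idx = np.searchsorted(_BOUNDARIES, frac, side="right")
    cat_idx = np.clip(cat_idx, 0, len(CATEGORIES) - 1)
    categories = [CATEGORIES[i] for i in cat_idx]
    if n == 1:
        categories = ["very_high"]
        frac = np.array([0.0])
    out = df.assign(percentile_rank=frac * 100.0, category=categories)
    return out[["user_id", "hg", "percentile_rank", "category"]]


def score_and_categorize(events: pd.DataFrame, users: pd.DataFrame) -> pd.DataFrame:
    """Full influence table: scores plus categories for all users."""
    scores = compute_scores(events, users)
    cats = assign_categories(scores)
    return scores.merge(cats[["user_id", "percentile_rank", "category"]], on="user_id")
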