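"""Reconstruct repost cascades: rooted who-reposted-from-whom trees.

Platform APIs report only which *original* post a repost shares, never
whom it was reposted from.  The cascade is therefore inferred: the
original post is the root; each repost attaches to the candidate parent
— the original author or an earlier non-official reposter whom the
reposter follows — whose own share is temporally closest before the
repost (the share most recently on the reposter's feed).  Official
accounts are excluded as reposters, though original posts *by* official
accounts are retained as roots.

When a reposter follows none of the prior sharers, the node attaches to
the root and is flagged (``fallback``) so downstream consumers can run
sensitivity analyses; alternatives (``drop`` the node, or ``closest``
prior sharer regardless of follow edges) are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from repostflow.data_io import ChronologyError


@dataclass
class Cascade:
    """A rooted repost tree for one original post.

    ``node_times`` maps every cascade member (including the root author)
    to their share timestamp; ``parent`` maps each reposter to the user
    they were inferred to repost from; ``fallback`` lists reposters
    attached to the root because no candidate parent existed.
    """

    root_post_id: str
    root_author_id: str
    node_times: dict[str, int]
    parent: dict[str, str]
    fallback: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        """Total reposts in the cascade (nodes minus the root)."""
        return len(self.parent)

    @property
    def nodes(self) -> set[str]:
        return set(self.node_times)


def _follow_lookup(edges: pd.DataFrame) -> dict[str, set[str]]:
    lookup: dict[str, set[str]] = {}
    for follower, followee in zip(edges["follower_id"], edges["followee_id"]):
        lookup.setdefault(follower, set()).add(followee)
    return lookup


def build_cascade(
    post: pd.Series,
    reposts: pd.DataFrame,
    edges: pd.DataFrame | dict[str, set[str]],
    users: pd.DataFrame | set[str],
    fallback_mode: str = "root",
) -> Cascade:
    """Build the cascade of one original post from its time-ordered reposts.

    ``edges`` may be a DataFrame or a precomputed follower -> followees
    mapping; ``users`` may be a DataFrame or a precomputed set of
    official user ids.  ``fallback_mode`` is one of ``root`` (attach to
    the root, flagged), ``drop`` (discard the node), or ``closest``
    (attach to the most recent prior sharer regardless of follow edges).
    """
    if fallback_mode not in {"root", "drop", "closest"}:
        raise ValueError(f"unknown fallback_mode {fallback_mode!r}")
    follows = edges if isinstance(edges, dict) else _follow_lookup(edges)
    official = (
        users
        if isinstance(users, set)
        else set(users.loc[users["is_official"], "user_id"])
    )

    root_author = str(post["user_id"])
    root_time = int(post["timestamp"])
    post_id = str(post["post_id"])

    cascade = Cascade(post_id, root_author, {root_author: root_time}, {})
    # share time of every current cascade member, root included
    share_time = {root_author: root_time}

    ordered = reposts.sort_values(["timestamp", "event_id"], kind="mergesort")
    for r in ordered.itertuples(index=False):
        x, t = str(r.user_id), int(r.timestamp)
        if x in official:
            continue
        if t <= root_time:
            raise ChronologyError(
                f"repost by {x!r} at t={t} not strictly after root post at t={root_time}"
            )
        followees = follows.get(x, set())
        candidates = [
            (share_time[s], s) for s in followees if s in share_time and share_time[s] < t
        ]
        if candidates:
            # temporally closest prior share; ties broken by user_id ascending
            best_t = max(ts for ts, _ in candidates)
            parent = min(s for ts, s in candidates if ts == best_t)
            is_fallback = False
        elif fallback_mode == "drop":
            continue
        elif fallback_mode == "closest":
            prior = [(ts, s) for s, ts in share_time.items() if ts < t]
            best_t = max(ts for ts, _ in prior)
            parent = min(s for ts, s in prior if ts == best_t)
            is_fallback = True
        else:  # root
            parent = root_author
            is_fallback = True
        cascade.node_times[x] = t
        cascade.parent[x] = parent
        if is_fallback:
            cascade.fallback.add(x)
        share_time[x] = t
    return cascade


def build_all_cascades(
    events: pd.DataFrame,
    edges: pd.DataFrame,
    users: pd.DataFrame,
    fallback_mode: str = "root",
) -> dict[str, Cascade]:
    """One cascade per original post with at least one surviving repost.

    Original posts by official accounts are retained as roots; official
    accounts are removed only as reposters.
    """
    follows = _follow_lookup(edges)
    official = set(users.loc[users["is_official"], "user_id"])
    posts = events[events["event_type"] == "post"]
    reposts = events[events["event_type"] == "repost"]

    cascades: dict[str, Cascade] = {}
    grouped = dict(tuple(reposts.groupby("post_id"))) if len(reposts) else {}
    for post in posts.itertuples(index=False):
        pid = str(post.post_id)
        group = grouped.get(pid)
        if group is None:
            continue
        post_row = pd.Series(
            {"post_id": pid, "user_id": post.user_id, "timestamp": post.timestamp}
        )
        cascade = build_cascade(post_row, group, follows, official, fallback_mode)
        if cascade.size >= 1:
            cascades[pid] = cascade
    return cascades


def cascades_to_frame(cascades: dict[str, Cascade]) -> pd.DataFrame:
    """Edge-list view: one row per repost plus one root row per cascade."""
    rows = []
    for pid in sorted(cascades):
        c = cascades[pid]
        rows.append((pid, c.root_author_id, "", c.node_times[c.root_author_id], 0))
        for child in sorted(c.parent, key=lambda u: (c.node_times[u], u)):
            rows.append((pid, child, c.parent[child], c.node_times[child], int(child in c.fallback)))
    return pd.DataFrame(
        rows,
        columns=["cascade_id", "child_user_id", "parent_user_id", "child_timestamp", "fallback_flag"],
    )
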