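"""Virtual timelines: reconstructed exposure of each user to followee reposts.

A user's virtual timeline is the chronological feed of reposts made by
the accounts they follow.  Three filtering rules apply:

1. only users who made at least one repost (of anything) during the
   observation window appear as viewers, removing dormant accounts;
2. official accounts are excluded as senders (their reposting has
   different motivations), though their original posts still seed
   cascades;
3. once a viewer has reposted a post, later followee shares of that same
   post are removed from their timeline (they are no longer exposures
   that could cause the repost).

Each emitted entry is one *view*.  A view is *credited* when the viewer
subsequently reposted the post and the cascade names this sender as the
viewer's parent — i.e. this exposure is the inferred transmission edge.
True impressions are unknowable; every timeline appearance counts as a
view by convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from repostflow.cascade_builder import Cascade

TIMELINE_COLUMNS = ["viewer_id", "sender_id", "post_id", "sender_share_time", "credited"]


def build_timelines(
    events: pd.DataFrame,
    edges: pd.DataFrame,
    users: pd.DataFrame,
    cascades: dict[str, Cascade],
    suppress_at_equal_time: bool = True,
) -> pd.DataFrame:
    """Emit one row per (viewer, followee repost) exposure.

    ``suppress_at_equal_time`` controls the rule-3 boundary: when True
    (default) a followee share timestamped exactly at the viewer's own
    repost time is suppressed.

    Returns a frame with columns ``viewer_id, sender_id, post_id,
    sender_share_time, credited`` ordered by viewer then share time.
    """
    reposts = events[events["event_type"] == "repost"]
    if len(reposts) == 0:
        return pd.DataFrame(columns=TIMELINE_COLUMNS)

    official = set(users.loc[users["is_official"], "user_id"])
    active_viewers = set(reposts["user_id"])

    sender_reposts = reposts[~reposts["user_id"].isin(official)]
    if len(sender_reposts) == 0:
        return pd.DataFrame(columns=TIMELINE_COLUMNS)

    # expand each repost to its sender's followers
    entries = sender_reposts.rename(
        columns={"user_id": "sender_id", "timestamp": "sender_share_time"}
    )[["sender_id", "post_id", "sender_share_time"]].merge(
        edges.rename(columns={"followee_id": "sender_id", "follower_id": "viewer_id"}),
        on="sender_id",
        how="inner",
    )
    entries = entries[entries["viewer_id"].isin(active_viewers)]

    # rule 3: drop shares at/after the viewer's own repost of the post
    own = reposts.rename(
        columns={"user_id": "viewer_id", "timestamp": "viewer_repost_time"}
    )[["viewer_id", "post_id", "viewer_repost_time"]]
    entries = entries.merge(own, on=["viewer_id", "post_id"], how="left")
    if suppress_at_equal_time:
        keep = entries["viewer_repost_time"].isna() | (
            entries["sender_share_time"] < entries["viewer_repost_time"]
        )
    else:
        keep = entries["viewer_repost_time"].isna() | (
            entries["sender_share_time"] <= entries["viewer_repost_time"]
        )
    entries = entries[keep]

    # credit: the cascade's inferred transmission edge sender -> viewer
    parent_rows = [
        (pid, child, c.parent[child])
        for pid, c in cascades.items()
        for child in c.parent
        if child not in c.fallback
    ]
    parents = pd.DataFrame(parent_rows, columns=["post_id", "viewer_id", "cascade_parent"])
    entries = entries.merge(parents, on=["post_id", "viewer_id"], how="left")
    entries["credited"] = (
        entries["cascade_parent"].notna()
        & (entries["cascade_parent"] == entries["sender_id"])
    )

    out = entries[TIMELINE_COLUMNS].sort_values(
        ["viewer_id", "sender_share_time", "post_id", "sender_id"], kind="mergesort"
    )
    out["credited"] = out["credited"].astype(bool)
    out["sender_share_time"] = out["sender_share_time"].astype("int64")
    return out.reset_index(drop=True)
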