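"""Cascading repost probability (CRP), share attribution, and repost rates.

The CRP of a user or influence category is

    CRP = (number of reposted reposts) / (number of viewed reposts)

where a *viewed repost* is one appearance of the sender's repost on a
follower's virtual timeline and a *reposted repost* is a viewed repost
that the viewer subsequently reposted with this sender as their cascade
parent.  A sender whose repost is viewed by three followers, two of whom
repost it onward, has CRP 2/3.

Category-level CRPs pool raw counts: viewed and credited entries are
summed within each category and divided once, not averaged across users.
Statistics can be restricted to a window of hours since the original
post and to posts above (or below) a final-popularity threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from repostflow.cascade_builder import Cascade

_SECONDS_PER_HOUR = 3600.0

CRP_COLUMNS = ["group", "window", "stratum", "viewed", "reposted", "crp", "defined"]


class UndefinedCRPError(ZeroDivisionError):
    """CRP requested for zero viewed reposts."""


def crp(viewed: int, reposted: int) -> float:
    """Pointwise CRP = reposted / viewed; undefined when nothing was viewed."""
    if reposted < 0 or viewed < reposted:
        raise ValueError("need viewed >= reposted >= 0")
    if viewed == 0:
        raise UndefinedCRPError("CRP is undefined for zero viewed reposts")
    return reposted / viewed


def post_times(events: pd.DataFrame) -> pd.Series:
    """Mapping post_id -> original post timestamp."""
    posts = events[events["event_type"] == "post"]
    return pd.Series(posts["timestamp"].to_numpy(), index=posts["post_id"])


def cascade_sizes(cascades: dict[str, Cascade]) -> pd.Series:
    """Mapping post_id -> total reposts in the constructed cascade."""
    return pd.Series({pid: c.size for pid, c in cascades.items()}, dtype="int64")


def _scope_entries(
    entries: pd.DataFrame,
    origin: pd.Series,
    sizes: pd.Series,
    window: tuple[float, float] | None,
    popularity_min: int = 0,
    popularity_max: int | None = None,
) -> pd.DataFrame:
    scoped = entries.copy()
    scoped["age_hours"] = (
        scoped["sender_share_time"] - scoped["post_id"].map(origin)
    ) / _SECONDS_PER_HOUR
    if window is not None:
        lo, hi = window
        scoped = scoped[(scoped["age_hours"] >= lo) & (scoped["age_hours"] < hi)]
    size = scoped["post_id"].map(sizes).fillna(0).astype(int)
    mask = size >= popularity_min
    if popularity_max is not None:
        mask &= size < popularity_max
    return scoped[mask]


def _attach_category(entries: pd.DataFrame, categories: pd.DataFrame) -> pd.DataFrame:
    cat = categories.set_index("user_id")["category"]
    out = entries.copy()
    out["sender_category"] = out["sender_id"].map(cat)
    if out["sender_category"].isna().any():
        missing = out.loc[out["sender_category"].isna(), "sender_id"].iloc[0]
        raise KeyError(f"no influence category for sender {missing!r}")
    return out


def _pooled_table(
    scoped: pd.DataFrame, window_label: str, stratum_label: str
) -> pd.DataFrame:
    from repostflow.influence_scoring import CATEGORIES

    grouped = scoped.groupby("sender_category")["credited"].agg(["size", "sum"])
    rows = []
    for cat in CATEGORIES:
        if cat in grouped.index:
            viewed = int(grouped.loc[cat, "size"])
            reposted = int(grouped.loc[cat, "sum"])
        else:
            viewed = reposted = 0
        defined = viewed > 0
        rows.append(
            (cat, window_label, stratum_label, viewed, reposted,
             reposted / viewed if defined else np.nan, defined)
        )
    return pd.DataFrame(rows, columns=CRP_COLUMNS)


def crp_by_user(entries: pd.DataFrame) -> pd.DataFrame:
    """Per-sender CRP: each user's viewed reposts and further-reposted views."""
    grouped = entries.groupby("sender_id")["credited"].agg(["size", "sum"])
    return pd.DataFrame(
        {
            "user_id": grouped.index,
            "viewed": grouped["size"].astype(int).to_numpy(),
            "reposted": grouped["sum"].astype(int).to_numpy(),
            "crp": (grouped["sum"] / grouped["size"]).to_numpy(),
        }
    ).reset_index(drop=True)


def crp_by_category(
    entries: pd.DataFrame,
    categories: pd.DataFrame,
    cascades: dict[str, Cascade],
    events: pd.DataFrame,
    window: tuple[float, float] = (0.0, 6.0),
    popularity_min: int = 0,
    popularity_max: int | None = None,
) -> pd.DataFrame:
    """Pooled CRP per influence category within a time window and stratum.

    ``window`` is a half-open interval of hours since the original post;
    ``popularity_min`` keeps posts whose constructed cascade has at least
    that many reposts (strata are cumulative: >=1000 contains >=5000);
    ``popularity_max`` (exclusive) carves the complement, e.g. the
    "<1000" stratum via ``popularity_min=0, popularity_max=1000``.
    Zero-view rows are emitted flagged ``defined=False`` rather than
    dropped, so "no data" is distinguishable from CRP 0.
    """
    scoped = _scope_entries(
        _attach_category(entries, categories),
        post_times(events),
        cascade_sizes(cascades),
        window,
        popularity_min,
        popularity_max,
    )
    if popularity_max is not None:
        stratum = f"[{popularity_min},{popularity_max})"
    else:
        stratum = f">={popularity_min}"
    return _pooled_table(scoped, f"[{window[0]},{window[1]})h", stratum)


def temporal_crp(
    entries: pd.DataFrame,
    categories: pd.DataFrame,
    cascades: dict[str, Cascade],
    events: pd.DataFrame,
    bin_width: float = 1.0,
    horizon: float = 24.0,
    popularity_min: int = 0,
) -> pd.DataFrame:
    """Pooled CRP per (category, half-open hourly bin since posting)."""
    scoped = _scope_entries(
        _attach_category(entries, categories),
        post_times(events),
        cascade_sizes(cascades),
        (0.0, horizon),
        popularity_min,
    )
    n_bins = int(np.ceil(horizon / bin_width))
    tables = []
    for k in range(n_bins):
        lo, hi = k * bin_width, min((k + 1) * bin_width, horizon)
        part = scoped[(scoped["age_hours"] >= lo) & (scoped["age_hours"] < hi)]
        tbl = _pooled_table(part, f"[{lo},{hi})h", f">={popularity_min}")
        tbl.insert(1, "bin", k)
        tables.append(tbl)
    return pd.concat(tables, ignore_index=True)


def share_attribution(
    entries: pd.DataFrame,
    categories: pd.DataFrame,
    cascades: dict[str, Cascade] | None = None,
    events: pd.DataFrame | None = None,
    window: tuple[float, float] | None = None,
    popularity_min: int = 0,
) -> pd.DataFrame:
    """View share and repost share of each influence category.

    ``view_share`` is the fraction of all in-scope views whose sender is
    in the category; ``repost_share`` the same for credited reposts.
    Each column sums to 1.  Raises :class:`UndefinedCRPError` when there
    are no in-scope views.
    """
    scoped = _attach_category(entries, categories)
    if window is not None or popularity_min > 0:
        if cascades is None or events is None:
            raise ValueError("cascades and events are required for scoped attribution")
        scoped = _scope_entries(
            scoped, post_times(events), cascade_sizes(cascades), window, popularity_min
        )
    total_views = len(scoped)
    if total_views == 0:
        raise UndefinedCRPError("no in-scope views: share table undefined")
    total_credits = int(scoped["credited"].sum())

    from repostflow.influence_scoring import CATEGORIES

    grouped = scoped.groupby("sender_category")["credited"].agg(["size", "sum"])
    rows = []
    for cat in CATEGORIES:
        v = int(grouped.loc[cat, "size"]) if cat in grouped.index else 0
        c = int(grouped.loc[cat, "sum"]) if cat in grouped.index else 0
        rows.append(
            (cat, v, c, v / total_views, c / total_credits if total_credits else np.nan)
        )
    return pd.DataFrame(
        rows, columns=["group", "viewed", "reposted", "view_share", "repost_share"]
    )


def repost_rate_by_category(
    events: pd.DataFrame, categories: pd.DataFrame
) -> pd.DataFrame:
    """Mean reposts made per user, by the reposting user's own category."""
    from repostflow.influence_scoring import CATEGORIES

    reposts = events[events["event_type"] == "repost"]
    cat = categories.set_index("user_id")["category"]
    made = reposts["user_id"].map(cat).value_counts()
    members = categories["category"].value_counts()
    rows = []
    for c in CATEGORIES:
        n_members = int(members.get(c, 0))
        n_made = int(made.get(c, 0))
        rows.append((c, n_members, n_made, n_made / n_members if n_members else np.nan))
    return pd.DataFrame(rows, columns=["group", "n_users", "n_reposts", "reposts_per_user"])
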