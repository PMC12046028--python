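import numpy as np
import pandas as pd
import pytest

from repostflow.cascade_builder import build_all_cascades
from repostflow.influence_scoring import CATEGORIES, score_and_categorize
from repostflow.secondary_spread import (
    UndefinedCRPError,
    crp,
    crp_by_category,
    crp_by_user,
    repost_rate_by_category,
    share_attribution,
    temporal_crp,
)
from repostflow.virtual_timeline import build_timelines

from conftest import make_edges, make_events, make_users


@pytest.mark.parametrize(
    "viewed,reposted,expected",
    [(3, 2, 2 / 3), (5, 0, 0.0), (4, 4, 1.0), (1, 1, 1.0)],
)
def test_crp_ratio(viewed, reposted, expected):
    assert crp(viewed, reposted) == pytest.approx(expected)


def test_crp_zero_views_is_undefined_not_zero():
    with pytest.raises(UndefinedCRPError):
        crp(0, 0)


def test_crp_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        crp(2, 3)


@pytest.fixture(scope="module")
def sim_tables(sim_dataset):
    _, users, edges, events = sim_dataset
    cascades = build_all_cascades(events, edges, users)
    entries = build_timelines(events, edges, users, cascades)
    categories = score_and_categorize(events, users)
    return users, edges, events, cascades, entries, categories


def test_worked_example_sharer_crp_is_two_thirds(fig2c_dataset):
    users, edges, events = fig2c_dataset
    cascades = build_all_cascades(events, edges, users)
    entries = build_timelines(events, edges, users, cascades)
    per_user = crp_by_user(entries).set_index("user_id")
    assert per_user.loc["S", "viewed"] == 3
    assert per_user.loc["S", "reposted"] == 2
    assert per_user.loc["S", "crp"] == pytest.approx(2 / 3)


def test_single_sender_category_row(fig2c_dataset):
    users, edges, events = fig2c_dataset
    cascades = build_all_cascades(events, edges, users)
    entries = build_timelines(events, edges, users, cascades)
    categories = score_and_categorize(events, users)
    table = crp_by_category(
        entries, categories, cascades, events, window=(0.0, 6.0)
    ).set_index("group")
    defined = table[table["defined"]]
    assert len(defined) == 1  # S is the only sender with views
    row = defined.iloc[0]
    assert (row["viewed"], row["reposted"]) == (3, 2)
    assert row["crp"] == pytest.approx(2 / 3)


def test_window_excluding_everything_flags_undefined(sim_tables):
    users, edges, events, cascades, entries, categories = sim_tables
    table = crp_by_category(entries, categories, cascades, events, window=(1e6, 2e6))
    assert not table["defined"].any()
    assert table["crp"].isna().all()


def test_pooled_crp_equals_total_ratio(sim_tables):
    users, edges, events, cascades, entries, categories = sim_tables
    table = crp_by_category(entries, categories, cascades, events, window=(0.0, 1e9))
    assert table["viewed"].sum() == len(entries)
    assert table["reposted"].sum() == entries["credited"].sum()
    pooled = table["reposted"].sum() / table["viewed"].sum()
    assert pooled == pytest.approx(entries["credited"].mean())


def test_narrowing_window_never_increases_counts(sim_tables):
    users, edges, events, cascades, entries, categories = sim_tables
    wide = crp_by_category(entries, categories, cascades, events, window=(0.0, 24.0))
    narrow = crp_by_category(entries, categories, cascades, events, window=(0.0, 6.0))
    assert (narrow["viewed"].to_numpy() <= wide["viewed"].to_numpy()).all()
    assert (narrow["reposted"].to_numpy() <= wide["reposted"].to_numpy()).all()


def test_popularity_strata_are_cumulative(sim_tables):
    users, edges, events, cascades, entries, categories = sim_tables
    loose = crp_by_category(entries, categories, cascades, events, popularity_min=10)
    tight = crp_by_category(entries, categories, cascades, events, popularity_min=50)
    assert (tight["viewed"].to_numpy() <= loose["viewed"].to_numpy()).all()
    # complement stratum partitions the views
    below = crp_by_category(
        entries, categories, cascades, events, popularity_min=0, popularity_max=10
    )
    full = crp_by_category(entries, categories, cascades, events, popularity_min=0)
    assert (below["viewed"] + loose["viewed"]).equals(full["viewed"])


def test_temporal_binning():
    users = make_users(["A", "S", "X"])
    edges = make_edges([("S", "A"), ("X", "S")])
    events = make_events(
        [("P", "A", 0)], [("r1", "S", "P", 1800), ("r2", "X", "P", 7200)]
    )
    cascades = build_all_cascades(events, edges, users)
    entries = build_timelines(events, edges, users, cascades)
    categories = score_and_categorize(events, users)
    table = temporal_crp(entries, categories, cascades, events, bin_width=1.0, horizon=3.0)
    by_bin = table.groupby("bin")["viewed"].sum()
    assert by_bin[0] == 1 and by_bin[1] == 0 and by_bin[2] == 0  # 0.5h -> bin [0,1)


def test_temporal_bin_count():
    users = make_users(["A", "S", "X"])
    edges = make_edges([("S", "A"), ("X", "S")])
    events = make_events([("P", "A", 0)], [("r1", "S", "P", 1800), ("r2", "X", "P", 7200)])
    cascades = build_all_cascades(events, edges, users)
    entries = build_timelines(events, edges, users, cascades)
    categories = score_and_categorize(events, users)
    table = temporal_crp(entries, categories, cascades, events, bin_width=0.5, horizon=3.0)
    assert len(table) == 6 * len(CATEGORIES)


def test_share_columns_sum_to_one(sim_tables):
    users, edges, events, cascades, entries, categories = sim_tables
    table = share_attribution(entries, categories)
    assert table["view_share"].sum() == pytest.approx(1.0)
    assert table["repost_share"].sum() == pytest.approx(1.0)


def test_share_arithmetic_two_groups():
    # hand-built entries: two sender categories with views 60/40, credits 50/50
    entries = pd.DataFrame(
        {
            "viewer_id": ["v"] * 100,
            "sender_id": ["a"] * 60 + ["b"] * 40,
            "post_id": ["p"] * 100,
            "sender_share_time": np.arange(100),
            "credited": [True] * 30 + [False] * 30 + [True] * 30 + [False] * 10,
        }
    )
    categories = pd.DataFrame(
        {"user_id": ["a", "b"], "category": ["very_high", "low"]}
    )
    table = share_attribution(entries, categories).set_index("group")
    assert table.loc["very_high", "view_share"] == pytest.approx(0.6)
    assert table.loc["low", "view_share"] == pytest.approx(0.4)
    assert table.loc["very_high", "repost_share"] == pytest.approx(0.5)
    assert table.loc["low", "repost_share"] == pytest.approx(0.5)


def test_share_undefined_without_views():
    entries = pd.DataFrame(
        columns=["viewer_id", "sender_id", "post_id", "sender_share_time", "credited"]
    )
    categories = pd.DataFrame({"user_id": [], "category": []})
    with pytest.raises(UndefinedCRPError):
        share_attribution(entries, categories)


def test_missing_sender_category_raises(sim_tables):
    users, edges, events, cascades, entries, categories = sim_tables
    broken = categories[categories["user_id"] != entries["sender_id"].iloc[0]]
    with pytest.raises(KeyError):
        crp_by_category(entries, broken, cascades, events)


def test_repost_rate_by_category():
    users = make_users(["a", "b", "c"])
    events = make_events(
        [("p1", "a", 0)], [("r1", "b", "p1", 10), ("r2", "c", "p1", 20)]
    )
    categories = pd.DataFrame(
        {"user_id": ["a", "b", "c"], "category": ["very_high", "low", "low"]}
    )
    table = repost_rate_by_category(events, categories).set_index("group")
    assert table.loc["low", "reposts_per_user"] == pytest.approx(1.0)
    assert table.loc["very_high", "reposts_per_user"] == 0.0
    assert np.isnan(table.loc["mid", "reposts_per_user"])  # no members
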