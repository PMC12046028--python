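"""Shared fixtures: inline dataset builders and one simulated dataset."""

from __future__ import annotations

import pandas as pd
import pytest

from repostflow.data_io import EVENT_COLUMNS, sort_events
from repostflow.synthetic_data import SimulationConfig, simulate_dataset


def make_users(ids, official=(), topics=None) -> pd.DataFrame:
    topics = topics or {}
    return pd.DataFrame(
        {
            "user_id": list(ids),
            "is_official": [u in set(official) for u in ids],
            "topic": [topics.get(u, "t0") for u in ids],
        }
    )


def make_edges(pairs) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=["follower_id", "followee_id"])


def make_events(posts, reposts=()) -> pd.DataFrame:
    """posts: (post_id, author, t); reposts: (repost_id, user, post_id, t)."""
    rows = [("post", pid, u, pid, t) for pid, u, t in posts]
    rows += [("repost", rid, u, pid, t) for rid, u, pid, t in reposts]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df["timestamp"] = df["timestamp"].astype("int64")
    return sort_events(df)


@pytest.fixture(scope="session")
def sim_dataset():
    """One default-condition synthetic dataset shared across unit tests."""
    config = SimulationConfig(seed=42)
    users, edges, events = simulate_dataset(config)
    return config, users, edges, events


@pytest.fixture(scope="session")
def fig2c_dataset():
    """Minimal worked instance: a sharer viewed by three followers, two of
    whom repost with the sharer as cascade parent (CRP 2/3)."""
    users = make_users(["A", "B", "S", "F1", "F2", "F3"])
    edges = make_edges(
        [("S", "A"), ("F1", "S"), ("F2", "S"), ("F3", "S"), ("F3", "B")]
    )
    events = make_events(
        posts=[("P", "A", 0), ("Q", "B", 50)],
        reposts=[
            ("r1", "S", "P", 100),
            ("r2", "F3", "Q", 150),  # keeps F3 an active (non-dormant) viewer
            ("r3", "F1", "P", 200),
            ("r4", "F2", "P", 300),
        ],
    )
    return users, edges, events
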